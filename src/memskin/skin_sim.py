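"""Biophysical circuit simulator for non-linear skin recordings.

The model is the two-branch parallel circuit of the skin under a dry
measuring electrode:

* a **sweat-duct memristor** whose memductance ``G_D(x) = g_min + (g_max -
  g_min) x`` tracks a dimensionless duct-filling state ``x`` in [0, 1],
  driven electro-osmotically by the effective voltage (separate fill and
  drain gains, first-order relaxation back to the baseline filling);
* a **stratum-corneum branch**: an NTC-thermistor conductance
  ``G_S(T) = g_ref exp(-B (1/T - 1/T_ref))`` self-heated by Joule power
  through a first-order thermal circuit, in parallel with a capacitance
  ``C_S``;
* a series DC offset ``e_dc`` (endogenous skin / half-cell potentials), so
  the branch elements see ``v_eff = v + e_dc``;
* additive Gaussian current-measurement noise.

State equations (fixed-step RK4 on the stimulus grid with internal
substeps)::

    dx/dt = a(v_eff) * v_eff - (x - x0) / tau_x,   a = a_plus if v_eff > 0 else a_minus
    dT/dt = (G_S(T) * v_eff**2 - (T - T_amb) / R_th) / C_th
    i(t)  = (G_D(x) + G_S(T)) * v_eff + C_S * dv/dt + noise

Around an equilibrium state the small-signal admittance is
``Y = G_D(x_Q) + G_S(T_Q) + j 2*pi*f C_S``.

A population sampler draws per-subject parameter sets from per-phenotype
log-normal distributions; the five phenotype classes reproduce the observed
loop morphologies (symmetric large-lobe, small-lobe, asymmetric,
offset-shifted pinch, and the two-pinched-point thermistor-dominated class).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidParameterError,
    InvalidSpecError,
    InvalidStateError,
    NumericalFailureError,
)
from .recording import Recording
from .stimuli import VoltageStimulus, experiment_grid, generate_waveform, waveform_functions

__all__ = [
    "SweatDuctParams",
    "StratumCorneumParams",
    "SkinCircuitParams",
    "PopulationSpec",
    "SimulatedSubject",
    "PHENOTYPE_CLASSES",
    "DEFAULT_CLASS_WEIGHTS",
    "DEFAULT_CLASS_DISTRIBUTIONS",
    "PHENOTYPE_CONFIG_VERSION",
    "simulate_recording",
    "simulate_batch",
    "simulate_cohort",
    "sample_population",
    "small_signal_admittance",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class SweatDuctParams:
    """Sweat-duct memristor parameters.

    ``g_min``/``g_max`` bound the memductance (siemens); ``x0`` is the
    baseline duct filling the state relaxes to with time constant ``tau_x``
    (seconds); ``a_plus``/``a_minus`` are the electro-osmotic fill/drain
    gains (1/(V*s)) for positive/negative effective voltage.
    """

    g_min: float
    g_max: float
    x0: float = 0.5
    a_plus: float = 0.1
    a_minus: float = 0.1
    tau_x: float = 8.0

    def __post_init__(self) -> None:
        if self.g_min < 0:
            raise InvalidParameterError(f"g_min must be >= 0 S, got {self.g_min}")
        if self.g_max < self.g_min:
            raise InvalidParameterError("g_max must be >= g_min")
        if not (0.0 <= self.x0 <= 1.0):
            raise InvalidParameterError(f"x0 must lie in [0, 1], got {self.x0}")
        if self.a_plus < 0 or self.a_minus < 0:
            raise InvalidParameterError("fill/drain gains must be >= 0")
        if not (self.tau_x > 0):
            raise InvalidParameterError(f"tau_x must be > 0 s, got {self.tau_x}")

    def memductance(self, x):
        """G_D(x) in siemens for duct filling x in [0, 1]."""
        return self.g_min + (self.g_max - self.g_min) * np.asarray(x)


@dataclass(frozen=True)
class StratumCorneumParams:
    """Stratum-corneum NTC thermistor + capacitance parameters.

    ``g_ref`` is the conductance at the reference temperature ``T_ref``;
    ``b_ntc`` (kelvin) sets the Arrhenius-type temperature sensitivity;
    the lumped thermal circuit has heat capacity ``c_th`` (J/K) and thermal
    resistance ``r_th`` (K/W) to the ambient ``T_amb``; ``c_s`` is the
    parallel capacitance (farads).
    """

    g_ref: float = 1.5e-6
    b_ntc: float = 3000.0
    t_ref: float = 306.0
    t_amb: float = 306.0
    c_th: float = 2.0e-6
    r_th: float = 2.0e5
    c_s: float = 15.0e-9

    def __post_init__(self) -> None:
        if self.g_ref < 0 or self.b_ntc < 0 or self.c_s < 0:
            raise InvalidParameterError("g_ref, b_ntc and c_s must be >= 0")
        if not (self.t_ref > 0 and self.t_amb > 0):
            raise InvalidParameterError("temperatures must be positive (kelvin)")
        if not (self.c_th > 0 and self.r_th > 0):
            raise InvalidParameterError("c_th and r_th must be > 0")

    def conductance(self, T):
        """G_S(T) in siemens; non-decreasing in T (NTC behaviour)."""
        return self.g_ref * np.exp(-self.b_ntc * (1.0 / np.asarray(T) - 1.0 / self.t_ref))


@dataclass(frozen=True)
class SkinCircuitParams:
    """Full parameter set of the skin circuit model."""

    duct: SweatDuctParams
    sc: StratumCorneumParams = field(default_factory=StratumCorneumParams)
    e_dc: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0 A, got {self.noise_sd}")


def small_signal_admittance(
    params: SkinCircuitParams, x_q: float, t_q: float, f: float
) -> complex:
    """Small-signal (mem-)admittance about the equilibrium state (x_q, t_q).

    ``Y = G_D(x_q) + G_S(t_q) + j * 2*pi*f * C_S`` in siemens.
    """
    if not (0.0 <= x_q <= 1.0):
        raise InvalidStateError(f"x_q must lie in [0, 1], got {x_q}")
    if not (t_q > 0):
        raise InvalidStateError(f"t_q must be > 0 K, got {t_q}")
    if f < 0:
        raise InvalidParameterError(f"frequency must be >= 0 Hz, got {f}")
    g = float(params.duct.memductance(x_q)) + float(params.sc.conductance(t_q))
    return complex(g, 2.0 * np.pi * f * params.sc.c_s)


# ---------------------------------------------------------------------------
# ODE integration


def _param_arrays(param_sets: list[SkinCircuitParams]) -> dict[str, np.ndarray]:
    cols: dict[str, list[float]] = {k: [] for k in (
        "g_min", "g_max", "x0", "a_plus", "a_minus", "tau_x",
        "g_ref", "b_ntc", "t_ref", "t_amb", "c_th", "r_th", "c_s",
        "e_dc", "noise_sd")}
    for p in param_sets:
        d, s = p.duct, p.sc
        for k in ("g_min", "g_max", "x0", "a_plus", "a_minus", "tau_x"):
            cols[k].append(getattr(d, k))
        cols["g_ref"].append(s.g_ref)
        cols["b_ntc"].append(s.b_ntc)
        cols["t_ref"].append(s.t_ref)
        cols["t_amb"].append(s.t_amb)
        cols["c_th"].append(s.c_th)
        cols["r_th"].append(s.r_th)
        cols["c_s"].append(s.c_s)
        cols["e_dc"].append(p.e_dc)
        cols["noise_sd"].append(p.noise_sd)
    return {k: np.asarray(v, dtype=float) for k, v in cols.items()}


def _integrate(
    pa: dict[str, np.ndarray],
    stim: VoltageStimulus,
    substeps: int,
    x_init: np.ndarray | None = None,
    t_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RK4-integrate the state ODEs for a batch of parameter sets.

    Returns noiseless currents ``i`` of shape (m, n) plus the state
    trajectories ``x`` and ``T`` on the sample grid.
    """
    m = len(pa["g_min"])
    n = stim.n_samples
    v_fn, dv_fn = waveform_functions(stim)
    h = stim.dt / substeps
    n_fine = (n - 1) * substeps
    t_fine = np.arange(n_fine + 1) * h
    v_fine = np.asarray(v_fn(t_fine), dtype=float)
    v_mid = np.asarray(v_fn(t_fine[:-1] + 0.5 * h), dtype=float)

    x0, ap, am, tau = pa["x0"], pa["a_plus"], pa["a_minus"], pa["tau_x"]
    gref, bntc = pa["g_ref"], pa["b_ntc"]
    inv_tref = 1.0 / pa["t_ref"]
    tamb, cth, rth = pa["t_amb"], pa["c_th"], pa["r_th"]
    e_dc = pa["e_dc"]

    def deriv(V, x, T):
        ve = V + e_dc
        a = np.where(ve > 0.0, ap, am)
        dx = a * ve - (x - x0) / tau
        gs = gref * np.exp(-bntc * (1.0 / T - inv_tref))
        dT = (gs * ve * ve - (T - tamb) / rth) / cth
        return dx, dT

    x = np.array(x0, copy=True) if x_init is None else np.asarray(x_init, dtype=float).copy()
    T = np.array(tamb, copy=True) if t_init is None else np.asarray(t_init, dtype=float).copy()
    xs = np.empty((m, n))
    Ts = np.empty((m, n))
    xs[:, 0], Ts[:, 0] = x, T

    half = 0.5 * h
    sixth = h / 6.0
    out = 1
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for s in range(n_fine):
            V0, Vm, V1 = v_fine[s], v_mid[s], v_fine[s + 1]
            k1x, k1T = deriv(V0, x, T)
            k2x, k2T = deriv(Vm, x + half * k1x, T + half * k1T)
            k3x, k3T = deriv(Vm, x + half * k2x, T + half * k2T)
            k4x, k4T = deriv(V1, x + h * k3x, T + h * k3T)
            x = np.clip(x + sixth * (k1x + 2.0 * k2x + 2.0 * k3x + k4x), 0.0, 1.0)
            T = T + sixth * (k1T + 2.0 * k2T + 2.0 * k3T + k4T)
            if (s + 1) % substeps == 0:
                xs[:, out], Ts[:, out] = x, T
                out += 1

    # 1e4 K is far beyond any physical skin temperature: treat thermal
    # runaway the same as numerical overflow and name the regime.
    ok = np.isfinite(xs).all(axis=1) & np.isfinite(Ts).all(axis=1) & (np.abs(Ts) < 1e4).all(axis=1)
    if not ok.all():
        bad = np.where(~ok)[0]
        raise NumericalFailureError(
            "state integration produced non-finite or runaway values for "
            f"parameter set(s) {bad.tolist()}; likely an unstable electro-thermal "
            "regime (r_th * g_ref * b_ntc too large for the applied amplitude)"
        )

    t_samp = np.arange(n) * stim.dt
    v_samp = np.asarray(v_fn(t_samp), dtype=float)
    dv_samp = np.asarray(dv_fn(t_samp), dtype=float)
    ve = v_samp[None, :] + e_dc[:, None]
    gd = pa["g_min"][:, None] + (pa["g_max"] - pa["g_min"])[:, None] * xs
    gs = gref[:, None] * np.exp(-bntc[:, None] * (1.0 / Ts - inv_tref[:, None]))
    i = (gd + gs) * ve + pa["c_s"][:, None] * dv_samp[None, :]
    return i, xs, Ts


def _noise_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(np.random.SeedSequence(seed))


def simulate_batch(
    param_sets: list[SkinCircuitParams],
    stim: VoltageStimulus,
    seeds: list | None = None,
    substeps: int = 10,
    subject_ids: list[str] | None = None,
    site: str = "forehead",
    initial_states: tuple[np.ndarray, np.ndarray] | None = None,
    return_states: bool = False,
):
    """Simulate many parameter sets under one shared stimulus (vectorized).

    ``seeds`` (one per parameter set) seed the additive current noise; pass
    ``None`` entries (or omit) for noiseless traces.  Returns a list of
    :class:`Recording`; with ``return_states=True`` also the (x, T) state
    trajectories on the sample grid.
    """
    m = len(param_sets)
    pa = _param_arrays(param_sets)
    x_init = t_init = None
    if initial_states is not None:
        x_init, t_init = initial_states
    i, xs, Ts = _integrate(pa, stim, substeps, x_init, t_init)
    t, v = generate_waveform(stim)
    if subject_ids is None:
        subject_ids = [f"S{k:03d}" for k in range(m)]
    recs = []
    for k in range(m):
        ik = i[k]
        sd = param_sets[k].noise_sd
        seed_k = None if seeds is None else seeds[k]
        if sd > 0 and seed_k is not None:
            ik = ik + _noise_rng(seed_k).normal(0.0, sd, size=len(ik))
        recs.append(
            Recording(
                subject_id=subject_ids[k], site=site, stimulus=stim,
                t=t, v=v, i=ik, meta={"substeps": substeps},
            )
        )
    if return_states:
        return recs, xs, Ts
    return recs


def simulate_recording(
    params: SkinCircuitParams,
    stim: VoltageStimulus,
    seed=None,
    subject_id: str = "sim",
    site: str = "forehead",
    substeps: int = 10,
    initial_state: tuple[float, float] | None = None,
) -> Recording:
    """Simulate one recording of the skin circuit under a voltage stimulus.

    ``seed`` feeds the additive Gaussian current noise (ignored when
    ``params.noise_sd == 0``); ``initial_state = (x, T)`` overrides the
    default re-initialization at (x0, T_amb), e.g. for state carry-over
    between consecutive stimuli.
    """
    init = None
    if initial_state is not None:
        init = (np.array([initial_state[0]]), np.array([initial_state[1]]))
    (rec,) = simulate_batch(
        [params], stim, seeds=[seed], substeps=substeps,
        subject_ids=[subject_id], site=site, initial_states=init,
    )
    return rec


# ---------------------------------------------------------------------------
# population sampling

PHENOTYPE_CLASSES = ("symmetric_large", "small_lobe", "asymmetric", "offset_shift", "two_pinch")

#: Forehead morphology counts over the 28-subject cohort: 6 symmetric
#: large-lobe (classes A/B merged), 10 small-lobe (C), 8 asymmetric (D),
#: 1 with a strongly offset pinch (E) and 3 thermistor-dominated two-pinch
#: loops (F).
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "symmetric_large": 6 / 28,
    "small_lobe": 10 / 28,
    "asymmetric": 8 / 28,
    "offset_shift": 1 / 28,
    "two_pinch": 3 / 28,
}

PHENOTYPE_CONFIG_VERSION = "1.0"

# distribution spec per field: ("lognormal", median, sigma_of_log),
# ("normal", mean, sd) or ("fixed", value). Medians chosen so that simulated
# currents stay below 100 uA at 1.2 V, two-pinch subjects peak at 2-10 uA,
# and the electro-thermal feedback loop gain stays < 1.
_DUCT_SC = {
    "g_ref": ("lognormal", 1.5e-6, 0.3),
    "b_ntc": ("lognormal", 3000.0, 0.1),
    "t_ref": ("fixed", 306.0),
    "t_amb": ("fixed", 306.0),
    "c_th": ("fixed", 2.0e-6),
    "r_th": ("lognormal", 2.0e5, 0.15),
    "c_s": ("lognormal", 15.0e-9, 0.3),
}

DEFAULT_CLASS_DISTRIBUTIONS: dict[str, dict[str, tuple]] = {
    "symmetric_large": {
        "g_min": ("lognormal", 8e-6, 0.4),
        "g_span": ("lognormal", 35e-6, 0.3),
        "x0": ("fixed", 0.5),
        "a_plus": ("lognormal", 0.12, 0.25),
        "a_minus": ("lognormal", 0.12, 0.25),
        "tau_x": ("lognormal", 8.0, 0.2),
        "e_dc": ("normal", 0.0, 0.02),
        "noise_sd": ("fixed", 50e-9),
        **_DUCT_SC,
    },
    "small_lobe": {
        "g_min": ("lognormal", 4e-6, 0.4),
        "g_span": ("lognormal", 8e-6, 0.3),
        "x0": ("fixed", 0.4),
        "a_plus": ("lognormal", 0.02, 0.3),
        "a_minus": ("lognormal", 0.02, 0.3),
        "tau_x": ("lognormal", 6.0, 0.2),
        "e_dc": ("normal", 0.0, 0.02),
        "noise_sd": ("fixed", 50e-9),
        **_DUCT_SC,
    },
    "asymmetric": {
        "g_min": ("lognormal", 5e-6, 0.4),
        "g_span": ("lognormal", 30e-6, 0.3),
        "x0": ("fixed", 0.12),
        "a_plus": ("lognormal", 0.15, 0.25),
        "a_minus": ("lognormal", 0.02, 0.3),
        "tau_x": ("lognormal", 8.0, 0.2),
        "e_dc": ("normal", 0.0, 0.02),
        "noise_sd": ("fixed", 50e-9),
        **_DUCT_SC,
    },
    "offset_shift": {
        "g_min": ("lognormal", 6e-6, 0.4),
        "g_span": ("lognormal", 25e-6, 0.3),
        "x0": ("fixed", 0.4),
        "a_plus": ("lognormal", 0.1, 0.25),
        "a_minus": ("lognormal", 0.1, 0.25),
        "tau_x": ("lognormal", 8.0, 0.2),
        "e_dc": ("normal", 0.25, 0.05),
        "noise_sd": ("fixed", 50e-9),
        **{**_DUCT_SC, "c_s": ("lognormal", 30e-9, 0.2)},
    },
    # duct contact absent: current travels through the stratum corneum only
    "two_pinch": {
        "g_min": ("fixed", 0.0),
        "g_span": ("fixed", 0.0),
        "x0": ("fixed", 0.0),
        "a_plus": ("fixed", 0.0),
        "a_minus": ("fixed", 0.0),
        "tau_x": ("fixed", 1.0),
        "e_dc": ("normal", 0.0, 0.01),
        "noise_sd": ("fixed", 50e-9),
        "g_ref": ("lognormal", 3e-6, 0.2),
        "b_ntc": ("lognormal", 6000.0, 0.1),
        "t_ref": ("fixed", 306.0),
        "t_amb": ("fixed", 306.0),
        "c_th": ("fixed", 2.2e-6),
        "r_th": ("lognormal", 6.0e5, 0.15),
        "c_s": ("lognormal", 15.6e-9, 0.2),
    },
}


@dataclass(frozen=True)
class PopulationSpec:
    """Specification of a synthetic subject population.

    ``class_weights`` are mixture probabilities over the phenotype classes
    (must sum to 1); ``distributions`` give per-class parameter
    distributions (defaults packaged with the model, version
    :data:`PHENOTYPE_CONFIG_VERSION`).
    """

    n_subjects: int = 28
    class_weights: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))
    distributions: dict = field(default_factory=lambda: DEFAULT_CLASS_DISTRIBUTIONS)
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_subjects) != self.n_subjects or self.n_subjects < 1:
            raise InvalidSpecError(f"n_subjects must be a positive integer, got {self.n_subjects}")
        unknown = set(self.class_weights) - set(PHENOTYPE_CLASSES)
        if unknown:
            raise InvalidSpecError(f"unknown phenotype classes {sorted(unknown)}")
        w = np.array([self.class_weights.get(c, 0.0) for c in PHENOTYPE_CLASSES])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise InvalidSpecError(
                f"class weights must be non-negative and sum to 1 (got sum {w.sum():.12g})"
            )


@dataclass(frozen=True)
class SimulatedSubject:
    subject_id: str
    phenotype: str
    params: SkinCircuitParams


def _draw(dist: tuple, rng: np.random.Generator) -> float:
    kind = dist[0]
    if kind == "fixed":
        return float(dist[1])
    if kind == "lognormal":
        _, median, sigma = dist
        return float(median * np.exp(sigma * rng.standard_normal()))
    if kind == "normal":
        _, mu, sd = dist
        return float(rng.normal(mu, sd))
    raise InvalidSpecError(f"unknown distribution kind {kind!r}")


def sample_population(spec: PopulationSpec) -> list[SimulatedSubject]:
    """Draw a reproducible subject population from a :class:`PopulationSpec`."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    w = np.array([spec.class_weights.get(c, 0.0) for c in PHENOTYPE_CLASSES])
    classes = rng.choice(len(PHENOTYPE_CLASSES), size=spec.n_subjects, p=w / w.sum())
    subjects = []
    for k in range(spec.n_subjects):
        cls = PHENOTYPE_CLASSES[classes[k]]
        dists = spec.distributions[cls]
        d = {name: _draw(dists[name], rng) for name in dists}
        g_min = max(d["g_min"], 0.0)
        duct = SweatDuctParams(
            g_min=g_min, g_max=g_min + max(d["g_span"], 0.0),
            x0=min(max(d["x0"], 0.0), 1.0),
            a_plus=d["a_plus"], a_minus=d["a_minus"], tau_x=d["tau_x"],
        )
        sc = StratumCorneumParams(
            g_ref=d["g_ref"], b_ntc=d["b_ntc"], t_ref=d["t_ref"], t_amb=d["t_amb"],
            c_th=d["c_th"], r_th=d["r_th"], c_s=d["c_s"],
        )
        params = SkinCircuitParams(duct=duct, sc=sc, e_dc=d["e_dc"], noise_sd=d["noise_sd"])
        subjects.append(SimulatedSubject(subject_id=f"S{k:03d}", phenotype=cls, params=params))
    return subjects


def simulate_cohort(
    spec: PopulationSpec,
    grid: list[VoltageStimulus] | None = None,
    site: str = "forehead",
    carry_over: bool = False,
    substeps: int = 10,
) -> list[Recording]:
    """Simulate every (subject, stimulus) pair of a synthetic cohort.

    Returns recordings ordered subject-major (all stimuli of subject 0
    first).  State variables re-initialize to (x0, T_amb) for every stimulus
    by default; with ``carry_over=True`` the final state of each stimulus
    seeds the next one in grid order, emulating the after-effect a non-linear
    measurement has on subsequent recordings.
    """
    if grid is None:
        grid = experiment_grid()
    subjects = sample_population(spec)
    params = [s.params for s in subjects]
    ids = [s.subject_id for s in subjects]
    per_stim: list[list[Recording]] = []
    state = None
    for j, stim in enumerate(grid):
        seeds = [np.random.SeedSequence([spec.seed, k, j, 7]) for k in range(len(subjects))]
        recs, xs, Ts = simulate_batch(
            params, stim, seeds=seeds, substeps=substeps, subject_ids=ids, site=site,
            initial_states=state, return_states=True,
        )
        for k, rec in enumerate(recs):
            rec.meta.update(phenotype=subjects[k].phenotype, stimulus_index=j,
                            seed=[spec.seed, k, j, 7])
        per_stim.append(recs)
        if carry_over:
            state = (xs[:, -1], Ts[:, -1])
    return [per_stim[j][k] for k in range(len(subjects)) for j in range(len(grid))]
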
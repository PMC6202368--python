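"""Per-recording statistics of pinched hysteresis loops.

Implements every loop statistic used in the analysis:

* ``non_linearity`` — the DC-offset-robust non-linearity parameter
  ``NL = (i_max - i(0.5 v_max)) / (i(0.75 v_max) - i(0.5 v_max))``, with the
  two reference currents interpolated on the ascending-voltage branch in the
  first quadrant and ``i_max`` the global current maximum of the period.
  NL = 2 for a linear resistive response; state changes push it above 2, a
  capacitive phase lead pulls it below.
* ``lobe_area`` — total enclosed loop area (A1 + A2) by the stepwise
  |branch-difference| trapezoid method on a common voltage grid, with a
  polygon-decomposition fallback for self-looping branches.
* ``max_current`` — global current maximum and its phase angle within the
  period (the state keeps growing past the voltage peak, so the angle
  exceeds 90 degrees for memristive loops).
* ``detect_pinch_points`` — brute-force polyline self-intersection with
  clustering and a transversal/tangential classification from local branch
  slopes.
* ``phase_shift`` / ``state_dependent_phase_shift`` — the RC phase lead
  ``alpha = atan(2*pi*f*C/G)`` and its state-dependent generalization.
* ``lockin_admittance`` — in-phase/quadrature demodulation of a sinusoidal
  recording into conductance, susceptance and capacitance.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry
from .errors import (
    DegenerateLoopError,
    InsufficientDataError,
    InvalidIndexError,
    InvalidParameterError,
    InvalidPeriodError,
    UnsupportedStimulusError,
)
from .recording import Recording

__all__ = [
    "LoopMetrics",
    "PinchPoint",
    "AdmittanceMeasurement",
    "extract_period",
    "non_linearity",
    "lobe_area",
    "max_current",
    "detect_pinch_points",
    "phase_shift",
    "state_dependent_phase_shift",
    "lockin_admittance",
    "compute_loop_metrics",
    "analyze_recordings",
]

PERIODIC_KINDS = ("sinusoidal", "triangular")


@dataclass(frozen=True)
class PinchPoint:
    """One detected self-intersection of a V-I loop."""

    v: float
    i: float
    slope_a_deg: float
    slope_b_deg: float
    tangential: bool


@dataclass(frozen=True)
class AdmittanceMeasurement:
    """Lock-in result: conductance g, susceptance b (siemens), capacitance
    c = b / (2 pi f) (farads) at frequency f (hertz)."""

    g: float
    b: float
    c: float
    f: float

    def __post_init__(self) -> None:
        if self.f > 0 and not np.isclose(self.c, self.b / (2.0 * np.pi * self.f), rtol=1e-12):
            raise InvalidParameterError("capacitance inconsistent with susceptance and frequency")


@dataclass(frozen=True)
class LoopMetrics:
    """Per-period V-I statistics."""

    period_index: int
    nl: float
    lobe_area: float
    lobe_area_q1: float
    lobe_area_q3: float
    lobe_area_normalized: float
    i_max: float
    i_max_angle_deg: float
    pinch_points: tuple
    n_pinch: int
    q1_signed_area: float
    q3_signed_area: float
    tangential: bool | None


# ---------------------------------------------------------------------------


def extract_period(rec: Recording, period_index: int) -> Recording:
    """One period of a periodic recording, with time re-zeroed.

    ``period_index`` is 1-based; the analysis conventionally uses period 3,
    by which the loop shape has stabilized.
    """
    stim = rec.stimulus
    if stim.kind not in PERIODIC_KINDS:
        raise UnsupportedStimulusError(
            f"period extraction requires a periodic stimulus, got {stim.kind!r}"
        )
    if not (1 <= period_index <= stim.periods):
        raise InvalidIndexError(
            f"period_index {period_index} outside recorded range 1..{stim.periods}"
        )
    spp = stim.samples_per_period
    lo = (period_index - 1) * spp
    hi = period_index * spp
    return Recording(
        subject_id=rec.subject_id, site=rec.site, stimulus=stim,
        t=rec.t[lo:hi] - rec.t[lo], v=rec.v[lo:hi], i=rec.i[lo:hi],
        meta={**rec.meta, "period_index": period_index},
    )


def _signed(rec: Recording) -> tuple[np.ndarray, np.ndarray]:
    """Voltage and current multiplied by the stimulus sign, so the analysed
    half-cycle is always the positive one."""
    s = rec.stimulus.sign
    return s * rec.v, s * rec.i


def non_linearity(
    period: Recording, v_max: float | None = None, denom_floor: float = 1e-12
) -> float:
    """Non-linearity parameter NL of one period.

    ``i(0.5 v_max)`` and ``i(0.75 v_max)`` are linearly interpolated on the
    ascending-voltage branch within the first quadrant; ``i_max`` is the
    global maximum of the current over the period (preferred over
    ``i(v_max)`` because the memristive state keeps changing past the voltage
    peak).  A strictly linear in-phase response gives exactly 2.
    """
    v, i = _signed(period)
    if v_max is None:
        v_max = period.stimulus.amplitude
    i_max = float(np.max(i))
    apex = int(np.argmax(v))
    if apex < 1:
        raise InvalidPeriodError("period does not start on the ascending-voltage branch")
    bv, bi = v[: apex + 1], i[: apex + 1]
    mask = bv >= 0.0
    bv, bi = bv[mask], bi[mask]
    if len(bv) < 2 or np.max(bv) < 0.75 * v_max - 1e-12:
        raise InvalidPeriodError(
            "ascending branch never reaches 0.75 of the voltage amplitude"
        )
    order = np.argsort(bv, kind="stable")
    i_half, i_three_q = np.interp([0.5 * v_max, 0.75 * v_max], bv[order], bi[order])
    denom = i_three_q - i_half
    if abs(denom) < denom_floor:
        raise DegenerateLoopError(
            f"NL denominator {denom:.3e} A below floor {denom_floor:.1e} A"
        )
    return (i_max - i_half) / denom


# ---------------------------------------------------------------------------


def _circular_chain(n: int, start: int, stop: int) -> np.ndarray:
    """Indices start..stop walking forward around a circular array."""
    return np.arange(start, start + ((stop - start) % n) + 1) % n


def lobe_area(
    period: Recording, grid: int = 500
) -> tuple[float, tuple[float, float]]:
    """Total lobe area of a closed V-I loop and its split by voltage sign.

    Splits the loop at the two voltage extrema into an ascending and a
    descending branch, resamples both onto a common uniform voltage grid and
    accumulates the per-step absolute trapezoid-area differences; the result
    is the geometric loop area (A1 + A2), counted positively in both lobes.

    Returns ``(a_total, (a_pos, a_neg))`` in ampere-volts, where ``a_pos`` is
    the contribution from the v >= 0 region (A1) and ``a_neg`` from v < 0
    (A2).  If a branch is not monotone in voltage (a self-looping artifact),
    the method falls back to polygon decomposition with a warning.
    """
    v, i = _signed(period)
    n = len(v)
    hi_idx = int(np.argmax(v))
    lo_idx = int(np.argmin(v))
    asc = _circular_chain(n, lo_idx, hi_idx)
    desc = _circular_chain(n, hi_idx, lo_idx)
    vr = float(np.ptp(v)) or 1.0

    def branch(idx):
        bv, bi = v[idx], i[idx]
        monotone = np.all(np.diff(bv) >= -1e-9 * vr)
        return bv, bi, monotone

    av, ai, a_ok = branch(asc)
    dv_, di_, d_ok = branch(desc[::-1])  # reverse so voltage ascends
    if not (a_ok and d_ok):
        warnings.warn(
            "non-monotone voltage branch; falling back to polygon decomposition",
            RuntimeWarning, stacklevel=2,
        )
        loops = geometry.simple_loops(v, i)
        a_pos = a_neg = 0.0
        for lx, ly in loops:
            a = abs(geometry.shoelace_area(lx, ly))
            if float(np.mean(lx)) >= 0.0:
                a_pos += a
            else:
                a_neg += a
        return a_pos + a_neg, (a_pos, a_neg)

    lo = max(av[0], dv_[0])
    hi = min(av[-1], dv_[-1])
    nodes = np.linspace(lo, hi, grid + 1)
    ia = np.interp(nodes, av, ai)
    id_ = np.interp(nodes, dv_, di_)
    dv_step = np.diff(nodes)
    trap_a = 0.5 * (ia[:-1] + ia[1:]) * dv_step
    trap_d = 0.5 * (id_[:-1] + id_[1:]) * dv_step
    contrib = np.abs(trap_a - trap_d)
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    a_pos = float(np.sum(contrib[mid >= 0.0]))
    a_neg = float(np.sum(contrib[mid < 0.0]))
    return a_pos + a_neg, (a_pos, a_neg)


def max_current(period: Recording) -> tuple[float, float]:
    """Global maximum of the (sign-corrected) current and its phase angle.

    The angle is ``360 * t / T`` degrees within the period; ties break to the
    earliest sample.  For memristive loops the maximum falls after the
    voltage peak (angle > 90 degrees).
    """
    _, i = _signed(period)
    idx = int(np.argmax(i))  # argmax returns the earliest maximum
    return float(i[idx]), 360.0 * idx / len(i)


def _local_slope_deg(v, i, seg, window, vr, ir, n):
    idx = np.arange(seg - window, seg + window + 2) % n
    coeff = np.polyfit(v[idx] / vr, i[idx] / ir, 1)
    return float(np.degrees(np.arctan(coeff[0])))


def detect_pinch_points(
    period: Recording,
    merge_frac: float = 0.01,
    slope_window: int = 5,
    tangential_tol_deg: float = 15.0,
) -> list[PinchPoint]:
    """Self-intersections (pinch points) of the closed V-I polyline.

    Brute-force segment-pair intersection; intersections closer than
    ``merge_frac`` of the per-axis data range are clustered into one pinch.
    Branch slopes at each pinch are estimated by a local linear fit over
    +/- ``slope_window`` samples (in range-normalized coordinates); a pinch
    is *tangential* when the two slopes agree within
    ``tangential_tol_deg`` degrees of arc, *transversal* otherwise.
    """
    v, i = period.v, period.i
    n = len(v)
    if n < 8:
        raise InsufficientDataError(f"need >= 8 samples for pinch detection, got {n}")
    vr = float(np.ptp(v)) or 1.0
    ir = float(np.ptp(i)) or 1.0
    # intersect in range-normalized coordinates: the geometric epsilons are
    # then scale-free, and pinches sitting exactly on a sample vertex (a loop
    # through the origin at a zero crossing) are caught by the endpoint
    # tolerance.
    hits = geometry.segment_intersections(v / vr, i / ir, endpoint_tol=1e-9)
    if not hits:
        return []
    clusters: list[dict] = []
    for (px, py, a, b, _, _) in hits:
        px, py = px * vr, py * ir
        for cl in clusters:
            cx, cy = np.mean(cl["px"]), np.mean(cl["py"])
            if abs(px - cx) <= merge_frac * vr and abs(py - cy) <= merge_frac * ir:
                cl["px"].append(px)
                cl["py"].append(py)
                break
        else:
            clusters.append({"px": [px], "py": [py], "seg_a": a, "seg_b": b})
    out = []
    for cl in clusters:
        sa = _local_slope_deg(v, i, cl["seg_a"], slope_window, vr, ir, n)
        sb = _local_slope_deg(v, i, cl["seg_b"], slope_window, vr, ir, n)
        d = abs(sa - sb) % 180.0
        d = min(d, 180.0 - d)
        out.append(
            PinchPoint(
                v=float(np.mean(cl["px"])), i=float(np.mean(cl["py"])),
                slope_a_deg=sa, slope_b_deg=sb,
                tangential=bool(d <= tangential_tol_deg),
            )
        )
    return out


# ---------------------------------------------------------------------------


def phase_shift(g: float, c: float, f: float) -> float:
    """RC phase lead ``alpha = atan(2*pi*f*C/G)`` in degrees."""
    if g <= 0:
        raise InvalidParameterError(f"conductance must be > 0 S, got {g}")
    if c < 0 or f < 0:
        raise InvalidParameterError("capacitance and frequency must be >= 0")
    return float(np.degrees(np.arctan(2.0 * np.pi * f * c / g)))


def state_dependent_phase_shift(g_of_state, c: float, f: float, states) -> np.ndarray:
    """Elementwise phase lead along a state trajectory:
    ``alpha(x, T) = atan(2*pi*f*C / G(x, T))`` in degrees."""
    g = np.asarray(g_of_state(states), dtype=float)
    if np.any(g <= 0):
        raise InvalidParameterError("state-dependent conductance must be > 0 S everywhere")
    if c < 0 or f < 0:
        raise InvalidParameterError("capacitance and frequency must be >= 0")
    return np.degrees(np.arctan(2.0 * np.pi * f * c / g))


def lockin_admittance(rec: Recording) -> AdmittanceMeasurement:
    """Demodulate a sinusoidal recording into conductance and susceptance.

    In-phase and quadrature references at the stimulus frequency are averaged
    over whole periods: ``g = 2 <i sin> / A``, ``b = 2 <i cos> / A``,
    ``c = b / (2 pi f)``.  A non-integer period count is truncated to whole
    periods with a warning.
    """
    stim = rec.stimulus
    if stim.kind != "sinusoidal":
        raise UnsupportedStimulusError("lock-in demodulation requires a sinusoidal stimulus")
    spp = stim.samples_per_period
    n_whole = (len(rec) // spp) * spp
    if n_whole == 0:
        raise InsufficientDataError("recording shorter than one period")
    if n_whole != len(rec):
        warnings.warn(
            f"truncating {len(rec) - n_whole} samples to a whole number of periods",
            RuntimeWarning, stacklevel=2,
        )
    t = rec.t[:n_whole] - rec.t[0]
    i = rec.i[:n_whole]
    w = 2.0 * np.pi * stim.frequency
    ref_sin = stim.sign * np.sin(w * t)
    ref_cos = stim.sign * np.cos(w * t)
    g = 2.0 * float(np.mean(i * ref_sin)) / stim.amplitude
    b = 2.0 * float(np.mean(i * ref_cos)) / stim.amplitude
    return AdmittanceMeasurement(g=g, b=b, c=b / w, f=stim.frequency)


# ---------------------------------------------------------------------------
# aggregation over recordings


def _signed_quadrant_areas(period: Recording) -> tuple[float, float]:
    """Signed (shoelace) areas of the v >= 0 and v < 0 sub-loops.

    Counter-clockwise traversal gives a positive sign; memristive loops are
    counter-clockwise in the first quadrant and clockwise in the third.
    """
    v, i = period.v, period.i
    n = len(v)
    mask = v >= 0.0

    def longest_run(m):
        if m.all():
            return np.arange(n)
        if not m.any():
            return np.array([], dtype=int)
        # circular runs: rotate so a False sits at position 0
        start = int(np.argmin(m))
        rot = np.roll(m, -start)
        idx = np.arange(n)
        best, cur = [], []
        for j in range(n):
            if rot[j]:
                cur.append((j + start) % n)
            else:
                if len(cur) > len(best):
                    best = cur
                cur = []
        if len(cur) > len(best):
            best = cur
        return np.asarray(best, dtype=int)

    q1 = longest_run(mask)
    q3 = longest_run(~mask)
    a1 = geometry.shoelace_area(v[q1], i[q1]) if len(q1) >= 3 else 0.0
    a3 = geometry.shoelace_area(v[q3], i[q3]) if len(q3) >= 3 else 0.0
    return float(a1), float(a3)


def compute_loop_metrics(rec: Recording, period_index: int = 3) -> LoopMetrics:
    """All per-period loop statistics for one recording.

    NL is reported as NaN when the loop is degenerate for the NL definition
    (vanishing denominator or an ascending branch that never reaches
    0.75 v_max); all geometric statistics are still computed.
    """
    period = extract_period(rec, period_index)
    try:
        nl = non_linearity(period)
    except (DegenerateLoopError, InvalidPeriodError):
        nl = float("nan")
    a_total, (a1, a3) = lobe_area(period)
    i_max, angle = max_current(period)
    pinches = detect_pinch_points(period)
    q1, q3 = _signed_quadrant_areas(period)
    tang: bool | None = None
    if pinches:
        tang = all(p.tangential for p in pinches)
    return LoopMetrics(
        period_index=period_index, nl=nl,
        lobe_area=a_total, lobe_area_q1=a1, lobe_area_q3=a3,
        lobe_area_normalized=a_total / i_max if i_max > 0 else float("nan"),
        i_max=i_max, i_max_angle_deg=angle,
        pinch_points=tuple(pinches), n_pinch=len(pinches),
        q1_signed_area=q1, q3_signed_area=q3, tangential=tang,
    )


def analyze_recordings(
    recordings, periods=(3,), skip_nonperiodic: bool = True
) -> pd.DataFrame:
    """Loop metrics for a set of recordings as a flat table.

    One row per recording x period.  Recordings with a non-periodic stimulus
    kind (decaying sinusoid) carry no per-period statistics and are skipped.
    """
    rows = []
    for rec in recordings:
        if rec.stimulus.kind not in PERIODIC_KINDS:
            if skip_nonperiodic:
                continue
            raise UnsupportedStimulusError(
                f"recording {rec.subject_id} has non-periodic kind {rec.stimulus.kind!r}"
            )
        for p in periods:
            lm = compute_loop_metrics(rec, period_index=p)
            rows.append({
                "subject_id": rec.subject_id,
                "site": rec.site,
                "kind": rec.stimulus.kind,
                "amplitude": rec.stimulus.amplitude,
                "frequency": rec.stimulus.frequency,
                "sign": rec.stimulus.sign,
                "phenotype": rec.meta.get("phenotype"),
                "period": p,
                "nl": lm.nl,
                "lobe_area": lm.lobe_area,
                "lobe_area_q1": lm.lobe_area_q1,
                "lobe_area_q3": lm.lobe_area_q3,
                "lobe_area_normalized": lm.lobe_area_normalized,
                "i_max": lm.i_max,
                "i_max_angle_deg": lm.i_max_angle_deg,
                "n_pinch": lm.n_pinch,
                "tangential": lm.tangential,
                "q1_signed_area": lm.q1_signed_area,
                "q3_signed_area": lm.q3_signed_area,
            })
    return pd.DataFrame(rows)
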
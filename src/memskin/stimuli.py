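"""Voltage excitation waveforms and the 30-stimulus experimental grid.

The measurement protocol applies five voltage stimulus types (sinusoids at
0.4, 0.8 and 1.2 V amplitude, a triangular wave and a non-periodic decaying
sinusoid, both at 1.2 V) at six frequencies between 0.05 Hz and 2.5 Hz, three
periods each, sampled at 500 samples per period.  Only the frequency
endpoints are fixed by the protocol; the intermediate frequencies default to
a 1-2-5 ladder and are exposed as configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "VoltageStimulus",
    "generate_waveform",
    "waveform_functions",
    "experiment_grid",
    "DEFAULT_FREQUENCIES_HZ",
    "DEFAULT_AMPLITUDES_V",
    "WAVEFORM_KINDS",
]

WAVEFORM_KINDS = ("sinusoidal", "triangular", "decaying_sine")

#: Six-point frequency sweep. The protocol prints only the endpoints
#: (0.05 Hz and 2.5 Hz) and a 0.25 Hz example; a 1-2.5-5 ladder fills the rest.
DEFAULT_FREQUENCIES_HZ: tuple[float, ...] = (0.05, 0.1, 0.25, 0.5, 1.0, 2.5)

#: Sinusoidal amplitude levels of the protocol.
DEFAULT_AMPLITUDES_V: tuple[float, ...] = (0.4, 0.8, 1.2)


@dataclass(frozen=True)
class VoltageStimulus:
    """A parameterized excitation waveform.

    Parameters
    ----------
    kind
        One of ``sinusoidal``, ``triangular`` or ``decaying_sine`` (a sinusoid
        under a decaying amplitude envelope, the protocol's "non-periodic"
        stimulus).
    amplitude
        Peak voltage in volts, > 0.
    frequency
        Fundamental frequency in hertz, > 0.
    periods
        Number of periods applied (default 3).
    samples_per_period
        Output sampling density (default 500).
    sign
        +1 or -1; the protocol randomizes the sign of each stimulus.
    envelope
        Envelope shape for ``decaying_sine``: ``linear`` (default) decays from
        1 at t = 0 to 0 at the end of the last period; ``exponential`` is a
        shifted exponential with the same endpoints.
    """

    kind: str
    amplitude: float
    frequency: float
    periods: int = 3
    samples_per_period: int = 500
    sign: int = 1
    envelope: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in WAVEFORM_KINDS:
            raise InvalidParameterError(
                f"unknown waveform kind {self.kind!r}; expected one of {WAVEFORM_KINDS}"
            )
        if not (self.amplitude > 0):
            raise InvalidParameterError(f"amplitude must be > 0 V, got {self.amplitude}")
        if not (self.frequency > 0):
            raise InvalidParameterError(f"frequency must be > 0 Hz, got {self.frequency}")
        if int(self.periods) != self.periods or self.periods < 1:
            raise InvalidParameterError(f"periods must be a positive integer, got {self.periods}")
        if int(self.samples_per_period) != self.samples_per_period or self.samples_per_period < 2:
            raise InvalidParameterError(
                f"samples_per_period must be an integer >= 2, got {self.samples_per_period}"
            )
        if self.sign not in (1, -1):
            raise InvalidParameterError(f"sign must be +1 or -1, got {self.sign}")
        if self.envelope not in ("linear", "exponential"):
            raise InvalidParameterError(f"unknown envelope {self.envelope!r}")

    @property
    def n_samples(self) -> int:
        return self.periods * self.samples_per_period

    @property
    def duration(self) -> float:
        """Total stimulus duration in seconds."""
        return self.periods / self.frequency

    @property
    def dt(self) -> float:
        """Sample spacing in seconds."""
        return 1.0 / (self.frequency * self.samples_per_period)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageStimulus":
        return cls(**d)


def waveform_functions(
    stim: VoltageStimulus,
) -> tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]]:
    """Return vectorized callables ``(v(t), dv/dt(t))`` for a stimulus.

    The analytic derivative is used by the circuit simulator for the
    capacitive current term, avoiding finite-difference noise.
    """
    A = stim.sign * stim.amplitude
    f = stim.frequency
    w = 2.0 * np.pi * f
    total = stim.duration

    if stim.kind == "sinusoidal":

        def v(t):
            return A * np.sin(w * np.asarray(t))

        def dv(t):
            return A * w * np.cos(w * np.asarray(t))

    elif stim.kind == "triangular":
        # zero-phase triangle: 0 at t=0, apex +A at T/4, -A at 3T/4
        def v(t):
            u = np.mod(f * np.asarray(t) + 0.25, 1.0)
            return A * (1.0 - 4.0 * np.abs(u - 0.5))

        def dv(t):
            u = np.mod(f * np.asarray(t) + 0.25, 1.0)
            return np.where(u < 0.5, 4.0 * A * f, -4.0 * A * f)

    else:  # decaying_sine
        if stim.envelope == "linear":

            def env(t):
                return 1.0 - np.asarray(t) / total

            def denv(t):
                return np.full_like(np.asarray(t, dtype=float), -1.0 / total)

        else:  # exponential, pinned to 0 at the end of the last period
            k = 3.0 / total
            c = np.exp(-k * total)

            def env(t):
                return (np.exp(-k * np.asarray(t)) - c) / (1.0 - c)

            def denv(t):
                return -k * np.exp(-k * np.asarray(t)) / (1.0 - c)

        def v(t):
            t = np.asarray(t)
            return A * np.sin(w * t) * env(t)

        def dv(t):
            t = np.asarray(t)
            return A * (w * np.cos(w * t) * env(t) + np.sin(w * t) * denv(t))

    return v, dv


def generate_waveform(stim: VoltageStimulus) -> tuple[np.ndarray, np.ndarray]:
    """Sample a stimulus on its native grid.

    Returns
    -------
    t : ndarray
        Times in seconds, starting at 0, uniform spacing
        ``1 / (frequency * samples_per_period)``.
    v : ndarray
        Voltage in volts, ``v[0] == 0`` for all kinds.
    """
    n = stim.n_samples
    t = np.arange(n) * stim.dt
    v_fn, _ = waveform_functions(stim)
    return t, v_fn(t)


def experiment_grid(
    amplitudes: Sequence[float] = DEFAULT_AMPLITUDES_V,
    frequencies: Sequence[float] = DEFAULT_FREQUENCIES_HZ,
    periods: int = 3,
    samples_per_period: int = 500,
    seed: int | None = None,
) -> list[VoltageStimulus]:
    """The full experimental stimulus grid.

    Five stimulus types (sinusoids at each amplitude level, triangular and
    decaying sinusoid at the largest level) crossed with the six-point
    frequency sweep: 30 stimuli by default.

    If ``seed`` is given, stimulus order is shuffled and each stimulus sign is
    randomized, mirroring the randomized protocol; the randomization has no
    effect on any computed statistic.
    """
    a_top = max(amplitudes)
    types: list[tuple[str, float]] = [("sinusoidal", a) for a in amplitudes]
    types += [("triangular", a_top), ("decaying_sine", a_top)]
    grid = [
        VoltageStimulus(kind=k, amplitude=a, frequency=f, periods=periods,
                        samples_per_period=samples_per_period)
        for (k, a) in types
        for f in frequencies
    ]
    if seed is not None:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(grid))
        signs = rng.choice([1, -1], size=len(grid))
        grid = [dataclasses.replace(grid[j], sign=int(signs[j])) for j in order]
    return grid
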
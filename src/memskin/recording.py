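"""The Recording container: one time/voltage/current triplet with metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .stimuli import VoltageStimulus

SITES = ("forehead", "earlobe", "fingertip")


@dataclass
class Recording:
    """A single voltage-current recording.

    The unit every analysis consumes: time in seconds (uniform grid), applied
    voltage in volts, measured current in amperes, plus subject / skin-site /
    stimulus metadata.
    """

    subject_id: str
    site: str
    stimulus: VoltageStimulus
    t: np.ndarray
    v: np.ndarray
    i: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.site not in SITES:
            raise InvalidParameterError(f"unknown site {self.site!r}; expected one of {SITES}")
        n = len(self.t)
        if not (len(self.v) == n and len(self.i) == n and n >= 2):
            raise InvalidParameterError("t, v, i must have equal length >= 2")
        dt = np.diff(self.t)
        if not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-8, atol=1e-15)):
            raise InvalidParameterError("time grid must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)
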
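"""Recording file format: CSV payload with a JSON metadata sidecar.

A recording is stored as ``<name>.csv`` with the fixed header
``time_s,voltage_V,current_A`` (17 significant digits, lossless for float64)
and ``<name>.json`` holding subject / site / stimulus metadata plus a
``schema_version``.  Unknown metadata keys round-trip with a warning so
newer writers stay readable.

Deposited real recordings can be converted into this format; the layout of
the public deposit is not standardized, so conversion is left to a small
user-written adapter producing these two files per recording.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .errors import FormatError
from .recording import Recording
from .stimuli import VoltageStimulus

__all__ = ["SCHEMA_VERSION", "write_recording", "read_recording"]

SCHEMA_VERSION = "1.0"
_HEADER = "time_s,voltage_V,current_A"
_KNOWN_KEYS = {"schema_version", "subject_id", "site", "stimulus", "extras"}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> tuple[Path, Path]:
    """Write a recording to ``path`` (.csv) plus its JSON sidecar.

    Arrays are written as decimal text at 17 significant digits, so parsing
    reproduces the float64 values bit-for-bit.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    data = np.column_stack([rec.t, rec.v, rec.i])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=_HEADER, comments="")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": rec.subject_id,
        "site": rec.site,
        "stimulus": rec.stimulus.to_dict(),
        "extras": {k: v for k, v in rec.meta.items() if k not in _KNOWN_KEYS},
    }
    side = _sidecar(path)
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
        fh.write("\n")
    return path, side


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises :class:`FormatError` on a schema mismatch, a wrong column header
    or a non-uniform time grid; a missing sidecar raises ``FileNotFoundError``
    naming the expected path.  Unknown metadata keys are preserved on
    ``Recording.meta`` with a warning.
    """
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing metadata sidecar: expected {side}")
    with open(side) as fh:
        meta = json.load(fh)
    version = meta.get("schema_version")
    if version is None:
        raise FormatError(f"{side}: no schema_version field")
    if version.split(".")[0] != SCHEMA_VERSION.split(".")[0]:
        raise FormatError(
            f"{side}: schema_version {version} incompatible with reader {SCHEMA_VERSION}"
        )
    with open(path) as fh:
        header = fh.readline().strip()
    if header != _HEADER:
        raise FormatError(f"{path}: expected header {_HEADER!r}, got {header!r}")
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.ndim != 2 or data.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns, got shape {data.shape}")
    t, v, i = data.T
    dt = np.diff(t)
    if len(t) < 2 or not (np.all(dt > 0) and np.allclose(dt, dt[0], rtol=1e-8, atol=1e-15)):
        raise FormatError(f"{path}: time grid not strictly increasing and uniform")
    unknown = {k: v_ for k, v_ in meta.items() if k not in _KNOWN_KEYS}
    if unknown:
        warnings.warn(
            f"{side}: preserving unknown metadata keys {sorted(unknown)}",
            RuntimeWarning, stacklevel=2,
        )
    extra = {**meta.get("extras", {}), **unknown}
    return Recording(
        subject_id=meta["subject_id"],
        site=meta["site"],
        stimulus=VoltageStimulus.from_dict(meta["stimulus"]),
        t=t, v=v, i=i, meta=extra,
    )
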
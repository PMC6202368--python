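"""Population-level aggregation of loop metrics.

The cohort pipeline mirrors the study's statistical analysis: noisy
recordings are excluded by amplitude-specific maximum-current thresholds,
lobe area and maximum current are log10-transformed, each (site, waveform,
amplitude, frequency) group is summarized by mean / median / 5% / 95%
percentiles, the non-linearity parameter is modelled by a random-intercept
linear mixed model ``NL ~ 1 + |amplitude| + log2(frequency)``, and the
linear/non-linear boundary in the amplitude-frequency plane is the smallest
amplitude whose group NL statistic exceeds a threshold (default 2.05).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidParameterError, RankDeficiencyError

__all__ = [
    "EXCLUSION_THRESHOLDS_A",
    "EXCLUSION_SLOPE_A_PER_V",
    "CohortSummary",
    "LmmFit",
    "BoundaryMap",
    "exclusion_filter",
    "summarize",
    "fit_nl_mixed_model",
    "boundary_map",
]

#: i_max exclusion thresholds (amperes) by sinusoidal amplitude (volts):
#: rows with i_max strictly below the threshold are dropped as noise.
EXCLUSION_THRESHOLDS_A: dict[float, float] = {1.2: 2.1e-6, 0.8: 1.4e-6, 0.4: 0.7e-6}

#: Fallback threshold slope for amplitude levels outside the protocol
#: (the tabulated thresholds all equal 1.75 uA per volt of amplitude).
EXCLUSION_SLOPE_A_PER_V = 1.75e-6

GROUP_KEYS = ["site", "kind", "amplitude", "frequency"]
SUMMARY_METRICS = ("log10_lobe_area", "log10_i_max", "nl")


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive statistics of one stimulus group."""

    site: str
    kind: str
    amplitude: float
    frequency: float
    n: int
    stats: dict = field(default_factory=dict)  # metric -> {mean, median, p5, p95}


@dataclass(frozen=True)
class LmmFit:
    """Random-intercept mixed-model fit of the non-linearity parameter."""

    beta_intercept: float
    beta_amplitude: float
    beta_log2freq: float
    ci95_intercept: float
    ci95_amplitude: float
    ci95_log2freq: float
    random_intercept_var: float
    residual_var: float
    n_observations: int
    n_subjects: int
    converged: bool

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


@dataclass(frozen=True)
class BoundaryMap:
    """Per-frequency minimum amplitude at which the cohort is non-linear."""

    threshold: float
    rule: str
    boundary: dict  # frequency -> amplitude (volts) or None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frequency": list(self.boundary), "amplitude": list(self.boundary.values())}
        )


# ---------------------------------------------------------------------------


def exclusion_filter(
    rows: pd.DataFrame, thresholds: dict[float, float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows whose maximum current falls below the noise threshold.

    The threshold depends on the stimulus amplitude; rows exactly at the
    threshold are retained (the exclusion applies to currents *below* it).
    Amplitude levels without a tabulated threshold use the linear fallback
    ``1.75 uA/V * amplitude`` and are logged as such.

    Returns ``(kept, log)`` where ``log`` has one row per dropped recording
    with its group key and the threshold applied.
    """
    if thresholds is None:
        thresholds = EXCLUSION_THRESHOLDS_A
    if len(rows) == 0:
        return rows.copy(), pd.DataFrame(columns=list(rows.columns) + ["threshold"])

    def thr(a: float) -> float:
        for level, t in thresholds.items():
            if np.isclose(a, level):
                return t
        warnings.warn(
            f"no tabulated exclusion threshold for amplitude {a} V; "
            f"using {EXCLUSION_SLOPE_A_PER_V * a:.3e} A (1.75 uA/V)",
            RuntimeWarning, stacklevel=2,
        )
        return EXCLUSION_SLOPE_A_PER_V * a

    t = rows["amplitude"].map(thr)
    drop = rows["i_max"] < t
    log = rows.loc[drop].copy()
    log["threshold"] = t[drop]
    return rows.loc[~drop].copy(), log


def _percentile(values: np.ndarray, q: float) -> float:
    """Percentile by linear interpolation between order statistics."""
    return float(np.quantile(values, q / 100.0, method="linear"))


def summarize(rows: pd.DataFrame, group_keys=None) -> pd.DataFrame:
    """Groupwise cohort summary of log10 lobe area, log10 i_max and NL.

    One row per (site, kind, amplitude, frequency) group with n and, for
    each metric, mean / median / 5% / 95% percentiles (linear interpolation
    of order statistics).  Groups with n < 2 carry NaN percentiles and are
    flagged ``underpowered``.
    """
    if group_keys is None:
        group_keys = GROUP_KEYS
    df = rows.copy()
    with np.errstate(divide="ignore"):
        df["log10_lobe_area"] = np.log10(df["lobe_area"])
        df["log10_i_max"] = np.log10(df["i_max"])
    out = []
    for key, grp in df.groupby(group_keys, sort=True):
        row = dict(zip(group_keys, key))
        row["n"] = len(grp)
        row["underpowered"] = len(grp) < 2
        for m in SUMMARY_METRICS:
            vals = grp[m].dropna().to_numpy()
            if len(vals) == 0 or (len(vals) < 2):
                row[f"{m}_mean"] = float(vals[0]) if len(vals) else np.nan
                row[f"{m}_median"] = float(vals[0]) if len(vals) else np.nan
                row[f"{m}_p5"] = np.nan
                row[f"{m}_p95"] = np.nan
            else:
                row[f"{m}_mean"] = float(np.mean(vals))
                row[f"{m}_median"] = _percentile(vals, 50)
                row[f"{m}_p5"] = _percentile(vals, 5)
                row[f"{m}_p95"] = _percentile(vals, 95)
        out.append(row)
    return pd.DataFrame(out)


def fit_nl_mixed_model(rows: pd.DataFrame) -> LmmFit:
    """REML fit of ``NL ~ 1 + |amplitude| + log2(frequency)`` with a
    per-subject random intercept.

    Expects filtered period-3 sinusoidal rows with columns ``nl``,
    ``amplitude``, ``frequency`` and ``subject_id``.  The frequency
    coefficient is per doubling of frequency; the study convention quotes
    the NL increase per *bisection* (one halving), i.e. the negated
    coefficient.  95% CIs are Wald intervals on the fixed effects.
    """
    df = rows.dropna(subset=["nl"]).copy()
    n_subj = df["subject_id"].nunique()
    if n_subj < 2:
        raise RankDeficiencyError("need >= 2 subjects to separate the random intercept")
    if df["amplitude"].abs().round(12).nunique() < 2:
        raise RankDeficiencyError("amplitude factor has a single level; slope not identifiable")
    if df["frequency"].round(12).nunique() < 2:
        raise RankDeficiencyError("frequency factor has a single level; slope not identifiable")
    endog = df["nl"].to_numpy()
    exog = np.column_stack([
        np.ones(len(df)),
        df["amplitude"].abs().to_numpy(),
        np.log2(df["frequency"].to_numpy()),
    ])
    model = sm.MixedLM(endog, exog, groups=df["subject_id"].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(reml=True)
    ci = res.conf_int(alpha=0.05)
    half = (np.asarray(ci)[:3, 1] - np.asarray(ci)[:3, 0]) / 2.0
    return LmmFit(
        beta_intercept=float(res.fe_params[0]),
        beta_amplitude=float(res.fe_params[1]),
        beta_log2freq=float(res.fe_params[2]),
        ci95_intercept=float(half[0]),
        ci95_amplitude=float(half[1]),
        ci95_log2freq=float(half[2]),
        random_intercept_var=float(np.asarray(res.cov_re)[0, 0]),
        residual_var=float(res.scale),
        n_observations=int(len(df)),
        n_subjects=int(n_subj),
        converged=bool(res.converged),
    )


def boundary_map(
    summaries: pd.DataFrame, threshold: float = 2.05, rule: str = "median"
) -> BoundaryMap:
    """Linear/non-linear boundary in the amplitude-frequency plane.

    For each frequency, the smallest tested amplitude whose group NL
    statistic strictly exceeds ``threshold``; ``None`` where no amplitude
    qualifies.  ``rule='median'`` marks where the typical subject is
    non-linear; ``rule='p5-whisker'`` uses the lower (5%) whisker, i.e. the
    region where more than 95% of subjects are non-linear.
    """
    col = {"median": "nl_median", "p5-whisker": "nl_p5"}.get(rule)
    if col is None:
        raise InvalidParameterError(f"unknown boundary rule {rule!r}")
    freqs = sorted(summaries["frequency"].unique())
    amps = sorted(summaries["amplitude"].unique())
    cells = {(round(a, 12), round(f, 12)) for a, f in
             zip(summaries["amplitude"], summaries["frequency"])}
    if len(cells) < len(freqs) * len(amps):
        warnings.warn(
            "amplitude x frequency grid is not rectangular; missing cells "
            "treated as undefined", RuntimeWarning, stacklevel=2,
        )
    bnd: dict[float, float | None] = {}
    for f in freqs:
        sub = summaries[summaries["frequency"] == f]
        qualifying = sorted(sub.loc[sub[col] > threshold, "amplitude"])
        bnd[float(f)] = float(qualifying[0]) if qualifying else None
    return BoundaryMap(threshold=threshold, rule=rule, boundary=bnd)
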
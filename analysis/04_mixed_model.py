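"""Random-intercept mixed model of the non-linearity parameter.

Fits NL ~ 1 + |amplitude| + log2(frequency) with a per-subject random
intercept (REML) over the third-period sinusoidal recordings that survive
the noise exclusion, and reports the fixed effects with Wald 95% CIs.

Output: results/lmm_fit.json.
"""

from pathlib import Path

import pandas as pd

from memskin import exclusion_filter, fit_nl_mixed_model

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    df = pd.read_csv(ROOT / "results" / "loop_metrics.csv")
    rows = df[(df["kind"] == "sinusoidal") & (df["period"] == 3)]
    kept, _ = exclusion_filter(rows)
    fit = fit_nl_mixed_model(kept)
    fit.to_json(ROOT / "results" / "lmm_fit.json")

    print(f"n = {fit.n_observations} observations from {fit.n_subjects} subjects")
    print(f"NL increases by {fit.beta_amplitude:.3f} +/- {fit.ci95_amplitude:.3f} (95% CI) "
          "per volt of amplitude")
    print(f"each halving of the frequency changes NL by {-fit.beta_log2freq:.4f} "
          f"+/- {fit.ci95_log2freq:.4f} (95% CI)")
    print(f"random-intercept sd {fit.random_intercept_var ** 0.5:.3f}, "
          f"residual sd {fit.residual_var ** 0.5:.3f}")


if __name__ == "__main__":
    main()
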
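"""Delimit the linear vs non-linear measurement range.

From the cohort summary, finds per frequency the smallest tested amplitude
whose group NL statistic exceeds 2.05 - once with the median rule (the
typical subject is non-linear) and once with the 5%-whisker rule (more than
95% of subjects are non-linear).

Output: results/boundary_map.csv (one row per frequency and rule).
"""

from pathlib import Path

import pandas as pd

from memskin import boundary_map

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    summ = pd.read_csv(ROOT / "results" / "cohort_summary.csv")
    sin = summ[summ["kind"] == "sinusoidal"]
    frames = []
    for rule in ("median", "p5-whisker"):
        bm = boundary_map(sin, threshold=2.05, rule=rule)
        f = bm.to_frame()
        f["rule"] = rule
        frames.append(f)
        pretty = {fq: (a if a is not None else "-") for fq, a in bm.boundary.items()}
        print(f"{rule:>10} rule: minimum non-linear amplitude per frequency: {pretty}")
    pd.concat(frames).to_csv(ROOT / "results" / "boundary_map.csv", index=False)
    print("a sinusoid below the listed amplitude at each frequency can be "
          "considered a linear measurement for this cohort")


if __name__ == "__main__":
    main()
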
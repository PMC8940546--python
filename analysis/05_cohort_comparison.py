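#!/usr/bin/env python
"""Stable-versus-unstable cohort comparison on the synthetic cohort.

Reproduces the cohort analysis: demographic summaries, then pooled
two-independent-samples t-tests of the four bone-tunnel angles between the
stable (n=54) and unstable (n=36) groups at alpha = 0.05.
"""

from pathlib import Path

from kneemech import io_utils
from kneemech.cohort import categorical_breakdown, compare_cohort, summarize

ROOT = Path(__file__).resolve().parents[1] / "results"


def main():
    cohort = io_utils.read_csv(ROOT / "inputs" / "cohort.csv")

    print("demographics:")
    for group in ("stable", "unstable"):
        age = summarize(cohort, "age_years", group)
        sexes = categorical_breakdown(cohort, "sex", group)
        male_n, male_pct = sexes.get("male", (0, 0.0))
        print(f"  {group:9s} n={age.n:2d}  age {age.mean:.1f} +/- {age.sd:.1f}  "
              f"male {male_n} ({male_pct}%)")

    table = compare_cohort(cohort)
    io_utils.write_csv(table, ROOT / "cohort_comparison.csv")
    print("\nbone-tunnel angle comparison (pooled t, alpha = 0.05):")
    for _, row in table.iterrows():
        print(f"  {row.variable:20s} stable {row.mean_stable:5.2f} +/- {row.sd_stable:5.2f}  "
              f"unstable {row.mean_unstable:5.2f} +/- {row.sd_unstable:5.2f}  "
              f"t={row.t:5.2f}  p={row.p:.2e}  "
              f"{'significant' if row.significant else 'not significant'}")


if __name__ == "__main__":
    main()
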
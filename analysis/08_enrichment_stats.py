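#!/usr/bin/env python
"""Statistics over the stage outputs: the targeting-depletion resampling
Z-score (S-gene families vs the non-S-gene candidate pool) and a
chi-square test of origin label vs age class."""

import pandas as pd

from common import PIPELINE_DIR, TABLE_DIR, ensure_pipeline

from sgenes.stats import chi_square_test


def main():
    ensure_pipeline()
    stats = pd.read_csv(PIPELINE_DIR / "stats.tsv", sep="\t")
    rows = [tuple(r) for r in stats.itertuples(index=False)]
    for name, value in rows:
        print(f"{name}: {value}")

    ages = pd.read_csv(PIPELINE_DIR / "ages.tsv", sep="\t")
    profiles = pd.read_csv(PIPELINE_DIR / "origin_profiles.tsv", sep="\t")
    merged = ages.merge(profiles, on="family")
    merged["has_arc"] = merged.ratio_arc > 0.5
    table = pd.crosstab(merged.age_class, merged.has_arc)
    if table.shape[0] >= 2 and table.shape[1] >= 2 and (table > 0).all(None):
        res = chi_square_test(table.values, name="age_class x archaeal_origin")
        rows.append(("age_vs_archaeal_chi2", f"{res.chi2:.4f}"))
        rows.append(("age_vs_archaeal_p", f"{res.p_value:.4g}"))
        print(f"age class vs archaeal origin: chi2={res.chi2:.3f}, "
              f"p={res.p_value:.3g} (dof={res.dof})")
    else:
        print("age class vs archaeal origin: table degenerate, test skipped")
    pd.DataFrame(rows, columns=["statistic", "value"]).to_csv(
        TABLE_DIR / "enrichment.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
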
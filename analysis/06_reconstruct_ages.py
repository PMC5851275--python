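#!/usr/bin/env python
"""Map S-gene families onto the species tree, reconstruct gains and losses
under Dollo parsimony, and bin families into early (both Opimoda and
Diphoda), intermediate, and lineage-specific age classes."""

import pandas as pd

from common import PIPELINE_DIR, TABLE_DIR, ensure_pipeline


def main():
    ensure_pipeline()
    ages = pd.read_csv(PIPELINE_DIR / "ages.tsv", sep="\t")
    dollo = pd.read_csv(PIPELINE_DIR / "dollo.tsv", sep="\t")
    age_counts = ages.groupby("age_class").size().rename("n_families")
    age_counts.to_csv(TABLE_DIR / "age_counts.tsv", sep="\t")
    merged = ages.merge(dollo, on="family")
    merged.to_csv(TABLE_DIR / "family_ages.tsv", sep="\t", index=False)
    print("S-gene age classes:",
          ", ".join(f"{k}={v}" for k, v in age_counts.items()))
    print(f"mean Dollo losses per family: {dollo.n_losses.mean():.2f}")


if __name__ == "__main__":
    main()
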
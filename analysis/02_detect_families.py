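#!/usr/bin/env python
"""Cluster the all-vs-all similarity table into homology families
(E-value < 1e-5, identity >= 30%, mutual coverage >= 80%; connected
components) and select eukaryote-only candidate families with >= 3
species."""

import json

import pandas as pd

from common import PIPELINE_DIR, TABLE_DIR, ensure_pipeline


def main():
    ensure_pipeline()
    counts = json.loads((PIPELINE_DIR / "manifest.json").read_text())["counts"]
    fams = pd.read_csv(PIPELINE_DIR / "families.tsv", sep="\t")
    sizes = fams.groupby("family").size().value_counts().sort_index()
    table = sizes.rename("n_families").rename_axis("family_size").reset_index()
    table.to_csv(TABLE_DIR / "family_sizes.tsv", sep="\t", index=False)
    print(f"{counts['sequences']} sequences -> {counts['families']} homology "
          f"families, of which {counts['candidate_families']} are "
          "eukaryote-only candidates with >= 3 species")
    print(f"family-size spectrum written to {TABLE_DIR/'family_sizes.tsv'}")


if __name__ == "__main__":
    main()
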
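#!/usr/bin/env python
"""Decompose each S-gene into component families (70% reciprocal overlap,
merged to fixpoint) and assign archaeal / bacterial / prokaryotic /
eukaryotic origins from the ten best prokaryotic supporters; summarize
per-family origin profiles."""

import pandas as pd

from common import PIPELINE_DIR, TABLE_DIR, ensure_pipeline


def main():
    ensure_pipeline()
    comps = pd.read_csv(PIPELINE_DIR / "components.tsv", sep="\t")
    profiles = pd.read_csv(PIPELINE_DIR / "origin_profiles.tsv", sep="\t")
    origin_counts = comps.groupby("origin").size().rename("n_components")
    origin_counts.to_csv(TABLE_DIR / "component_origin_counts.tsv", sep="\t")
    label_counts = profiles.groupby("label").size().rename("n_families")
    label_counts.to_csv(TABLE_DIR / "origin_label_counts.tsv", sep="\t")
    print(f"{len(comps)} component families on "
          f"{comps.gene.nunique()} S-gene members")
    print("component origins:",
          ", ".join(f"{k}={v}" for k, v in origin_counts.items()))
    print("family origin labels:",
          ", ".join(f"{k}={v}" for k, v in label_counts.items()))


if __name__ == "__main__":
    main()
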
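#!/usr/bin/env python
"""Classify composite families against the prokaryotic datasets: full-length
homology -> pre-eukaryotic composite; no similarity -> eukaryotic
innovation; partial similarity only -> S-gene."""

import json

import pandas as pd

from common import PIPELINE_DIR, TABLE_DIR, ensure_pipeline


def main():
    ensure_pipeline()
    counts = json.loads((PIPELINE_DIR / "manifest.json").read_text())["counts"]
    classes = pd.read_csv(PIPELINE_DIR / "family_classes.tsv", sep="\t")
    funnel = classes.groupby("label").size().rename("n_families")
    funnel.to_csv(TABLE_DIR / "class_funnel.tsv", sep="\t")
    print(f"of {counts['composite_families']} composite families: "
          f"{counts['prok_full_families']} have full-length prokaryotic "
          f"homologs, {counts['euk_innovation_families']} are eukaryotic "
          f"innovations, {counts['sgene_families']} are S-genes")


if __name__ == "__main__":
    main()
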
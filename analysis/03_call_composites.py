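#!/usr/bin/env python
"""Flag chimeric genes by the triplet test (two non-family partial hits on
distinct regions, spans >= 30 aa, overlap <= 20 aa, neither full-length)
and call composite multidomain families by strict member majorities."""

import json

import pandas as pd

from common import PIPELINE_DIR, TABLE_DIR, ensure_pipeline


def main():
    ensure_pipeline()
    counts = json.loads((PIPELINE_DIR / "manifest.json").read_text())["counts"]
    calls = pd.read_csv(PIPELINE_DIR / "composite_families.tsv", sep="\t")
    calls.to_csv(TABLE_DIR / "composite_family_calls.tsv", sep="\t",
                 index=False)
    print(f"{counts['composite_genes']} genes carry triplet evidence of "
          f"chimerism; {counts['composite_families']} of "
          f"{counts['candidate_families']} candidate families pass both "
          "strict majorities (composite members and multidomain members)")


if __name__ == "__main__":
    main()
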
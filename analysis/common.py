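"""Shared plumbing for the numbered analysis scripts.

The study dataset lives under ``results/data`` (written by 01_simulate.py)
and every pipeline stage writes its TSVs under ``results/pipeline``.  The
stage computations all live in :mod:`sgenes`; scripts here only narrate
and tabulate.
"""

from __future__ import annotations

from pathlib import Path

REPO = Path(__file__).resolve().parent.parent
DATA_DIR = REPO / "results" / "data"
PIPELINE_DIR = REPO / "results" / "pipeline"
TABLE_DIR = REPO / "results" / "tables"

STUDY_SEED = 42

INPUT_FILES = {
    "hits": "hits.tsv", "hits_extended": "hits_extended.tsv",
    "taxa": "taxa.tsv", "taxa_extended": "taxa_extended.tsv",
    "tree": "tree.nwk", "domains": "domains.tsv", "operons": "operons.tsv",
    "introns": "introns.tsv", "targeting": "targeting.tsv",
    "fasta": "proteins.fasta",
}


def ensure_dataset():
    from sgenes.synthetic import SyntheticConfig, simulate_dataset

    if not (DATA_DIR / "hits.tsv").exists():
        simulate_dataset(SyntheticConfig(seed=STUDY_SEED), DATA_DIR)
    return DATA_DIR


def ensure_pipeline():
    """Run the full pipeline on the study dataset once; reuse its outputs."""
    from sgenes.pipeline import run_pipeline

    ensure_dataset()
    if not (PIPELINE_DIR / "manifest.json").exists():
        cfg = {
            "seed": STUDY_SEED,
            "inputs": {k: str(DATA_DIR / v) for k, v in INPUT_FILES.items()},
        }
        run_pipeline(cfg, PIPELINE_DIR)
    TABLE_DIR.mkdir(parents=True, exist_ok=True)
    return PIPELINE_DIR
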
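# sgenes — detection and evolutionary analysis of symbiogenetic genes

Eukaryotic genomes contain *S-genes* (symbiogenetic genes): chimeric
genes assembled within a eukaryotic lineage from at least one fragment
of prokaryotic ancestry, typically fused to fragments of other origins.
They are a distinct mode of evolutionary innovation — neither plain
vertical descent nor whole-gene transfer — and finding them requires a
long chain of sequence-comparison decisions.  This package implements
that chain as a tested, deterministic pipeline for people studying
eukaryogenesis, gene fusion, and domain-level gene origins:

1. **Families** — an undirected graph over all proteins with an edge
   when a local alignment has E < 1e-5, identity ≥ 30% and mutual
   coverage ≥ 80% (min over both partners of span/length); connected
   components are homology families; eukaryote-only families with ≥ 3
   species go forward.
2. **Composites** — gene C is chimeric when two genes outside C's family
   hit distinct regions of C (spans ≥ 30 aa, overlap ≤ 20 aa, neither
   full-length); a family is composite when strict majorities of members
   are chimeric and multidomain.
3. **Classes** — against a prokaryotic search set: full-length homology
   (coverage ≥ 0.8) ⇒ `PROK_FULL`; no similarity ⇒ `EUK_INNOVATION`;
   partial similarity only ⇒ `S_GENE`; plus an HMM-profile
   rescue/removal filter and a curated exclusion list.
4. **Components & origins** — partial hits on each S-gene are clustered
   (70% reciprocal overlap, merged to fixpoint) into component families;
   the ten best prokaryotic supporters vote an origin (ARC / BAC /
   PROK / EUK), and per-family origin profiles get labels like BAC-EUK.
5. **Ages** — Dollo parsimony (single gain at the MRCA, minimal losses)
   on a rooted species tree whose deepest split separates Opimoda from
   Diphoda; families present on both sides are *early* (pre-LECA
   candidates); gene-tree bipartitions (support ≥ 85) are screened for
   supergroup mixing.
6. **Corroboration** — operon-like composites (two components supported
   by two genes sharing one prokaryotic operon) and introns conserved
   between Opimoda and Diphoda within ±20 aa of component borders.
7. **Statistics** — chi-square enrichment with Benjamini–Hochberg
   adjustment, a seeded resampling Z-score for targeting
   depletion/enrichment, and PPI-degree/essentiality summaries.

Because real datasets at this scale cannot ship with a package, a
first-class synthetic generator (`sgenes.synthetic`) plants ground-truth
chimeras — S-genes with known component layouts, full-length transfers,
eukaryotic innovations, operon-derived fusions, conserved introns, and
known gain nodes — so every stage is verifiable end to end.  See
`docs/methods.md` for the model, its assumptions, and what passing these
tests does and does not show.

## Worked example

The numbered scripts under `analysis/` run the whole study; each is a
thin driver over the library and writes tables under `results/`.

```bash
cd analysis
python 01_simulate.py
python 02_detect_families.py
python 04_classify_sgenes.py
python 06_reconstruct_ages.py
```

prints

```
wrote .../results/data
  1395 sequences in the clustering dataset (30 extended prokaryotic sequences)
  planted families: 30 S-genes, 10 full-length transfers, 10 innovations, 108 single-domain families
  5 operon-derived fusions, 5 conserved-intron families
1395 sequences -> 148 homology families, of which 62 are eukaryote-only candidates with >= 3 species
of 50 composite families: 10 have full-length prokaryotic homologs, 10 are eukaryotic innovations, 30 are S-genes
S-gene age classes: EARLY=17, INTERMEDIATE=4, LINEAGE_SPECIFIC=9
mean Dollo losses per family: 0.17
```

Reading: of 148 homology families, 62 are eukaryote-only candidates and
50 pass the composite test; classification recovers exactly the planted
30/10/10 split, and the 30 S-gene families date to 17 early (present in
both Opimoda and Diphoda, i.e. pre-LECA candidates), 4 intermediate and
9 lineage-specific origins.  Scripts 05, 07 and 08 add component-origin
profiles, operon/intron corroboration (5 + 5 planted, 5 + 5 recovered)
and the enrichment statistics.

The same run is available programmatically:

```python
from sgenes.pipeline import run_pipeline
manifest = run_pipeline({"seed": 42, "synthetic": {"seed": 42}}, "out/")
print(manifest.counts)
```

or from explicit input files (BLAST outfmt-6 hits, taxon table, Newick
tree, annotation TSVs) via the `inputs:` block of the same config — the
column schemas are documented in `sgenes/io_formats.py` and enforced at
parse time.

## Layout

```
src/sgenes/        the library: io_formats, tree, synthetic, families,
                   composites, classify, components, ancestry, evidence,
                   stats, pipeline
analysis/          numbered study scripts (thin drivers, write results/)
tests/             pytest suite incl. brute-force oracles
scripts/           acceptance.py
docs/methods.md    model, assumptions, numerical choices, limitations
```
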
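"""End-to-end orchestration: families -> composites -> classes -> components
-> ages -> evidence -> stats, with a machine-readable run manifest.

The config is a declarative mapping (YAML file or dict) with either a
``synthetic`` block (a :class:`~sgenes.synthetic.SyntheticConfig`) or an
``inputs`` block of file paths, plus optional ``thresholds`` overrides.
Every stage is a pure function of inputs + config + seed, so deleting the
output directory and re-running reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .ancestry import age_class, build_presence_matrix, dollo_all
from .classify import (
    S_GENE,
    EUK_INNOVATION,
    PROK_FULL,
    apply_exclusions,
    apply_profile_filter,
    classify_family,
    parse_profile_hits,
    prokaryotic_hits_by_gene,
)
from .components import (
    ComponentFamily,
    assign_origins,
    cluster_component_instances,
    conservative_reassign,
    extract_component_instances,
    family_origin_profile,
    label_origin_profiles,
    merge_component_families,
)
from .composites import (
    annotate_multidomain,
    call_composite_families,
    detect_triplet_composites,
    incident_records,
)
from .evidence import (
    component_borders,
    conserved_introns,
    detect_operon_like,
    family_targeting,
    operon_like_families,
)
from .families import (
    Thresholds,
    build_family_graph,
    extract_families,
    family_of_map,
    select_candidate_families,
)
from .io_formats import (
    parse_domain_table,
    parse_hit_table,
    parse_intron_table,
    parse_operon_table,
    parse_targeting_table,
    parse_taxon_table,
    read_fasta,
    write_tsv,
)
from .stats import resampling_zscore
from .synthetic import SyntheticConfig, simulate_dataset
from .tree import parse_species_tree

log = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    counts: dict[str, int]
    seed: int
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(source: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    if "synthetic" not in cfg and "inputs" not in cfg:
        raise ValueError("config needs a 'synthetic' block or an 'inputs' block")
    return cfg


def _thresholds(cfg: Mapping[str, Any]) -> Thresholds:
    return Thresholds(**cfg.get("thresholds", {}))


def run_pipeline(config: str | Path | Mapping[str, Any],
                 outdir: str | Path) -> RunManifest:
    """Run every stage and write per-stage TSVs plus ``manifest.json``."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t = _thresholds(cfg)
    seed = int(cfg.get("seed", 0))

    # --- stage 0: inputs ---------------------------------------------------
    if "synthetic" in cfg:
        syn = dict(cfg["synthetic"])
        if "domain_length_range" in syn:
            syn["domain_length_range"] = tuple(syn["domain_length_range"])
        syn.setdefault("seed", seed)
        datadir = outdir / "data"
        simulate_dataset(SyntheticConfig(**syn), datadir)
        inputs = {
            "hits": datadir / "hits.tsv",
            "hits_extended": datadir / "hits_extended.tsv",
            "taxa": datadir / "taxa.tsv",
            "taxa_extended": datadir / "taxa_extended.tsv",
            "tree": datadir / "tree.nwk",
            "domains": datadir / "domains.tsv",
            "operons": datadir / "operons.tsv",
            "introns": datadir / "introns.tsv",
            "targeting": datadir / "targeting.tsv",
            "fasta": datadir / "proteins.fasta",
        }
    else:
        inputs = {k: Path(v) for k, v in cfg["inputs"].items()}

    taxa = parse_taxon_table(inputs["taxa"])
    taxa_all = dict(taxa)
    if "taxa_extended" in inputs:
        taxa_all.update(parse_taxon_table(inputs["taxa_extended"]))
    hits = parse_hit_table(inputs["hits"])
    hits_extended = (parse_hit_table(inputs["hits_extended"])
                     if "hits_extended" in inputs else [])
    tree = parse_species_tree(inputs["tree"], taxa)
    domains = (parse_domain_table(inputs["domains"], taxa_all)
               if "domains" in inputs else {})
    operons = parse_operon_table(inputs["operons"]) if "operons" in inputs else []
    introns = (parse_intron_table(inputs["introns"], taxa)
               if "introns" in inputs else {})
    targeting = (parse_targeting_table(inputs["targeting"])
                 if "targeting" in inputs else {})
    profile_hits = (parse_profile_hits(inputs["profile_hits"])
                    if "profile_hits" in inputs else [])
    excluded_ids = []
    if "exclude" in inputs:
        with open(inputs["exclude"]) as fh:
            excluded_ids = [line.strip() for line in fh
                            if line.strip() and not line.startswith("#")]

    digests = {name: _sha256(path) for name, path in sorted(inputs.items())}

    # --- stage 1: families -------------------------------------------------
    graph = build_family_graph(hits, taxa, t)
    families = extract_families(graph, taxa)
    fam_by_id = {f.id: f for f in families}
    family_of = family_of_map(families)
    candidates = select_candidate_families(families, taxa, t)
    write_tsv(outdir / "families.tsv", ["family", "gene"],
              [(f.id, m) for f in families for m in sorted(f.members)])
    write_tsv(outdir / "candidate_families.tsv",
              ["family", "n_members", "n_euk_species"],
              [(f.id, len(f.members), f.n_euk_species) for f in candidates])

    # --- stage 2: composites -----------------------------------------------
    triplets = detect_triplet_composites(hits, taxa, t, family_of)
    multidomain = annotate_multidomain(domains)
    calls = call_composite_families(candidates, triplets, multidomain, t)
    composite_calls = [c for c in calls if c.is_composite_family]
    write_tsv(outdir / "composite_genes.tsv", ["gene", "n_triplets"],
              [(g, len(ev)) for g, ev in sorted(triplets.items())])
    write_tsv(outdir / "triplets.tsv",
              ["composite", "component_a", "component_b", "span_a", "span_b",
               "overlap_aa"],
              [(e.composite, e.component_a, e.component_b,
                f"{e.span_a[0]}-{e.span_a[1]}", f"{e.span_b[0]}-{e.span_b[1]}",
                e.overlap_aa)
               for evs in (triplets[g] for g in sorted(triplets))
               for e in evs])
    write_tsv(outdir / "composite_families.tsv",
              ["family", "fraction_composite", "fraction_multidomain",
               "is_composite_family"],
              [(c.family_id, f"{c.fraction_composite:.4f}",
                f"{c.fraction_multidomain:.4f}", int(c.is_composite_family))
               for c in calls])

    # --- stage 3: classification -------------------------------------------
    prok_hits = prokaryotic_hits_by_gene(list(hits) + hits_extended, taxa_all)
    labels = [classify_family(fam_by_id[c.family_id], prok_hits, taxa_all, t)
              for c in composite_calls]
    labels, reclass_log = apply_profile_filter(labels, profile_hits, t)
    labels, removed = apply_exclusions(labels, excluded_ids)
    label_of = {lab.family_id: lab.label for lab in labels}
    write_tsv(outdir / "family_classes.tsv", ["family", "label"],
              sorted(label_of.items()))
    write_tsv(outdir / "reclassifications.tsv",
              ["family", "old_label", "new_label", "profile_target"],
              [(r.family_id, r.old_label, r.new_label, r.profile_hit.target)
               for r in reclass_log])

    # --- stage 4: components on S-genes ------------------------------------
    sgene_ids = sorted(f for f, lab in label_of.items() if lab == S_GENE)
    incident = incident_records(hits, taxa)
    components_by_gene: dict[str, list[ComponentFamily]] = {}
    mode = cfg.get("component_mode", "standard")
    for fam_id in sgene_ids:
        for gene in sorted(fam_by_id[fam_id].members):
            inst = extract_component_instances(gene, incident, taxa, t,
                                               family_of)
            comps = merge_component_families(
                cluster_component_instances(inst, t), t)
            comps = assign_origins(comps, t)
            if mode == "conservative":
                comps = conservative_reassign(comps, domains)
            components_by_gene[gene] = comps
    profiles = [family_origin_profile(fam_id,
                                      sorted(fam_by_id[fam_id].members),
                                      components_by_gene)
                for fam_id in sgene_ids]
    profiles = label_origin_profiles(profiles, method="rule", t=t)
    write_tsv(outdir / "components.tsv",
              ["gene", "component", "start", "end", "origin", "n_supporters"],
              [(g, c.id, c.representative[0], c.representative[1], c.origin,
                len(c.supporters))
               for g in sorted(components_by_gene)
               for c in components_by_gene[g]])
    write_tsv(outdir / "origin_profiles.tsv",
              ["family", "ratio_euk", "ratio_arc", "ratio_bac", "ratio_prok",
               "label"],
              [(p.family_id, *(f"{p.ratios[o]:.4f}"
                               for o in ("EUK", "ARC", "BAC", "PROK")),
                p.label)
               for p in profiles])

    # --- stage 5: ages -----------------------------------------------------
    sg_families = [fam_by_id[f] for f in sgene_ids]
    ages: dict[str, str] = {}
    dollo_rows = []
    if sg_families:
        presence = build_presence_matrix(sg_families, taxa, tree)
        for res in dollo_all(tree, presence):
            dollo_rows.append((res.family_id, res.gain_node, res.n_losses,
                               ",".join(sorted(res.loss_edges))))
        ages = {f: age_class(presence.loc[f].to_dict(), tree)
                for f in presence.index}
    write_tsv(outdir / "dollo.tsv", ["family", "gain_node", "n_losses",
                                     "loss_edges"], dollo_rows)
    write_tsv(outdir / "ages.tsv", ["family", "age_class"],
              sorted(ages.items()))

    # --- stage 6: auxiliary evidence ---------------------------------------
    operon_ev = detect_operon_like(components_by_gene, operons, family_of)
    operon_fams = operon_like_families(operon_ev)
    write_tsv(outdir / "operon_evidence.tsv",
              ["family", "composite", "component_a", "component_b",
               "gene_a", "gene_b", "genome", "operon"],
              [(e.family_id, e.composite, *e.component_pair, *e.gene_pair,
                e.genome, e.operon) for e in operon_ev])

    intron_rows = []
    intron_fams: set[str] = set()
    seqs = read_fasta(inputs["fasta"]) if "fasta" in inputs else {}
    for fam_id in sgene_ids:
        members = sorted(fam_by_id[fam_id].members)
        msa = {m: seqs[m] for m in members if m in seqs}
        if not msa or not any(m in introns for m in msa):
            continue
        if len({len(s) for s in msa.values()}) != 1:
            log.warning("family %s: unaligned member lengths; skipping introns",
                        fam_id)
            continue
        borders = {m: component_borders(components_by_gene.get(m, []))
                   for m in msa}
        calls = conserved_introns(fam_id, msa, introns, borders, taxa, t)
        for c in calls:
            intron_rows.append((c.family_id, c.column, c.opimoda_gene,
                                c.diphoda_gene, c.placement))
            if c.placement == "BETWEEN_COMPONENTS":
                intron_fams.add(fam_id)
    write_tsv(outdir / "intron_calls.tsv",
              ["family", "column", "opimoda_gene", "diphoda_gene", "placement"],
              intron_rows)

    targeting_rows = []
    targeted_of: dict[str, bool] = {}
    if targeting:
        for fam in candidates:
            flag, fractions = family_targeting(targeting, fam.members)
            targeted_of[fam.id] = flag
            targeting_rows.append(
                (fam.id, int(flag), *(f"{fractions[l]:.4f}"
                                      for l in ("MITO", "CHLORO", "SIGNAL"))))
    write_tsv(outdir / "family_targeting.tsv",
              ["family", "targeted", "f_mito", "f_chloro", "f_signal"],
              targeting_rows)

    # --- stage 7: statistics -----------------------------------------------
    stats_rows = []
    if targeted_of and sgene_ids:
        pool_ids = [f for f in sorted(targeted_of) if f not in set(sgene_ids)]
        pool = [targeted_of[f] for f in pool_ids]
        observed = sum(targeted_of.get(f, False) for f in sgene_ids)
        if len(pool) >= len(sgene_ids) and 0 < sum(pool) < len(pool):
            res = resampling_zscore(observed, pool, len(sgene_ids), t,
                                    seed=seed)
            stats_rows.append(("targeting_depletion_z", f"{res.z_score:.4f}"))
            stats_rows.append(("targeting_depletion_p_two_sided",
                               f"{res.p_two_sided:.3e}"))
            stats_rows.append(("targeting_depletion_p_one_sided",
                               f"{res.p_one_sided:.3e}"))
    write_tsv(outdir / "stats.tsv", ["statistic", "value"], stats_rows)

    # --- manifest ----------------------------------------------------------
    n_classes = {lab: sum(1 for v in label_of.values() if v == lab)
                 for lab in (S_GENE, PROK_FULL, EUK_INNOVATION)}
    counts = {
        "sequences": len(taxa),
        "families": len(families),
        "candidate_families": len(candidates),
        "composite_genes": len(triplets),
        "composite_families": len(composite_calls),
        "excluded_families": len(removed),
        "prok_full_families": n_classes[PROK_FULL],
        "euk_innovation_families": n_classes[EUK_INNOVATION],
        "sgene_families": n_classes[S_GENE],
        "component_families": sum(len(v) for v in components_by_gene.values()),
        "early_families": sum(1 for a in ages.values() if a == "EARLY"),
        "intermediate_families": sum(1 for a in ages.values()
                                     if a == "INTERMEDIATE"),
        "lineage_specific_families": sum(1 for a in ages.values()
                                         if a == "LINEAGE_SPECIFIC"),
        "operon_like_families": len(operon_fams),
        "conserved_intron_families": len(intron_fams),
    }
    expected_sgenes = (counts["composite_families"]
                       - counts["prok_full_families"]
                       - counts["euk_innovation_families"]
                       - counts["excluded_families"])
    if counts["sgene_families"] != expected_sgenes:
        raise AssertionError(
            "manifest funnel inconsistency: "
            f"{counts['sgene_families']} S-gene families != "
            f"{counts['composite_families']} composite - "
            f"{counts['prok_full_families']} full-length - "
            f"{counts['euk_innovation_families']} innovations - "
            f"{counts['excluded_families']} excluded"
        )
    log.info(
        "funnel: %d sequences -> %d families -> %d candidates -> %d composite "
        "-> %d S-genes (%d early)",
        counts["sequences"], counts["families"], counts["candidate_families"],
        counts["composite_families"], counts["sgene_families"],
        counts["early_families"],
    )
    manifest = RunManifest(config={k: v for k, v in cfg.items()},
                           input_digests=digests, counts=counts, seed=seed)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
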
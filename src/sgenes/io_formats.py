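"""Readers and writers for the external formats the pipeline consumes.

Coordinates are 1-based inclusive throughout (the BLAST tabular convention);
an interval ``(s, e)`` has length ``e - s + 1``.  All validation happens here:
downstream modules receive typed records and never re-check file syntax.
Comment lines beginning with ``#`` and blank lines are skipped in every TSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

EUKARYOTE = "EUKARYOTE"
BACTERIA = "BACTERIA"
ARCHAEA = "ARCHAEA"
DOMAINS_OF_LIFE = frozenset({EUKARYOTE, BACTERIA, ARCHAEA})

OPIMODA = "OPIMODA"
DIPHODA = "DIPHODA"
MEGAGROUPS = frozenset({OPIMODA, DIPHODA})

TARGETING_CLASSES = frozenset({"MITO", "CHLORO", "SIGNAL", "OTHER"})


class ParseError(ValueError):
    """A malformed input file; the message names the file and line."""


class ValidationError(ValueError):
    """A syntactically valid record that violates a domain invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """One sequence in the dataset with its taxonomic placement.

    ``supergroup`` and ``megagroup`` are present iff the record is
    eukaryotic; ``sequence`` is optional and, when present, must match
    ``length``.
    """

    id: str
    species: str
    domain_of_life: str
    length: int
    supergroup: str | None = None
    megagroup: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.domain_of_life not in DOMAINS_OF_LIFE:
            raise ValidationError(
                f"{self.id}: unknown domain_of_life {self.domain_of_life!r}"
            )
        if self.length < 1:
            raise ValidationError(f"{self.id}: length must be >= 1")
        is_euk = self.domain_of_life == EUKARYOTE
        if is_euk and not self.supergroup:
            raise ValidationError(f"{self.id}: eukaryote row lacks a supergroup")
        if is_euk and self.megagroup not in MEGAGROUPS:
            raise ValidationError(
                f"{self.id}: eukaryote row needs megagroup OPIMODA or DIPHODA"
            )
        if not is_euk and (self.supergroup or self.megagroup):
            raise ValidationError(
                f"{self.id}: supergroup/megagroup only apply to eukaryotes"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"{self.id}: sequence length {len(self.sequence)} != length field "
                f"{self.length}"
            )

    @property
    def is_eukaryote(self) -> bool:
        return self.domain_of_life == EUKARYOTE

    @property
    def is_prokaryote(self) -> bool:
        return self.domain_of_life in (BACTERIA, ARCHAEA)


@dataclass(frozen=True)
class SimilarityHit:
    """One pairwise local alignment (an HSP) in BLAST outfmt-6 terms.

    Multiple HSPs for one (query, subject) pair stay separate records;
    consumers decide how to aggregate.
    """

    query: str
    subject: str
    pct_identity: float
    aln_len: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(
                f"{self.query}/{self.subject}: pct_identity outside [0, 100]"
            )
        if self.qstart > self.qend or self.sstart > self.send:
            raise ValidationError(
                f"{self.query}/{self.subject}: reversed span "
                f"({self.qstart}-{self.qend}/{self.sstart}-{self.send}); protein "
                "alignments cannot be reversed"
            )
        if min(self.qstart, self.sstart) < 1:
            raise ValidationError(
                f"{self.query}/{self.subject}: coordinates are 1-based"
            )
        if self.evalue < 0 or self.bitscore < 0:
            raise ValidationError(
                f"{self.query}/{self.subject}: negative evalue or bitscore"
            )

    @property
    def qspan(self) -> tuple[int, int]:
        return (self.qstart, self.qend)

    @property
    def sspan(self) -> tuple[int, int]:
        return (self.sstart, self.send)


@dataclass
class AnnotationTables:
    """Optional per-gene annotation layers, each loaded from a plain TSV."""

    domains: dict[str, list[tuple[str, tuple[int, int]]]] = field(default_factory=dict)
    operons: list[tuple[str, str, str]] = field(default_factory=list)
    introns: dict[str, list[int]] = field(default_factory=dict)
    targeting: dict[str, str] = field(default_factory=dict)
    cog: dict[str, str] = field(default_factory=dict)
    degree: dict[str, int] = field(default_factory=dict)
    essential: dict[str, bool] = field(default_factory=dict)


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping comments/blanks."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def parse_hit_table(path: str | Path) -> list[SimilarityHit]:
    """Parse a 12-column BLAST outfmt-6 TSV into SimilarityHit records.

    Order is preserved; scientific-notation E-values are accepted.  A line
    with fewer than 12 fields, or an unparsable numeric field, raises
    :class:`ParseError` naming the line.
    """
    hits: list[SimilarityHit] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 12:
            raise ParseError(
                f"{path}:{lineno}: expected >= 12 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            hit = SimilarityHit(
                query=fields[0],
                subject=fields[1],
                pct_identity=float(fields[2]),
                aln_len=int(fields[3]),
                mismatch=int(fields[4]),
                gapopen=int(fields[5]),
                qstart=int(fields[6]),
                qend=int(fields[7]),
                sstart=int(fields[8]),
                send=int(fields[9]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
            )
        except ValidationError:
            raise
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ev = f"{h.evalue:.3g}" if h.evalue != 0 else "0.0"
            fh.write(
                f"{h.query}\t{h.subject}\t{h.pct_identity:.1f}\t{h.aln_len}\t"
                f"{h.mismatch}\t{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t"
                f"{h.send}\t{ev}\t{h.bitscore:.1f}\n"
            )


_TAXON_COLUMNS = ["id", "species", "domain_of_life", "length", "supergroup", "megagroup"]


def parse_taxon_table(path: str | Path) -> dict[str, ProteinRecord]:
    """Parse the sequence -> species/domain/supergroup table.

    Columns: id, species, domain_of_life, length, then optional supergroup
    and megagroup (empty or ``-`` for prokaryotes).  A header line starting
    with ``id`` is tolerated.  Duplicate ids are rejected.
    """
    taxa: dict[str, ProteinRecord] = {}
    for lineno, fields in _data_lines(path):
        if fields[0] == "id":
            continue
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected >= 4 fields")
        sup = fields[4] if len(fields) > 4 and fields[4] not in ("", "-") else None
        meg = fields[5] if len(fields) > 5 and fields[5] not in ("", "-") else None
        try:
            rec = ProteinRecord(
                id=fields[0],
                species=fields[1],
                domain_of_life=fields[2],
                length=int(fields[3]),
                supergroup=sup,
                megagroup=meg,
            )
        except ValueError as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from exc
        if rec.id in taxa:
            raise ValidationError(f"{path}:{lineno}: duplicate id {rec.id!r}")
        taxa[rec.id] = rec
    return taxa


def write_taxon_table(taxa: Mapping[str, ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TAXON_COLUMNS) + "\n")
        for rec in taxa.values():
            fh.write(
                f"{rec.id}\t{rec.species}\t{rec.domain_of_life}\t{rec.length}\t"
                f"{rec.supergroup or '-'}\t{rec.megagroup or '-'}\n"
            )


def parse_domain_table(
    path: str | Path, taxa: Mapping[str, ProteinRecord] | None = None
) -> dict[str, list[tuple[str, tuple[int, int]]]]:
    """Columns: gene, domain_name, start, end (1-based inclusive)."""
    out: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    for lineno, fields in _data_lines(path):
        if fields[0] == "gene":
            continue
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected gene, domain, start, end")
        gene, name = fields[0], fields[1]
        start, end = int(fields[2]), int(fields[3])
        if start < 1 or start > end:
            raise ValidationError(f"{path}:{lineno}: bad span {start}-{end}")
        if taxa is not None and gene in taxa and end > taxa[gene].length:
            raise ValidationError(
                f"{path}:{lineno}: span end {end} beyond {gene} length "
                f"{taxa[gene].length}"
            )
        out.setdefault(gene, []).append((name, (start, end)))
    return out


def parse_operon_table(path: str | Path) -> list[tuple[str, str, str]]:
    """Columns: genome, operon, gene."""
    rows = []
    for lineno, fields in _data_lines(path):
        if fields[0] == "genome":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected genome, operon, gene")
        rows.append((fields[0], fields[1], fields[2]))
    return rows


def parse_intron_table(
    path: str | Path, taxa: Mapping[str, ProteinRecord] | None = None
) -> dict[str, list[int]]:
    """Columns: gene, position (aa after which the intron falls, 1-based)."""
    out: dict[str, list[int]] = {}
    for lineno, fields in _data_lines(path):
        if fields[0] == "gene":
            continue
        gene, pos = fields[0], int(fields[1])
        if pos < 1:
            raise ValidationError(f"{path}:{lineno}: intron position must be >= 1")
        if taxa is not None and gene in taxa and pos > taxa[gene].length:
            raise ValidationError(
                f"{path}:{lineno}: intron position {pos} beyond {gene} length"
            )
        out.setdefault(gene, []).append(pos)
    for positions in out.values():
        positions.sort()
    return out


def parse_targeting_table(path: str | Path) -> dict[str, str]:
    """Columns: gene, location in {MITO, CHLORO, SIGNAL, OTHER}."""
    out: dict[str, str] = {}
    for lineno, fields in _data_lines(path):
        if fields[0] == "gene":
            continue
        gene, loc = fields[0], fields[1]
        if loc not in TARGETING_CLASSES:
            raise ValidationError(f"{path}:{lineno}: unknown location {loc!r}")
        out[gene] = loc
    return out


def parse_simple_map(path: str | Path, value_type=str) -> dict:
    """Two-column key -> value TSV (COG letters, PPI degree, essentiality)."""
    out = {}
    for lineno, fields in _data_lines(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        key, val = fields[0], fields[1]
        if value_type is bool:
            out[key] = val.strip().lower() in ("1", "true", "yes")
        else:
            out[key] = value_type(val)
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly aligned) FASTA into an ordered id -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_tsv(
    path: str | Path, header: Sequence[str], rows: Iterable[Sequence]
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
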
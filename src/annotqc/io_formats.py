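"""Readers/writers for the formats the pipeline touches, plus the core
domain types.

One coordinate convention holds everywhere inside the package: 0-based,
half-open ``[start, end)``. GFF3 and tabular hit files are 1-based
inclusive on disk; the conversion happens here, at the I/O boundary, and
nowhere else.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Parsed data violates a domain invariant."""


@dataclass
class SeqRecord:
    """A named DNA sequence over the alphabet {A, C, G, T, N}.

    Sequences are normalized to upper case on construction; any other
    letter is mapped to ``N`` with a logged warning rather than raising,
    so that pipelines keep running on slightly dirty input.
    """

    id: str
    seq: str
    desc: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValidationError(f"sequence id must be a non-empty token, got {self.id!r}")
        seq = self.seq.upper()
        if _NON_ACGTN.search(seq):
            n_bad = len(_NON_ACGTN.findall(seq))
            logger.warning(
                "sequence %s: %d non-ACGTN letter(s) replaced with N", self.id, n_bad
            )
            seq = _NON_ACGTN.sub("N", seq)
        self.seq = seq

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval with optional strand."""

    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"interval requires 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"strand must be one of + - ., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


def _interval_union_covers(container: Sequence[Interval], item: Interval) -> bool:
    """True if ``item`` is fully covered by the union of ``container``."""
    pos = item.start
    for iv in sorted(container):
        if iv.end <= pos:
            continue
        if iv.start > pos:
            return False
        pos = iv.end
        if pos >= item.end:
            return True
    return pos >= item.end


@dataclass
class GeneModel:
    """A predicted gene: exons with CDS/UTR sub-intervals on one scaffold.

    Invariants enforced at construction: exons sorted and pairwise
    disjoint; every CDS and UTR interval contained in the exon union;
    CDS and UTR disjoint. A gene is *intronless* iff it has one exon.
    """

    gene_id: str
    scaffold_id: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: at least one exon required")
        # strand is a property of the gene; sub-intervals are unstranded
        self.exons = sorted(Interval(e.start, e.end) for e in self.exons)
        self.cds = [Interval(c.start, c.end) for c in self.cds]
        self.utr = [Interval(u.start, u.end) for u in self.utr]
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons {a} and {b}")
        for kind, ivs in (("CDS", self.cds), ("UTR", self.utr)):
            for iv in ivs:
                if not _interval_union_covers(self.exons, iv):
                    raise ValidationError(
                        f"gene {self.gene_id}: {kind} {iv} outside the exon union"
                    )
        self.cds = sorted(self.cds)
        self.utr = sorted(self.utr)
        for c in self.cds:
            for u in self.utr:
                if c.overlaps(u):
                    raise ValidationError(
                        f"gene {self.gene_id}: CDS {c} overlaps UTR {u}"
                    )

    @property
    def intronless(self) -> bool:
        return len(self.exons) == 1

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds)

    @property
    def utr_length(self) -> int:
        return sum(len(u) for u in self.utr)

    @property
    def utr_ratio(self) -> float | None:
        """UTR/(UTR+CDS) on spliced lengths; None when both are empty."""
        tot = self.cds_length + self.utr_length
        if tot == 0:
            return None
        return self.utr_length / tot


@dataclass
class HitRecord:
    """One row of a 12-column tabular similarity search.

    Coordinates are kept 1-based inclusive *as read from file*; a
    minus-strand hit is flagged when subject coordinates are reversed.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gaps: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: qstart > qend"
            )
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )

    @property
    def subject_strand(self) -> str:
        return "-" if self.sstart > self.send else "+"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into :class:`SeqRecord` objects, in file order.

    Empty file yields an empty list; sequence lines before the first
    header raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header '>' before sequence data"
                )
            break
        else:
            return []
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq), desc=desc))
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    bio = [
        BioSeqRecord(Seq(r.seq), id=r.id, description=r.desc)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3

_UTR_TYPES = {"five_prime_UTR", "three_prime_UTR", "UTR"}


def _gff_attributes(field9: str) -> dict[str, str]:
    attrs = {}
    for part in field9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS/UTR features into :class:`GeneModel` objects.

    GFF3 1-based inclusive coordinates become internal 0-based half-open.
    When a gene has several mRNA children, the first one in file order is
    used (gene sets are reported without isoforms). A CDS that falls
    outside the exon union raises :class:`ValidationError` naming the gene.
    """
    path = Path(path)
    genes: dict[str, dict] = {}           # gene_id -> {scaffold, strand}
    gene_order: list[str] = []
    mrna_parent: dict[str, str] = {}      # mrna_id -> gene_id
    first_mrna: dict[str, str] = {}       # gene_id -> first mrna_id by file order
    parts: dict[str, dict[str, list[Interval]]] = {}  # mrna_id -> kind -> intervals

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 tab-separated fields")
            seqid, _source, ftype, start, end, _score, strand, _phase, attr9 = fields
            try:
                iv = Interval(int(start) - 1, int(end), strand if strand in "+-" else ".")
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: line {lineno}: bad coordinates: {exc}") from exc
            attrs = _gff_attributes(attr9)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise FormatError(f"{path}: line {lineno}: gene without ID attribute")
                genes[gid] = {"scaffold": seqid, "strand": iv.strand}
                gene_order.append(gid)
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if not mid or not parent:
                    raise FormatError(f"{path}: line {lineno}: mRNA needs ID and Parent")
                mrna_parent[mid] = parent
                first_mrna.setdefault(parent, mid)
            elif ftype == "exon" or ftype == "CDS" or ftype in _UTR_TYPES:
                parent = attrs.get("Parent")
                if not parent:
                    raise FormatError(f"{path}: line {lineno}: {ftype} without Parent")
                kind = "utr" if ftype in _UTR_TYPES else ftype.lower()
                parts.setdefault(parent, {"exon": [], "cds": [], "utr": []})[kind].append(iv)

    models = []
    for gid in gene_order:
        info = genes[gid]
        mid = first_mrna.get(gid)
        # features may also hang directly off the gene (no mRNA level)
        p = parts.get(mid, parts.get(gid, {"exon": [], "cds": [], "utr": []}))
        if not p["exon"]:
            raise ValidationError(f"gene {gid}: no exon features found")
        try:
            models.append(
                GeneModel(
                    gene_id=gid,
                    scaffold_id=info["scaffold"],
                    strand=info["strand"],
                    exons=p["exon"],
                    cds=p["cds"],
                    utr=p["utr"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return models


def _utr_type(model: GeneModel, utr: Interval) -> str:
    """Label a UTR interval as 5' or 3' relative to the CDS and strand."""
    if not model.cds:
        return "five_prime_UTR"
    before = utr.end <= model.cds[0].start
    if model.strand == "-":
        return "three_prime_UTR" if before else "five_prime_UTR"
    return "five_prime_UTR" if before else "three_prime_UTR"


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as gene/mRNA/exon/CDS/UTR GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            span = m.span
            base = (m.scaffold_id, "annotqc")
            mid = f"{m.gene_id}.t1"

            def line(ftype, iv, attrs):
                fh.write(
                    "\t".join(
                        [*base, ftype, str(iv.start + 1), str(iv.end), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )

            line("gene", span, f"ID={m.gene_id}")
            line("mRNA", span, f"ID={mid};Parent={m.gene_id}")
            for e in m.exons:
                line("exon", e, f"Parent={mid}")
            for c in m.cds:
                line("CDS", c, f"Parent={mid}")
            for u in m.utr:
                line(_utr_type(m, u), u, f"Parent={mid}")


# ---------------------------------------------------------------------------
# BED4


def read_bed(path: str | Path) -> list[tuple[str, Interval, str]]:
    """Read BED4 lines as (chrom, interval, name); BED is already 0-based half-open."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected at least 3 BED fields")
            try:
                iv = Interval(int(fields[1]), int(fields[2]))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else ""
            out.append((fields[0], iv, name))
    return out


def write_bed(entries: Iterable[tuple[str, Interval, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, iv, name in entries:
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# 12-column tabular hits

_HIT_COLUMNS = [
    "query_id", "subject_id", "pct_identity", "aln_len", "mismatches", "gaps",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
_HIT_DTYPES = {
    "pct_identity": float, "aln_len": int, "mismatches": int, "gaps": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column tab-separated similarity table (one hit per line)."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=_HIT_COLUMNS, dtype=str,
            comment="#", skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise FormatError(f"{path}: expected 12 tab-separated columns")
    for col, typ in _HIT_DTYPES.items():
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise FormatError(
                f"{path}: line {bad + 1}: non-numeric value {df[col].iloc[bad]!r} in column {col}"
            ) from None
    return [HitRecord(**row) for row in df.to_dict("records")]


def write_hits(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        h.query_id, h.subject_id, h.pct_identity, h.aln_len,
                        h.mismatches, h.gaps, h.qstart, h.qend, h.sstart, h.send,
                        h.evalue, h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# coverage tracks (2-column: 1-based position, depth)


def read_coverage(path: str | Path, length: int | None = None) -> np.ndarray:
    """Read a per-base depth track; returns an int array of the contig length.

    Positions on disk are 1-based; missing positions default to depth 0
    (``length`` must then be given or is taken as the max position seen).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["pos", "depth"])
    except pd.errors.EmptyDataError:
        return np.zeros(length or 0, dtype=int)
    n = length if length is not None else int(df["pos"].max())
    depth = np.zeros(n, dtype=int)
    pos = df["pos"].to_numpy(dtype=int) - 1
    if (pos < 0).any() or (pos >= n).any():
        raise FormatError(f"{path}: position outside [1, {n}]")
    depth[pos] = df["depth"].to_numpy(dtype=int)
    return depth


def write_coverage(depth: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, d in enumerate(depth, start=1):
            fh.write(f"{i}\t{int(d)}\n")
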
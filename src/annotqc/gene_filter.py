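"""Post-prediction gene filtering cascade.

Ab initio / evidence-combined gene builders overcall genes, in
particular single-exon models arising from transposable elements and
fragmented transcript alignments. This module classifies every
predicted gene KEEP or REMOVE with a single reason code, applying three
rules in order (first match wins):

R1 (any gene)       exons highly covered by repeats (>90%) OR tagged as
                    a transposable element, and no pfam and no blastp
                    hit -> REMOVE, reason REPEAT_TE.
R2 (intronless)     predicted from RNA-seq only (no protein species),
                    composed of >80% UTR (UTR/(UTR+CDS) on spliced
                    lengths), and no pfam/blastp hit -> REMOVE, reason
                    UTR_RNA_ONLY.
R3 (intronless)     none of the support conditions holds — (i) at least
                    one mRNA sample and one protein species, (ii) mRNA
                    support from at least two samples, (iii) a curated
                    same-species protein — and no pfam/blastp hit
                    -> REMOVE, reason WEAK_EVIDENCE.

A pfam or blastp hit therefore always rescues a gene: evidence can only
flip REMOVE to KEEP, never the reverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from annotqc.io_formats import GeneModel, ValidationError

REASONS = ("KEPT", "REPEAT_TE", "UTR_RNA_ONLY", "WEAK_EVIDENCE")


@dataclass
class EvidenceRecord:
    """Per-gene evidence flags and counts feeding the filter cascade."""

    gene_id: str
    has_pfam: bool
    has_blastp: bool
    repeat_cov: float          # fraction of exonic bases under repeats
    te_tagged: bool
    n_mrna_samples: int
    n_protein_species: int
    has_self_uniprot: bool
    utr_ratio: float | None    # UTR/(UTR+CDS) on spliced lengths; None if no CDS/UTR

    def __post_init__(self) -> None:
        if not 0.0 <= self.repeat_cov <= 1.0:
            raise ValidationError(f"{self.gene_id}: repeat_cov outside [0, 1]")
        if self.n_mrna_samples < 0 or self.n_protein_species < 0:
            raise ValidationError(f"{self.gene_id}: negative support count")
        if self.utr_ratio is not None and not 0.0 <= self.utr_ratio <= 1.0:
            raise ValidationError(f"{self.gene_id}: utr_ratio outside [0, 1]")


@dataclass
class FilterDecision:
    gene_id: str
    verdict: str               # "KEEP" | "REMOVE"
    reason: str                # one of REASONS
    rule_trace: list[str] = field(default_factory=list)


def classify_gene(
    model: GeneModel,
    ev: EvidenceRecord,
    repeat_cov_threshold: float = 0.90,
    utr_ratio_threshold: float = 0.80,
) -> FilterDecision:
    """Classify one gene through the R1/R2/R3 cascade; first match wins."""
    if model.gene_id != ev.gene_id:
        raise ValidationError(f"model/evidence id mismatch: {model.gene_id} vs {ev.gene_id}")
    trace: list[str] = []
    no_hits = not ev.has_pfam and not ev.has_blastp

    r1 = (ev.repeat_cov > repeat_cov_threshold or ev.te_tagged) and no_hits
    trace.append(f"R1:{'hit' if r1 else 'pass'}")
    if r1:
        return FilterDecision(ev.gene_id, "REMOVE", "REPEAT_TE", trace)

    if model.intronless:
        utr = ev.utr_ratio if ev.utr_ratio is not None else model.utr_ratio
        r2 = (
            ev.n_protein_species == 0
            and utr is not None
            and utr > utr_ratio_threshold
            and no_hits
        )
        trace.append(f"R2:{'hit' if r2 else 'pass'}")
        if r2:
            return FilterDecision(ev.gene_id, "REMOVE", "UTR_RNA_ONLY", trace)

        supported = (
            (ev.n_mrna_samples >= 1 and ev.n_protein_species >= 1)
            or ev.n_mrna_samples >= 2
            or ev.has_self_uniprot
        )
        r3 = not supported and no_hits
        trace.append(f"R3:{'hit' if r3 else 'pass'}")
        if r3:
            return FilterDecision(ev.gene_id, "REMOVE", "WEAK_EVIDENCE", trace)

    return FilterDecision(ev.gene_id, "KEEP", "KEPT", trace)


@dataclass
class FilterSummary:
    n_genes: int
    reason_counts: dict[str, int]
    intronless_fraction_kept: float
    mean_gene_length: float
    median_gene_length: float
    mean_cds_length: float
    median_cds_length: float


def filter_gene_set(
    models: Sequence[GeneModel],
    evidence: Sequence[EvidenceRecord],
    **thresholds,
) -> tuple[list[GeneModel], list[FilterDecision], FilterSummary]:
    """Classify every gene; return (kept models, all decisions, summary).

    Gene and CDS length statistics in the summary describe the *kept*
    set: gene length is the genomic span, CDS length the spliced coding
    length. Raises when models and evidence do not match one-to-one.
    """
    ev_by_id = {e.gene_id: e for e in evidence}
    model_ids = {m.gene_id for m in models}
    orphans = sorted(model_ids.symmetric_difference(ev_by_id))
    if orphans:
        raise ValidationError(f"model/evidence mismatch for: {', '.join(orphans)}")

    decisions = [classify_gene(m, ev_by_id[m.gene_id], **thresholds) for m in models]
    kept = [m for m, d in zip(models, decisions) if d.verdict == "KEEP"]
    counts = {r: 0 for r in REASONS}
    for d in decisions:
        counts[d.reason] += 1

    gene_lens = np.array([len(m.span) for m in kept]) if kept else np.array([0])
    cds_lens = np.array([m.cds_length for m in kept]) if kept else np.array([0])
    summary = FilterSummary(
        n_genes=len(models),
        reason_counts=counts,
        intronless_fraction_kept=(
            sum(m.intronless for m in kept) / len(kept) if kept else 0.0
        ),
        mean_gene_length=float(gene_lens.mean()),
        median_gene_length=float(np.median(gene_lens)),
        mean_cds_length=float(cds_lens.mean()),
        median_cds_length=float(np.median(cds_lens)),
    )
    return kept, decisions, summary


# ---------------------------------------------------------------------------
# evidence table I/O

_EVIDENCE_COLUMNS = [
    "gene_id", "has_pfam", "has_blastp", "repeat_cov", "te_tagged",
    "n_mrna_samples", "n_protein_species", "has_self_uniprot", "utr_ratio",
]
_BOOL_COLUMNS = ("has_pfam", "has_blastp", "te_tagged", "has_self_uniprot")


def read_evidence(path: str | Path) -> list[EvidenceRecord]:
    """Read a tab-separated evidence table (columns = EvidenceRecord fields)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing evidence columns: {sorted(missing)}")
    records = []
    for row in df.to_dict("records"):
        utr = row["utr_ratio"]
        records.append(
            EvidenceRecord(
                gene_id=str(row["gene_id"]),
                has_pfam=bool(int(row["has_pfam"])),
                has_blastp=bool(int(row["has_blastp"])),
                repeat_cov=float(row["repeat_cov"]),
                te_tagged=bool(int(row["te_tagged"])),
                n_mrna_samples=int(row["n_mrna_samples"]),
                n_protein_species=int(row["n_protein_species"]),
                has_self_uniprot=bool(int(row["has_self_uniprot"])),
                utr_ratio=None if pd.isna(utr) else float(utr),
            )
        )
    return records


def write_evidence(records: Sequence[EvidenceRecord], path: str | Path) -> None:
    rows = []
    for e in records:
        row = {c: getattr(e, c) for c in _EVIDENCE_COLUMNS}
        for c in _BOOL_COLUMNS:
            row[c] = int(row[c])
        rows.append(row)
    pd.DataFrame(rows, columns=_EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)
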
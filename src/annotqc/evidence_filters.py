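"""Retention rules for transcript and protein alignment evidence.

Before gene prediction, aligned mRNA contigs and reference proteins are
filtered so that only well-supported alignments feed the gene builder:
transcript alignments must cover most of the contig at high identity,
protein matches must be near the best match for that protein and cover
at least half of it, and single-exon transcripts seen in only one
RNA-seq sample are discarded as likely noise.

All thresholds are strict inequalities ("higher than", "more than").
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from intervaltree import IntervalTree

from annotqc.io_formats import Interval


@dataclass
class AlignedEvidence:
    """One alignment of an evidence sequence (mRNA contig or protein)."""

    evidence_id: str
    kind: str  # "mRNA" | "protein"
    sample_or_species: str
    length: int          # contig length (mRNA) or protein length (aa)
    aligned_len: int
    identity: float      # percent, 0-100
    score: float = 0.0
    best_score_in_group: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.aligned_len <= self.length:
            raise ValueError(f"{self.evidence_id}: aligned_len outside [0, length]")
        if not 0 <= self.identity <= 100:
            raise ValueError(f"{self.evidence_id}: identity outside [0, 100]")


def retain_transcript_alignments(
    evidence: list[AlignedEvidence],
    min_overlap: float = 0.80,
    min_identity: float = 95.0,
) -> list[AlignedEvidence]:
    """Keep mRNA alignments covering more than 80% of the contig at more
    than 95% identity (both strict)."""
    return [
        e
        for e in evidence
        if e.kind == "mRNA"
        and e.aligned_len / e.length > min_overlap
        and e.identity > min_identity
    ]


def retain_protein_matches(
    evidence: list[AlignedEvidence],
    score_fraction: float = 0.90,
    min_aligned_fraction: float = 0.50,
) -> list[AlignedEvidence]:
    """Two-stage protein-match retention.

    Stage 1 keeps, within each protein's match group, matches scoring
    strictly more than ``score_fraction`` of the group's best score (the
    best match itself always survives). Stage 2 keeps proteins with
    strictly more than half their length aligned.
    """
    groups: dict[str, list[AlignedEvidence]] = defaultdict(list)
    for e in evidence:
        if e.kind == "protein":
            groups[e.evidence_id].append(e)
    kept = []
    for matches in groups.values():
        best = max(m.score for m in matches)
        for m in matches:
            if m.score >= best or m.score > score_fraction * best:
                if m.aligned_len / m.length > min_aligned_fraction:
                    kept.append(m)
    return kept


@dataclass
class TranscriptAlignment:
    """Genomic placement of one aligned transcript contig."""

    transcript_id: str
    sample: str
    scaffold: str
    span: Interval  # genomic span, stranded
    n_exons: int


def drop_sample_specific_single_exon(
    transcripts: list[TranscriptAlignment],
) -> list[TranscriptAlignment]:
    """Remove single-exon transcripts supported by a single sample only.

    A single-exon transcript is dropped iff no transcript from a
    *different* sample overlaps it (same scaffold, same strand, at least
    one shared base). Multi-exon transcripts are always kept.
    """
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    for i, t in enumerate(transcripts):
        trees[(t.scaffold, t.span.strand)].addi(t.span.start, t.span.end, i)
    kept = []
    for i, t in enumerate(transcripts):
        if t.n_exons > 1:
            kept.append(t)
            continue
        hits = trees[(t.scaffold, t.span.strand)].overlap(t.span.start, t.span.end)
        if any(transcripts[h.data].sample != t.sample for h in hits):
            kept.append(t)
    return kept
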
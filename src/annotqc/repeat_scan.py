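"""Satellite-monomer and reference-copy scanning by exact local
alignment with iterative masking.

Tandem satellite arrays and multi-copy insertions (e.g. a mitochondrial
genome mis-assembled in tandem into a nuclear scaffold) are detected by
repeatedly Smith-Waterman-aligning a probe sequence against a scaffold:
the best local hit is reported, its scaffold span is masked with N, and
the alignment is repeated until the best score drops below a floor
derived from the reporting thresholds. Exact alignment replaces seeded
heuristics here; at the scale of a single monomer or reference probe it
is fast enough and fully deterministic. Scoring: match +1, mismatch -1,
gap open -2, gap extend -1 (configurable).

Reported occurrences are guaranteed pairwise non-overlapping by the
masking, and raising the identity threshold can only shrink the set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from annotqc.io_formats import Interval, SeqRecord


@dataclass
class RepeatOccurrence:
    scaffold_id: str
    interval: Interval
    identity: float           # percent over alignment columns
    monomer_coverage: float   # fraction of the probe spanned by the alignment
    score: float


@dataclass
class ScanSummary:
    n_occurrences: int
    n_scaffolds_hit: int
    total_bp: int


def _make_aligner(
    match: float = 1.0, mismatch: float = -1.0, gap_open: float = -2.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int, float]:
    """(target_start, target_end, query_start, query_end, pct_identity)."""
    t_blocks, q_blocks = alignment.aligned
    matches = columns = 0
    target, query = alignment.target, alignment.query
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        seg_t, seg_q = target[ts:te], query[qs:qe]
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
        columns += te - ts
    # count gap columns between consecutive blocks
    for (t0, t1), (n0, n1) in zip(t_blocks[:-1], t_blocks[1:]):
        columns += n0 - t1
    for (q0, q1), (n0, n1) in zip(q_blocks[:-1], q_blocks[1:]):
        columns += n0 - q1
    identity = 100.0 * matches / columns if columns else 0.0
    return (
        int(t_blocks[0][0]),
        int(t_blocks[-1][1]),
        int(q_blocks[0][0]),
        int(q_blocks[-1][1]),
        identity,
    )


def _iterative_scan(
    scaffold: SeqRecord,
    probe: str,
    min_score: float,
    aligner: Align.PairwiseAligner,
    max_hits: int = 10_000,
) -> list[RepeatOccurrence]:
    """All local hits of ``probe`` in ``scaffold`` scoring >= min_score,
    found greedily best-first with N-masking between iterations."""
    seq = list(scaffold.seq)
    hits = []
    for _ in range(max_hits):
        result = aligner.align("".join(seq), probe)
        if result.score < min_score:
            break
        aln = result[0]
        ts, te, qs, qe, ident = _alignment_stats(aln)
        if te <= ts:
            break
        hits.append(
            RepeatOccurrence(
                scaffold_id=scaffold.id,
                interval=Interval(ts, te),
                identity=ident,
                monomer_coverage=(qe - qs) / len(probe),
                score=float(result.score),
            )
        )
        seq[ts:te] = "N" * (te - ts)
    hits.sort(key=lambda h: h.interval)
    return hits


def _score_floor(probe_len: int, min_coverage: float, min_identity: float) -> float:
    """Gap-free lower bound on the score of a reportable hit: a hit
    covering a fraction c of the probe at identity p scores at least
    c*L*(2p-1) under +1/-1 match/mismatch scoring."""
    p = min_identity / 100.0
    return max(10.0, math.floor(min_coverage * probe_len * (2.0 * p - 1.0)))


def scan_monomer(
    scaffolds: list[SeqRecord],
    monomer: str,
    min_coverage: float = 0.80,
    min_identity: float = 90.0,
    min_score: float | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[list[RepeatOccurrence], ScanSummary]:
    """Find satellite-monomer occurrences across scaffolds.

    An occurrence is kept iff the alignment spans strictly more than
    ``min_coverage`` of the monomer and has identity at least
    ``min_identity`` percent (coverage strict, identity inclusive).
    Returns the kept occurrences and a per-scan summary (count,
    scaffolds hit, total bp covered).
    """
    if len(monomer) < 20:
        raise ValueError("monomer must be at least 20 bp")
    monomer = monomer.upper()
    if min_score is None:
        min_score = _score_floor(len(monomer), min_coverage, min_identity)
    aligner = aligner or _make_aligner()
    occurrences = []
    for scaf in scaffolds:
        for hit in _iterative_scan(scaf, monomer, min_score, aligner):
            if hit.monomer_coverage > min_coverage and hit.identity >= min_identity:
                occurrences.append(hit)
    summary = ScanSummary(
        n_occurrences=len(occurrences),
        n_scaffolds_hit=len({o.scaffold_id for o in occurrences}),
        total_bp=sum(len(o.interval) for o in occurrences),
    )
    return occurrences, summary


def count_reference_copies(
    scaffold: SeqRecord,
    reference: str,
    min_identity: float = 80.0,
    min_coverage: float = 0.80,
    min_score: float | None = None,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[int, list[RepeatOccurrence]]:
    """Count near-full-length copies of a reference inside one scaffold.

    A copy is an iteratively-masked local hit covering strictly more
    than ``min_coverage`` of the reference at >= ``min_identity``
    percent identity. Fragments below the coverage cut are not counted.
    """
    if len(reference) > len(scaffold.seq):
        return 0, []
    reference = reference.upper()
    if min_score is None:
        min_score = _score_floor(len(reference), min_coverage, min_identity)
    aligner = aligner or _make_aligner()
    hits = _iterative_scan(scaffold, reference, min_score, aligner)
    copies = [
        h for h in hits if h.monomer_coverage > min_coverage and h.identity >= min_identity
    ]
    return len(copies), copies
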
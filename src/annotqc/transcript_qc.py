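"""Post-processing of assembled transcript contigs.

De novo transcriptome assemblers (Velvet/Oases style) leave three kinds
of artefact that this module cleans up before the contigs are used as
annotation evidence:

* unreliable contig ends (trimmed),
* low-complexity contigs (DUST-style masking plus a length/complexity
  filter),
* chimeric contigs fusing two transcripts, detectable as an internal
  run of zero consistent read-pair coverage; these are split, but never
  inside an ORF or an annotated domain.

Finally contigs are oriented from the strand votes of consistent pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

from annotqc.io_formats import Interval, SeqRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class CoverageTrack:
    """Per-base depth of consistent read pairs plus strand vote counts."""

    contig_id: str
    depth: np.ndarray
    plus_pairs: int = 0
    minus_pairs: int = 0

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=int)
        if (self.depth < 0).any():
            raise ValueError(f"{self.contig_id}: negative depth")


@dataclass
class Orf:
    interval: Interval
    frame: int  # 0..2, offset within the strand's reading direction

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass
class OrfSet:
    contig_id: str
    orfs: list[Orf] = field(default_factory=list)

    def intervals(self) -> list[Interval]:
        return [o.interval for o in self.orfs]


@dataclass
class BreakReport:
    """One candidate zero-coverage gap and what was done with it."""

    gap: Interval
    midpoint: int
    actionable: bool
    reason: str  # "split" | "overlaps_orf" | "overlaps_domain" | "contig_end"


def trim_ends(contig: SeqRecord, n: int = 5) -> SeqRecord:
    """Remove the first and last ``n`` bases; short contigs become empty."""
    if n < 0:
        raise ValueError("trim length must be >= 0")
    seq = contig.seq[n: len(contig.seq) - n] if len(contig.seq) > 2 * n else ""
    return SeqRecord(id=contig.id, seq=seq, desc=contig.desc)


def _window_dust_score(window: str) -> float:
    """Symmetric DUST score of one window: sum c_t(c_t-1)/2 over triplet
    counts, normalised by (w-2) and scaled x10."""
    w = len(window)
    if w < 3:
        return 0.0
    counts = Counter(window[i: i + 3] for i in range(w - 2))
    s = sum(c * (c - 1) // 2 for c in counts.values())
    return 10.0 * s / (w - 2)


def dust_mask(seq: str, window: int = 64, score_threshold: float = 20.0) -> list[Interval]:
    """Low-complexity masking from triplet-count window scores.

    Slides a window of ``window`` bases (shorter at the tail end of short
    sequences); windows whose score exceeds ``score_threshold`` are
    masked in full, and overlapping masked windows are merged. The score
    follows the symmetric DUST statistic: perfectly repetitive sequence
    approaches a score of 10*(w-2)/2 while random sequence stays near 1.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 3:
        return []
    w = min(window, n)
    counts: Counter = Counter(seq[i: i + 3] for i in range(w - 2))
    s = sum(c * (c - 1) // 2 for c in counts.values())
    masked: list[list[int]] = []

    def note(start: int, end: int) -> None:
        if masked and start <= masked[-1][1]:
            masked[-1][1] = max(masked[-1][1], end)
        else:
            masked.append([start, end])

    for start in range(0, n - w + 1):
        if 10.0 * s / (w - 2) > score_threshold:
            note(start, start + w)
        if start + w < n:  # roll the window one base right
            out_t = seq[start: start + 3]
            counts[out_t] -= 1
            s -= counts[out_t]
            in_t = seq[start + w - 2: start + w + 1]
            s += counts[in_t]
            counts[in_t] += 1
    return [Interval(a, b) for a, b in masked]


def complexity_filter(
    contigs: list[SeqRecord],
    masks: dict[str, list[Interval]],
    min_len: int = 150,
    min_unmasked: float = 0.75,
) -> list[SeqRecord]:
    """Keep contigs strictly longer than ``min_len`` with a strictly
    higher unmasked fraction than ``min_unmasked``."""
    kept = []
    for c in contigs:
        n = len(c.seq)
        if n <= min_len:
            continue
        masked = sum(len(iv) for iv in masks.get(c.id, []))
        if (n - masked) / n > min_unmasked:
            kept.append(c)
    return kept


def _orfs_one_strand(seq: str, min_aa: int, strand: str, contig_len: int) -> list[Orf]:
    out = []
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        for i in range(frame, n - 2, 3):
            codon = seq[i: i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in STOP_CODONS:
                for s in starts:
                    aa = (i - s) // 3  # codons before the stop
                    if aa >= min_aa:
                        if strand == "+":
                            iv = Interval(s, i + 3, "+")
                        else:  # mirror coordinates back onto the forward strand
                            iv = Interval(contig_len - (i + 3), contig_len - s, "-")
                        out.append(Orf(interval=iv, frame=frame))
                starts = []
    return out


def find_orfs(seq: str, min_aa: int = 100, contig_id: str = "") -> OrfSet:
    """All complete ORFs (ATG through in-frame stop) on six frames.

    ``min_aa`` counts coding codons excluding the stop. Coordinates are
    reported on the forward strand of the contig; minus-strand ORFs are
    mirrored accordingly. Every reported span has length divisible by 3.
    """
    seq = seq.upper()
    fwd = _orfs_one_strand(seq, min_aa, "+", len(seq))
    rev = _orfs_one_strand(str(Seq(seq).reverse_complement()), min_aa, "-", len(seq))
    orfs = sorted(fwd + rev, key=lambda o: (o.interval.start, o.interval.end, o.strand))
    return OrfSet(contig_id=contig_id, orfs=orfs)


def pair_coverage(
    alignments: list[tuple[Interval, Interval]],
    contig_len: int,
    contig_id: str = "",
    max_insert: int = 1000,
) -> CoverageTrack:
    """Depth of *consistent* read pairs over a contig.

    A pair is consistent iff the two mates are convergent (the leftmost
    mate on the plus strand, the rightmost on the minus strand) and
    their outer span is at most ``max_insert``. Depth is incremented
    over the full outer span. Strand votes come from the orientation of
    read 1: a plus-strand read 1 votes for the plus transcript strand.
    """
    diff = np.zeros(contig_len + 1, dtype=int)
    plus = minus = 0
    for r1, r2 in alignments:
        if r1.end > contig_len or r2.end > contig_len:
            raise ValueError(f"{contig_id}: read interval outside contig of length {contig_len}")
        left, right = (r1, r2) if r1.start <= r2.start else (r2, r1)
        convergent = left.strand == "+" and right.strand == "-"
        span = right.end - left.start
        if not convergent or span > max_insert:
            continue
        diff[left.start] += 1
        diff[right.end] -= 1
        if r1.strand == "+":
            plus += 1
        else:
            minus += 1
    depth = np.cumsum(diff[:-1])
    return CoverageTrack(contig_id=contig_id, depth=depth, plus_pairs=plus, minus_pairs=minus)


def _zero_runs(depth: np.ndarray, min_gap: int) -> list[Interval]:
    runs = []
    n = len(depth)
    i = 0
    while i < n:
        if depth[i] == 0:
            j = i
            while j < n and depth[j] == 0:
                j += 1
            if j - i >= min_gap:
                runs.append(Interval(i, j))
            i = j
        else:
            i += 1
    return runs


def split_chimeric(
    contig: SeqRecord,
    track: CoverageTrack,
    orfs: list[Interval],
    domains: list[Interval],
    min_gap: int = 10,
) -> tuple[list[SeqRecord], list[BreakReport]]:
    """Split a contig at internal zero-coverage gaps outside ORFs/domains.

    Candidate gaps are maximal runs of depth exactly 0 spanning at least
    ``min_gap`` bases. A gap is actionable iff it lies strictly inside
    the contig and intersects no ORF and no domain interval; the gap
    bases themselves are removed (the junction sequence is artefactual)
    and the report records the gap midpoint as the break position.
    Sub-contigs are renamed ``id.1``, ``id.2``, ... left to right.
    """
    n = len(contig.seq)
    if len(track.depth) != n:
        raise ValueError(f"{contig.id}: coverage track length {len(track.depth)} != contig length {n}")
    reports: list[BreakReport] = []
    cuts: list[Interval] = []
    for gap in _zero_runs(track.depth, min_gap):
        mid = (gap.start + gap.end) // 2
        if gap.start == 0 or gap.end == n:
            reports.append(BreakReport(gap, mid, False, "contig_end"))
        elif any(gap.overlaps(o) for o in orfs):
            reports.append(BreakReport(gap, mid, False, "overlaps_orf"))
        elif any(gap.overlaps(d) for d in domains):
            reports.append(BreakReport(gap, mid, False, "overlaps_domain"))
        else:
            reports.append(BreakReport(gap, mid, True, "split"))
            cuts.append(gap)

    if not cuts:
        return [contig], reports
    pieces = []
    pos = 0
    for gap in cuts:
        pieces.append((pos, gap.start))
        pos = gap.end
    pieces.append((pos, n))
    subs = [
        SeqRecord(id=f"{contig.id}.{k}", seq=contig.seq[a:b], desc=contig.desc)
        for k, (a, b) in enumerate(pieces, start=1)
        if b > a
    ]
    return subs, reports


def orient_contig(contig: SeqRecord, track: CoverageTrack) -> tuple[SeqRecord, str]:
    """Orient a contig from its strand votes.

    Returns the (possibly reverse-complemented) contig and a decision
    label: ``"kept"``, ``"reversed"`` or ``"ambiguous"`` (tie; input
    orientation kept).
    """
    if track.minus_pairs > track.plus_pairs:
        rc = str(Seq(contig.seq).reverse_complement())
        return SeqRecord(id=contig.id, seq=rc, desc=contig.desc), "reversed"
    if track.minus_pairs == track.plus_pairs:
        return contig, "ambiguous"
    return contig, "kept"
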
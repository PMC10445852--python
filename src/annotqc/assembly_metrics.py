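"""Assembly contiguity and composition statistics, plus the scaffold
length filter applied before annotation.

Definitions follow standard practice: NX is the length of the contig at
which the descending cumulative length first reaches X% of the total,
LX its 1-based rank, and auN the length-weighted mean contig length
(area under the Nx curve), sum(l_i^2) / sum(l_i).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from annotqc.io_formats import SeqRecord


def _round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (printed tables use this, not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_of(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` rounded half-away-from-zero to ``decimals``."""
    if total <= 0:
        raise ValueError("percent_of requires total > 0")
    if count < 0:
        raise ValueError("percent_of requires count >= 0")
    return _round_half_away(100.0 * count / total, decimals)


@dataclass
class AssemblyStats:
    n_contigs: int
    cumulative_size: int
    max_len: int
    mean_len: int
    n50: int
    l50: int
    n90: int
    l90: int
    auN: int
    gc_percent: float
    n_count: int
    n_percent: float

    def to_dict(self) -> dict:
        return asdict(self)


def _nx_lx(sorted_desc: Sequence[int], total: int, x: int) -> tuple[int, int]:
    target = x / 100.0 * total
    cum = 0
    for rank, length in enumerate(sorted_desc, start=1):
        cum += length
        if cum >= target:
            return length, rank
    return sorted_desc[-1], len(sorted_desc)  # unreachable for x <= 100


def compute_stats(records: Sequence[SeqRecord]) -> AssemblyStats:
    """Compute contiguity/composition statistics for a set of contigs.

    GC% is computed over A+C+G+T only (N excluded from the denominator)
    and printed with two decimals; mean length and auN are rounded to the
    nearest integer, half away from zero.
    """
    if not records:
        raise ValueError("compute_stats requires a non-empty contig list")
    lengths = sorted((len(r) for r in records), reverse=True)
    total = sum(lengths)
    n50, l50 = _nx_lx(lengths, total, 50)
    n90, l90 = _nx_lx(lengths, total, 90)
    aun = _round_half_away(sum(l * l for l in lengths) / total)

    gc = at = nn = 0
    for r in records:
        gc += r.seq.count("G") + r.seq.count("C")
        at += r.seq.count("A") + r.seq.count("T")
        nn += r.seq.count("N")
    acgt = gc + at
    gc_percent = _round_half_away(100.0 * gc / acgt, 2) if acgt else 0.0

    return AssemblyStats(
        n_contigs=len(lengths),
        cumulative_size=total,
        max_len=lengths[0],
        mean_len=int(_round_half_away(total / len(lengths))),
        n50=n50,
        l50=l50,
        n90=n90,
        l90=l90,
        auN=int(aun),
        gc_percent=gc_percent,
        n_count=nn,
        n_percent=percent_of(nn, total, 2),
    )


def filter_scaffolds(
    records: Sequence[SeqRecord], min_len_bp: int = 35_000
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Split scaffolds into (kept, discarded) by a strict length cut.

    Kept scaffolds are strictly longer than ``min_len_bp`` (default 35 kb,
    the cut applied before annotating the assembly); input order is
    preserved in both lists.
    """
    kept = [r for r in records if len(r) > min_len_bp]
    discarded = [r for r in records if len(r) <= min_len_bp]
    return kept, discarded
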
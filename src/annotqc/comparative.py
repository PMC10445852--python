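"""Two-genome comparative analyses.

Orthology is approximated by reciprocal best hits (RBH) between the two
proteomes at a maximum e-value of 1e-10; macrosynteny is summarised by
chaining orthologs into collinear blocks per (scaffold, chromosome)
pair; paralog families are connected components of the within-species
similarity graph; family expansion is tabulated as per-family member
counts in the two species; and conservation of coding lengths is
quantified by an ordinary least-squares regression of log10 CDS lengths
between ortholog pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from annotqc.io_formats import HitRecord, Interval

DEFAULT_MAX_EVALUE = 1e-10


@dataclass
class OrthologPair:
    """A reciprocal-best-hit gene pair, optionally placed on both genomes."""

    gene_a: str
    gene_b: str
    bitscore_ab: float
    bitscore_ba: float
    pos_a: tuple[str, int] | None = None  # (scaffold, midpoint bp)
    pos_b: tuple[str, int] | None = None  # (chromosome, midpoint bp)
    span_a: Interval | None = None
    span_b: Interval | None = None


@dataclass
class SyntenyBlock:
    scaffold_a: str
    chrom_b: str
    pairs: list[OrthologPair]
    orientation: str  # "same" | "inverted"

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ParalogCluster:
    species: str
    members: frozenset[str]
    family: str | None = None

    def __len__(self) -> int:
        return len(self.members)


def best_hits(
    hits: Iterable[HitRecord], max_evalue: float = DEFAULT_MAX_EVALUE
) -> dict[str, str]:
    """Best subject per query: highest bitscore among hits with
    evalue <= max_evalue; ties broken by lower e-value, then by
    lexicographically smaller subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        if h.evalue > max_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None or (-h.bitscore, h.evalue, h.subject_id) < (
            -cur.bitscore, cur.evalue, cur.subject_id
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def reciprocal_best_hits(
    hits_ab: Sequence[HitRecord],
    hits_ba: Sequence[HitRecord],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    pos_a: Mapping[str, tuple[str, int]] | None = None,
    pos_b: Mapping[str, tuple[str, int]] | None = None,
) -> list[OrthologPair]:
    """Pairs (a, b) that are mutually best in both search directions."""
    ab = best_hits(hits_ab, max_evalue)
    ba = best_hits(hits_ba, max_evalue)
    score_ab = {(h.query_id, h.subject_id): h.bitscore for h in hits_ab}
    score_ba = {(h.query_id, h.subject_id): h.bitscore for h in hits_ba}
    pairs = []
    for a, b in sorted(ab.items()):
        if ba.get(b) == a:
            pairs.append(
                OrthologPair(
                    gene_a=a,
                    gene_b=b,
                    bitscore_ab=score_ab.get((a, b), 0.0),
                    bitscore_ba=score_ba.get((b, a), 0.0),
                    pos_a=pos_a.get(a) if pos_a else None,
                    pos_b=pos_b.get(b) if pos_b else None,
                )
            )
    return pairs


def collapse_isoforms(
    hits: Iterable[HitRecord], isoform_to_gene: Mapping[str, str], side: str = "subject"
) -> list[HitRecord]:
    """Optionally collapse protein isoforms to genes, keeping the best-
    scoring isoform hit per (query, gene)."""
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if side == "subject":
            key = (h.query_id, isoform_to_gene.get(h.subject_id, h.subject_id))
        else:
            key = (isoform_to_gene.get(h.query_id, h.query_id), h.subject_id)
        cur = best.get(key)
        if cur is None or h.bitscore > cur.bitscore:
            best[key] = h
    out = []
    for (q, s), h in sorted(best.items()):
        repl = dict(h.__dict__)
        repl["query_id" if side == "query" else "subject_id"] = s if side == "subject" else q
        if side == "query":
            repl["query_id"] = q
        out.append(HitRecord(**repl))
    return out


def chain_synteny(
    pairs: Sequence[OrthologPair],
    min_genes: int = 3,
    max_gap: int = 1_000_000,
) -> list[SyntenyBlock]:
    """Chain positioned ortholog pairs into collinear macrosynteny blocks.

    Within each (scaffold_a, chrom_b) combination, pairs are sorted by
    their position on genome A and greedily extended while positions on
    genome B stay monotone (in either direction, fixed by the first two
    pairs of the chain) and consecutive gaps on both genomes stay within
    ``max_gap``. Chains shorter than ``min_genes`` are discarded.
    Orientation is "same" when B positions increase along the chain.
    """
    by_combo: dict[tuple[str, str], list[OrthologPair]] = {}
    for p in pairs:
        if p.pos_a is None or p.pos_b is None:
            raise ValueError(f"pair {p.gene_a}/{p.gene_b} lacks genome positions")
        by_combo.setdefault((p.pos_a[0], p.pos_b[0]), []).append(p)

    blocks = []
    for (scaf, chrom), combo in sorted(by_combo.items()):
        combo.sort(key=lambda p: (p.pos_a[1], p.gene_a))
        chain: list[OrthologPair] = []
        direction = 0  # 0 unknown, +1 increasing b, -1 decreasing b

        def close() -> None:
            nonlocal chain, direction
            if len(chain) >= min_genes:
                blocks.append(
                    SyntenyBlock(
                        scaffold_a=scaf,
                        chrom_b=chrom,
                        pairs=chain,
                        orientation="inverted" if direction < 0 else "same",
                    )
                )
            chain, direction = [], 0

        for p in combo:
            if not chain:
                chain = [p]
                continue
            prev = chain[-1]
            gap_a = p.pos_a[1] - prev.pos_a[1]
            db = p.pos_b[1] - prev.pos_b[1]
            step = int(np.sign(db))
            ok = (
                gap_a <= max_gap
                and abs(db) <= max_gap
                and step != 0
                and (direction == 0 or step == direction)
            )
            if ok:
                chain.append(p)
                if direction == 0:
                    direction = step
            else:
                close()
                chain = [p]
        close()
    return blocks


def write_links(
    items: Sequence[OrthologPair] | Sequence[SyntenyBlock], path: str | Path
) -> int:
    """Write circos-style link lines: one per ortholog pair, six
    tab-separated fields (scaffold_a, start_a, end_a, chrom_b, start_b,
    end_b), sorted. Returns the number of lines written."""
    pairs: list[OrthologPair] = []
    for item in items:
        if isinstance(item, SyntenyBlock):
            pairs.extend(item.pairs)
        else:
            pairs.append(item)
    lines = []
    for p in pairs:
        sa = p.span_a or (Interval(p.pos_a[1], p.pos_a[1] + 1) if p.pos_a else None)
        sb = p.span_b or (Interval(p.pos_b[1], p.pos_b[1] + 1) if p.pos_b else None)
        if sa is None or sb is None or p.pos_a is None or p.pos_b is None:
            raise ValueError(f"pair {p.gene_a}/{p.gene_b} lacks positions for links")
        lines.append((p.pos_a[0], sa.start, sa.end, p.pos_b[0], sb.start, sb.end))
    lines.sort()
    with open(path, "w") as fh:
        for ln in lines:
            fh.write("\t".join(str(x) for x in ln) + "\n")
    return len(lines)


def paralog_clusters(
    self_hits: Iterable[HitRecord],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    species: str = "",
) -> tuple[list[ParalogCluster], list[str]]:
    """Cluster within-species hits into paralog families.

    Self-pairs (query == subject) and hits above the e-value threshold
    are dropped; clusters are connected components of the remaining
    undirected graph. Genes seen in the hit table but left without any
    surviving edge are returned separately as singletons. Clusters are
    sorted largest first.
    """
    g = nx.Graph()
    seen: set[str] = set()
    for h in self_hits:
        seen.update((h.query_id, h.subject_id))
        if h.query_id != h.subject_id and h.evalue <= max_evalue:
            g.add_edge(h.query_id, h.subject_id)
    clusters = [
        ParalogCluster(species=species, members=frozenset(cc))
        for cc in nx.connected_components(g)
    ]
    clusters.sort(key=lambda c: (-len(c), min(c.members)))
    singletons = sorted(seen - set(g.nodes))
    return clusters, singletons


def expansion_table(
    clusters_a: Sequence[ParalogCluster],
    clusters_b: Sequence[ParalogCluster],
    family_of_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Per-family member counts in species A and B.

    Counts clustered genes per family label; rows sorted by the species-A
    count, descending. The ratio column is the string "inf" when the
    family is absent from species B.
    """
    def counts(clusters: Sequence[ParalogCluster]) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in clusters:
            for g in c.members:
                fam = family_of_gene.get(g)
                if fam is not None:
                    out[fam] = out.get(fam, 0) + 1
        return out

    ca, cb = counts(clusters_a), counts(clusters_b)
    rows = []
    for fam in sorted(set(ca) | set(cb)):
        a, b = ca.get(fam, 0), cb.get(fam, 0)
        rows.append(
            {
                "family": fam,
                "count_a": a,
                "count_b": b,
                "ratio": "inf" if b == 0 else round(a / b, 2),
            }
        )
    df = pd.DataFrame(rows, columns=["family", "count_a", "count_b", "ratio"])
    return df.sort_values(["count_a", "family"], ascending=[False, True]).reset_index(drop=True)


def cds_length_regression(
    cds_len_a: Sequence[float], cds_len_b: Sequence[float], base: float = 10.0
) -> tuple[float, float, float]:
    """OLS regression of log CDS length in species B on species A.

    Returns (intercept, slope, R^2) with logs taken in ``base``
    (default 10; slope and R^2 are base-invariant, the intercept is
    not). Requires at least 3 pairs of strictly positive lengths.
    """
    a = np.asarray(cds_len_a, dtype=float)
    b = np.asarray(cds_len_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("regression requires >= 3 paired lengths")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("regression requires strictly positive lengths")
    x = np.log(a) / np.log(base)
    y = np.log(b) / np.log(base)
    res = stats.linregress(x, y)
    return float(res.intercept), float(res.slope), float(res.rvalue**2)
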
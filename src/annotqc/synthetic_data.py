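"""Synthetic inputs with attached ground truth for every pipeline stage.

Four generators emulate the structure of a real beetle genome project at
desk scale, so that each downstream analysis can be validated against a
planted truth without any sequencing data:

* :func:`simulate_genome` — scaffolds with tandem satellite arrays
  (142-bp monomer) and one scaffold carrying tandem copies of a
  mitochondrion-like reference, the classic coverage-driven
  mis-assembly signature.
* :func:`simulate_annotation` — gene models with controlled intronless
  fraction and UTR ratios, plus evidence records constructed so that
  every retention/removal reason of the gene filter is represented and
  the true label is known by construction.
* :func:`simulate_chimeric_contigs` — transcript contigs, some of which
  fuse two transcripts around a junction with zero consistent-pair
  coverage; junctions are placed outside ORFs/domains except for a
  controlled "unsplittable" subset.
* :func:`simulate_homology` — within- and between-species hit tables
  with planted 1:1 orthologs, collinear gene orders broken by a
  configured number of inversions, and one expanded gene family.

Background sequence is i.i.d. uniform ACGT, which keeps low-complexity
masking behaviour predictable; every draw comes from a single
numpy Generator seeded by ``SimConfig.seed``, so all outputs are
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from annotqc.gene_filter import EvidenceRecord
from annotqc.io_formats import GeneModel, HitRecord, Interval, SeqRecord
from annotqc.transcript_qc import CoverageTrack

# Fixed synthetic 142-bp satellite monomer (a random sequence, not any
# published satellite; the real monomer sequence is not distributed).
SATELLITE_MONOMER_142 = (
    "AAGACGGTATCTAAACACCCGGATCACGCGCCGTTATATGATGTCAGTTTCTCGATGTCGAGCACT"
    "CGCCAAATTAGTCGTAAACTGCGCTGAAGACGAAATTCTGAGCGGACATTTGTGTTCGTCTAGGTACAGTGGCCAG"
)

_BASES = np.array(list("ACGT"))

KEEP_REASON = "KEPT"
REMOVAL_REASONS = ("REPEAT_TE", "UTR_RNA_ONLY", "WEAK_EVIDENCE")


class ConfigError(ValueError):
    """A simulation configuration that cannot be realised."""


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the study's own defaults.

    The satellite monomer is 142 bp and the mitochondrion-like reference
    15,724 bp by default, matching the repeat and organelle sizes the
    pipeline is designed around; sizes and counts are desk-scale.
    """

    seed: int = 0
    # genome
    n_scaffolds: int = 8
    scaffold_len_range: tuple[int, int] = (30_000, 60_000)
    satellite_monomer: str = SATELLITE_MONOMER_142
    satellite_array_counts: tuple[int, ...] = (12, 8, 5, 20)
    satellite_identity_range: tuple[float, float] = (0.85, 1.0)
    mito_len: int = 15_724
    mito_copies: int = 3
    mito_identity_range: tuple[float, float] = (0.85, 0.89)
    # annotation
    n_genes: int = 60
    intronless_fraction: float = 0.27
    utr_ratio_range: tuple[float, float] = (0.05, 0.70)
    frac_repeat_te: float = 0.15
    frac_utr_rna_only: float = 0.10
    frac_weak_evidence: float = 0.10
    # transcript contigs
    n_contigs: int = 200
    chimera_fraction: float = 0.30
    junction_gap: int = 40
    unsplittable_fraction: float = 0.10
    # homology / synteny
    n_orthologs: int = 500
    n_hom_scaffolds: int = 4
    n_species_specific: int = 50
    n_expanded_family: int = 20
    expanded_family_size_b: int = 2
    rearrangement_ops: int = 2
    inversion_len: int = 5
    score_noise: float = 5.0
    gene_spacing: int = 10_000

    def __post_init__(self) -> None:
        for name in (
            "n_scaffolds", "mito_len", "mito_copies", "n_genes", "n_contigs",
            "n_orthologs", "n_hom_scaffolds", "n_species_specific",
            "n_expanded_family", "rearrangement_ops",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "intronless_fraction", "frac_repeat_te", "frac_utr_rna_only",
            "frac_weak_evidence", "chimera_fraction", "unsplittable_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Planted truth, filled in piecewise by the four generators."""

    # genome part
    satellite_intervals: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    mito_scaffold: str | None = None
    mito_reference: str | None = None
    mito_intervals: list[tuple[int, int, float]] = field(default_factory=list)
    # annotation part
    gene_labels: dict[str, str] = field(default_factory=dict)
    # chimera part
    chimera_breaks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    unsplittable: set[str] = field(default_factory=set)
    # homology part
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    pos_a: dict[str, tuple[str, int]] = field(default_factory=dict)
    pos_b: dict[str, tuple[str, int]] = field(default_factory=dict)
    expected_blocks: dict[tuple[str, str], int] = field(default_factory=dict)
    expanded_family: dict[str, list[str]] = field(default_factory=dict)
    family_of_gene: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _degrade(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute bases so the copy has approximately the given identity."""
    n_mut = int(round((1.0 - identity) * len(seq)))
    if n_mut == 0:
        return seq
    out = list(seq)
    for pos in rng.choice(len(seq), size=n_mut, replace=False):
        out[pos] = str(rng.choice([b for b in "ACGT" if b != out[pos]]))
    return "".join(out)


# ---------------------------------------------------------------------------
# genome


def simulate_genome(config: SimConfig) -> tuple[list[SeqRecord], GroundTruth]:
    """Scaffolds with planted satellite arrays and a tandem-multiplied
    mitochondrion-like region on the first scaffold.

    Satellite arrays are tandem monomer copies, each degraded to an
    identity drawn from ``satellite_identity_range``; per-copy intervals
    and realised identities go into the truth. Raises
    :class:`ConfigError` when a planted feature does not fit.
    """
    rng = config.rng()
    n_arrays = len(config.satellite_array_counts)
    if config.n_scaffolds < n_arrays + (1 if config.mito_copies else 0):
        raise ConfigError("not enough scaffolds to host the planted features")

    truth = GroundTruth()
    scaffolds: list[SeqRecord] = []
    lo, hi = config.scaffold_len_range
    lengths = rng.integers(lo, hi + 1, config.n_scaffolds)

    mono = config.satellite_monomer.upper()
    mito_ref = _random_seq(rng, config.mito_len) if config.mito_copies else None
    truth.mito_reference = mito_ref

    for i in range(config.n_scaffolds):
        sid = f"scaffold_{i + 1}"
        n = int(lengths[i])
        if i == 0 and config.mito_copies:
            # tandem mito-like copies with 1-kb flanks
            body = []
            pos = 1000
            for _ in range(config.mito_copies):
                ident = rng.uniform(*config.mito_identity_range)
                copy = _degrade(rng, mito_ref, ident)
                body.append(copy)
                truth.mito_intervals.append((pos, pos + len(copy), ident))
                pos += len(copy)
            seq = _random_seq(rng, 1000) + "".join(body) + _random_seq(rng, 1000)
            truth.mito_scaffold = sid
            scaffolds.append(SeqRecord(id=sid, seq=seq))
            continue

        seq = list(_random_seq(rng, n))
        array_idx = i - (1 if config.mito_copies else 0)
        if 0 <= array_idx < n_arrays:
            count = config.satellite_array_counts[array_idx]
            need = count * len(mono)
            if need + 2000 >= n:
                raise ConfigError(
                    f"{sid}: satellite array of {count} copies ({need} bp) exceeds scaffold"
                )
            start = int(rng.integers(1000, n - need - 1000))
            pos = start
            ivs = []
            for _ in range(count):
                ident = rng.uniform(*config.satellite_identity_range)
                copy = _degrade(rng, mono, ident)
                seq[pos: pos + len(copy)] = copy
                ivs.append((pos, pos + len(copy), ident))
                pos += len(copy)
            truth.satellite_intervals[sid] = ivs
        scaffolds.append(SeqRecord(id=sid, seq="".join(seq)))
    return scaffolds, truth


# ---------------------------------------------------------------------------
# annotation


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    scaffold_id: str,
    offset: int,
    intronless: bool,
    utr_ratio: float,
) -> GeneModel:
    n_exons = 1 if intronless else int(rng.integers(2, 7))
    exon_lens = rng.integers(120, 401, n_exons)
    intron_lens = rng.integers(60, 801, max(n_exons - 1, 0))
    exons = []
    pos = offset
    for k in range(n_exons):
        exons.append(Interval(pos, pos + int(exon_lens[k])))
        pos += int(exon_lens[k])
        if k < n_exons - 1:
            pos += int(intron_lens[k])
    spliced = int(exon_lens.sum())
    utr_len = min(int(round(utr_ratio * spliced)), spliced - 1)
    # 5'-UTR occupies the first utr_len spliced bases, CDS the rest
    cds, utr = [], []
    consumed = 0
    for e in exons:
        e_len = len(e)
        u_here = max(0, min(utr_len - consumed, e_len))
        if u_here:
            utr.append(Interval(e.start, e.start + u_here))
        if u_here < e_len:
            cds.append(Interval(e.start + u_here, e.end))
        consumed += e_len
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(
        gene_id=gene_id, scaffold_id=scaffold_id, strand=strand,
        exons=exons, cds=cds, utr=utr,
    )


def simulate_annotation(
    config: SimConfig, genome: list[SeqRecord]
) -> tuple[list[GeneModel], list[EvidenceRecord], GroundTruth]:
    """Gene models plus evidence records with known filter labels.

    Labels are assigned first (fractions from the config), then the gene
    geometry and evidence are drawn so that the filtering cascade, run at
    default thresholds, must reproduce the label: e.g. a REPEAT_TE gene
    gets repeat coverage above 0.9 (or a TE tag) and no pfam/blastp hit,
    a UTR_RNA_ONLY gene is intronless with a UTR ratio above 0.8 and
    RNA-only support. KEEP genes cycle through the distinct ways a gene
    can be retained (pfam/blastp hit, multi-exon with clean evidence,
    two mRNA samples, mRNA+protein support, curated same-species protein).
    """
    if not genome:
        raise ConfigError("simulate_annotation requires a genome")
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_genes
    n_rep = int(round(config.frac_repeat_te * n))
    n_utr = int(round(config.frac_utr_rna_only * n))
    n_weak = int(round(config.frac_weak_evidence * n))
    # intronless-only removal reasons cannot exceed the intronless budget
    target = int(round(config.intronless_fraction * n))
    n_utr = min(n_utr, target)
    n_weak = min(n_weak, max(0, target - n_utr))
    labels = (
        ["REPEAT_TE"] * n_rep + ["UTR_RNA_ONLY"] * n_utr
        + ["WEAK_EVIDENCE"] * n_weak + [KEEP_REASON] * (n - n_rep - n_utr - n_weak)
    )
    rng.shuffle(labels)

    # intronless flags: forced for the intronless-only removal reasons,
    # topped up elsewhere to approach the configured fraction
    intronless = [lab in ("UTR_RNA_ONLY", "WEAK_EVIDENCE") for lab in labels]
    deficit = target - sum(intronless)
    open_idx = [i for i, f in enumerate(intronless) if not f]
    if deficit > 0 and open_idx:
        for i in rng.choice(open_idx, size=min(deficit, len(open_idx)), replace=False):
            intronless[i] = True

    models, evidence = [], []
    truth = GroundTruth()
    cursors = {s.id: 200 for s in genome}
    keep_variant = 0
    for i, lab in enumerate(labels):
        gid = f"gene_{i + 1:05d}"
        if lab == "UTR_RNA_ONLY":
            utr_ratio = rng.uniform(0.85, 0.95)
        elif lab == KEEP_REASON and intronless[i]:
            utr_ratio = rng.uniform(0.05, 0.70)  # keep clear of the UTR rule
        else:
            utr_ratio = rng.uniform(*config.utr_ratio_range)

        scaffold = genome[i % len(genome)]
        offset = cursors[scaffold.id]
        model = _build_gene(rng, gid, scaffold.id, offset, intronless[i], utr_ratio)
        cursors[scaffold.id] = model.span.end + int(rng.integers(200, 600))
        models.append(model)
        real_ratio = model.utr_ratio

        if lab == "REPEAT_TE":
            by_te = rng.random() < 0.5
            ev = EvidenceRecord(
                gene_id=gid, has_pfam=False, has_blastp=False,
                repeat_cov=float(rng.uniform(0.91, 1.0)) if not by_te else float(rng.uniform(0.0, 0.5)),
                te_tagged=by_te,
                n_mrna_samples=int(rng.integers(0, 3)),
                n_protein_species=int(rng.integers(0, 3)),
                has_self_uniprot=False, utr_ratio=real_ratio,
            )
        elif lab == "UTR_RNA_ONLY":
            ev = EvidenceRecord(
                gene_id=gid, has_pfam=False, has_blastp=False,
                repeat_cov=float(rng.uniform(0.0, 0.5)), te_tagged=False,
                n_mrna_samples=int(rng.integers(1, 4)), n_protein_species=0,
                has_self_uniprot=False, utr_ratio=real_ratio,
            )
        elif lab == "WEAK_EVIDENCE":
            ev = EvidenceRecord(
                gene_id=gid, has_pfam=False, has_blastp=False,
                repeat_cov=float(rng.uniform(0.0, 0.5)), te_tagged=False,
                n_mrna_samples=int(rng.integers(0, 2)), n_protein_species=0,
                has_self_uniprot=False, utr_ratio=real_ratio,
            )
        else:  # KEEP, cycling through the retention routes
            keep_variant += 1
            v = keep_variant % 5
            has_pfam = v == 0
            has_blastp = v == 1
            if intronless[i] and v >= 2:
                n_mrna, n_prot, self_up = {
                    2: (2, 0, False), 3: (1, 1, False), 4: (0, 0, True)
                }[v]
            else:
                n_mrna, n_prot, self_up = int(rng.integers(1, 4)), int(rng.integers(1, 3)), False
            ev = EvidenceRecord(
                gene_id=gid, has_pfam=has_pfam, has_blastp=has_blastp,
                repeat_cov=float(rng.uniform(0.0, 0.89)),
                te_tagged=bool(has_pfam or has_blastp) and rng.random() < 0.3,
                n_mrna_samples=n_mrna, n_protein_species=n_prot,
                has_self_uniprot=self_up, utr_ratio=real_ratio,
            )
        evidence.append(ev)
        truth.gene_labels[gid] = lab
    return models, evidence, truth


# ---------------------------------------------------------------------------
# chimeric transcript contigs


def simulate_chimeric_contigs(
    config: SimConfig,
) -> tuple[
    list[SeqRecord],
    dict[str, CoverageTrack],
    dict[str, list[Interval]],
    dict[str, list[Interval]],
    GroundTruth,
]:
    """Transcript contigs with planted chimeric junctions.

    A chimeric contig concatenates two transcripts; the first
    ``junction_gap`` bases after the junction carry zero consistent-pair
    coverage while everything else is covered. ORF and domain intervals
    are placed away from the junction except for the configured
    unsplittable subset, whose junction falls inside an ORF. Returns
    (contigs, coverage tracks, ORF BED intervals, domain BED intervals,
    truth).
    """
    rng = np.random.default_rng(config.seed + 2)
    contigs: list[SeqRecord] = []
    tracks: dict[str, CoverageTrack] = {}
    orfs: dict[str, list[Interval]] = {}
    domains: dict[str, list[Interval]] = {}
    truth = GroundTruth()

    n_chim = int(round(config.chimera_fraction * config.n_contigs))
    n_unsplit = int(round(config.unsplittable_fraction * n_chim))
    kinds = ["unsplittable"] * n_unsplit + ["chimera"] * (n_chim - n_unsplit)
    kinds += ["clean"] * (config.n_contigs - len(kinds))
    rng.shuffle(kinds)

    gap = config.junction_gap
    for i, kind in enumerate(kinds):
        cid = f"contig_{i + 1:04d}"
        base_depth = int(rng.integers(5, 31))
        if kind == "clean":
            n = int(rng.integers(400, 1501))
            seq = _random_seq(rng, n)
            depth = np.full(n, base_depth, dtype=int)
            orfs[cid] = [Interval(50, min(350, n - 10))]
            domains[cid] = []
            truth.chimera_breaks[cid] = []
        else:
            l1 = int(rng.integers(400, 1201))
            l2 = int(rng.integers(400, 1201))
            n = l1 + l2
            seq = _random_seq(rng, n)
            depth = np.full(n, base_depth, dtype=int)
            depth[l1: l1 + gap] = 0
            if kind == "chimera":
                orfs[cid] = [Interval(50, l1 - 50), Interval(l1 + gap + 50, n - 50)]
                domains[cid] = [Interval(60, l1 - 60)] if rng.random() < 0.5 else []
                truth.chimera_breaks[cid] = [(l1, l1 + gap)]
            else:  # junction buried inside an ORF: no legal break
                orfs[cid] = [Interval(l1 - 100, l1 + gap + 100)]
                domains[cid] = []
                truth.chimera_breaks[cid] = [(l1, l1 + gap)]
                truth.unsplittable.add(cid)
        minus = rng.random() < 0.2
        plus_pairs = int(rng.integers(20, 51))
        minus_pairs = int(rng.integers(0, 10))
        if minus:
            plus_pairs, minus_pairs = minus_pairs, plus_pairs
        contigs.append(SeqRecord(id=cid, seq=seq))
        tracks[cid] = CoverageTrack(
            contig_id=cid, depth=depth, plus_pairs=plus_pairs, minus_pairs=minus_pairs
        )
    return contigs, tracks, orfs, domains, truth


# ---------------------------------------------------------------------------
# homology / synteny / paralogs


@dataclass
class HomologySim:
    hits_ab: list[HitRecord]
    hits_ba: list[HitRecord]
    hits_aa: list[HitRecord]
    hits_bb: list[HitRecord]
    truth: GroundTruth


def _hit(q: str, s: str, bitscore: float, evalue: float = 1e-120) -> HitRecord:
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=90.0, aln_len=300,
        mismatches=30, gaps=0, qstart=1, qend=300, sstart=1, send=300,
        evalue=evalue, bitscore=round(bitscore, 1),
    )


def simulate_homology(config: SimConfig) -> HomologySim:
    """Hit tables with planted orthologs, inversions and one expanded family.

    Orthologs are distributed evenly over ``n_hom_scaffolds`` scaffold /
    chromosome pairs with collinear positions; each configured
    rearrangement inverts an interior run of ``inversion_len`` ortholog
    positions on a distinct scaffold pair, adding exactly two synteny
    breakpoints there (the truth records the expected block count per
    pair). Ortholog hits score around 500 with additive uniform noise of
    half-width ``score_noise`` (set 0 for exact tests); decoy hits score
    around 300, so planted best hits stay best for any noise below 100.
    Species-specific genes only receive hits above the e-value cutoff
    and an expanded family (default 20 members in A vs 2 in B) is wired
    as an all-vs-all within-species clique.
    """
    rng = np.random.default_rng(config.seed + 3)
    truth = GroundTruth()
    k = config.n_hom_scaffolds
    per = config.n_orthologs // k
    counts = [per + (1 if i < config.n_orthologs % k else 0) for i in range(k)]

    def noise() -> float:
        return float(rng.uniform(-config.score_noise, config.score_noise)) if config.score_noise else 0.0

    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    idx = 0
    b_pos_of: dict[str, int] = {}
    for s in range(k):
        scaf, chrom = f"scaffA_{s + 1}", f"chrB_{s + 1}"
        genes = []
        for j in range(counts[s]):
            idx += 1
            a, b = f"ta_{idx:05d}", f"tb_{idx:05d}"
            genes.append((a, b))
            truth.ortholog_pairs.append((a, b))
            truth.pos_a[a] = (scaf, (j + 1) * config.gene_spacing)
            b_pos_of[b] = j
        # invert an interior run on the first `rearrangement_ops` pairs
        order = list(range(counts[s]))
        n_bp = 0
        if s < config.rearrangement_ops and counts[s] >= config.inversion_len + 6:
            start = int(rng.integers(3, counts[s] - config.inversion_len - 3))
            order[start: start + config.inversion_len] = reversed(
                order[start: start + config.inversion_len]
            )
            n_bp = 2
        truth.expected_blocks[(scaf, chrom)] = 1 + n_bp
        for j, (a, b) in enumerate(genes):
            rank = order.index(j)
            truth.pos_b[b] = (chrom, (rank + 1) * config.gene_spacing)
        for j, (a, b) in enumerate(genes):
            hits_ab.append(_hit(a, b, 500 + noise()))
            hits_ba.append(_hit(b, a, 500 + noise()))
            if j + 1 < len(genes):  # decoy second-best hits
                hits_ab.append(_hit(a, genes[j + 1][1], 300 + noise(), evalue=1e-60))
                hits_ba.append(_hit(b, genes[j + 1][0], 300 + noise(), evalue=1e-60))

    # species-specific genes: only weak hits above the e-value cutoff
    for j in range(config.n_species_specific):
        a, b = f"sa_{j + 1:04d}", f"sb_{j + 1:04d}"
        partner_b = f"tb_{(j % max(idx, 1)) + 1:05d}"
        partner_a = f"ta_{(j % max(idx, 1)) + 1:05d}"
        hits_ab.append(_hit(a, partner_b, 60.0, evalue=1e-5))
        hits_ba.append(_hit(b, partner_a, 60.0, evalue=1e-5))

    # within-species hits: expanded family cliques + background clusters
    hits_aa: list[HitRecord] = []
    hits_bb: list[HitRecord] = []

    def clique(prefix: str, label: str, size: int, out: list[HitRecord]) -> list[str]:
        members = [f"{prefix}_{label}_{i + 1:03d}" for i in range(size)]
        for x in members:
            truth.family_of_gene[x] = label
        for i, x in enumerate(members):
            for y in members[i + 1:]:
                out.append(_hit(x, y, 400 + noise(), evalue=1e-80))
        return members

    fam_a = clique("pa", "HISTONE", config.n_expanded_family, hits_aa)
    fam_b = clique("pb", "HISTONE", config.expanded_family_size_b, hits_bb)
    truth.expanded_family = {"A": fam_a, "B": fam_b}
    for label, size_a, size_b in (("ANKYRIN", 4, 3), ("ABC", 3, 2)):
        clique("pa", label, size_a, hits_aa)
        clique("pb", label, size_b, hits_bb)
    # self-only hits: genes that must come out as singletons
    for j in range(5):
        g = f"pa_SINGLE_{j + 1:02d}"
        hits_aa.append(_hit(g, g, 600.0))

    return HomologySim(
        hits_ab=hits_ab, hits_ba=hits_ba, hits_aa=hits_aa, hits_bb=hits_bb, truth=truth
    )


# ---------------------------------------------------------------------------
# ortholog CDS lengths for the regression


def simulate_cds_lengths(
    n: int = 10_000,
    intercept: float = 0.508,
    slope: float = 0.939,
    sigma: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired ortholog CDS lengths following a log-linear model.

    log10(len_b) = intercept + slope * log10(len_a) + N(0, sigma), with
    log10(len_a) uniform over [2, 4] (CDS lengths of 100 bp to 10 kb).
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(2.0, 4.0, n)
    y = intercept + slope * x + rng.normal(0.0, sigma, n)
    return 10.0**x, 10.0**y
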
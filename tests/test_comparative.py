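import numpy as np
import pytest

from annotqc.comparative import (
    OrthologPair,
    best_hits,
    cds_length_regression,
    chain_synteny,
    expansion_table,
    paralog_clusters,
    reciprocal_best_hits,
    write_links,
)
from annotqc.io_formats import HitRecord
from annotqc.synthetic_data import SimConfig, simulate_homology


def hit(q, s, bitscore, evalue=1e-50):
    return HitRecord(
        query_id=q, subject_id=s, pct_identity=90.0, aln_len=100, mismatches=10,
        gaps=0, qstart=1, qend=100, sstart=1, send=100, evalue=evalue, bitscore=bitscore,
    )


class TestBestHits:
    def test_highest_bitscore_wins(self):
        assert best_hits([hit("q1", "s1", 200), hit("q1", "s2", 150)]) == {"q1": "s1"}

    def test_evalue_threshold_is_inclusive_max(self):
        assert best_hits([hit("q1", "s1", 200, evalue=1e-9)]) == {}
        assert best_hits([hit("q1", "s1", 200, evalue=1e-10)]) == {"q1": "s1"}

    def test_tie_breaking_lower_evalue_then_lexicographic(self):
        hits = [hit("q", "sB", 100, 1e-30), hit("q", "sA", 100, 1e-40)]
        assert best_hits(hits) == {"q": "sA"}
        hits = [hit("q", "sB", 100, 1e-30), hit("q", "sA", 100, 1e-30)]
        assert best_hits(hits) == {"q": "sA"}

    def test_matches_exhaustive_argmax_oracle(self, rng):
        hits = [
            hit(f"q{i}", f"s{j}", float(rng.integers(50, 500)))
            for i in range(20)
            for j in rng.choice(30, size=5, replace=False)
        ]
        got = best_hits(hits)
        for q in {h.query_id for h in hits}:
            qhits = [h for h in hits if h.query_id == q and h.evalue <= 1e-10]
            expected = min(qhits, key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
            assert got[q] == expected.subject_id


class TestReciprocalBestHits:
    def test_mutual_best_pair(self):
        pairs = reciprocal_best_hits([hit("a1", "b1", 300)], [hit("b1", "a1", 290)])
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]

    def test_asymmetric_best_no_pair(self):
        ab = [hit("a1", "b1", 300)]
        ba = [hit("b1", "a2", 400), hit("b1", "a1", 300)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_noise_free_planted_orthologs_recovered_exactly(self, small_config):
        hom = simulate_homology(small_config)
        pairs = reciprocal_best_hits(hom.hits_ab, hom.hits_ba)
        assert {(p.gene_a, p.gene_b) for p in pairs} == set(hom.truth.ortholog_pairs)

    def test_symmetry_under_species_swap(self, small_config):
        hom = simulate_homology(small_config)
        fwd = reciprocal_best_hits(hom.hits_ab, hom.hits_ba)
        rev = reciprocal_best_hits(hom.hits_ba, hom.hits_ab)
        assert {(p.gene_a, p.gene_b) for p in fwd} == {(p.gene_b, p.gene_a) for p in rev}


def pair(i, pa, pb, scaf="s1", chrom="c1"):
    return OrthologPair(
        gene_a=f"a{i}", gene_b=f"b{i}", bitscore_ab=100, bitscore_ba=100,
        pos_a=(scaf, pa), pos_b=(chrom, pb),
    )


def chain_oracle(pairs, min_genes=3, max_gap=1_000_000):
    """Naive maximal-run chaining: re-check the whole chain at every step."""
    def valid(chain):
        if len(chain) < 2:
            return True
        steps = [b.pos_b[1] - a.pos_b[1] for a, b in zip(chain, chain[1:])]
        gaps_a = [b.pos_a[1] - a.pos_a[1] for a, b in zip(chain, chain[1:])]
        if any(s == 0 for s in steps):
            return False
        if any(abs(s) > max_gap for s in steps) or any(g > max_gap for g in gaps_a):
            return False
        return all(s > 0 for s in steps) or all(s < 0 for s in steps)

    by_combo = {}
    for p in pairs:
        by_combo.setdefault((p.pos_a[0], p.pos_b[0]), []).append(p)
    blocks = []
    for combo in by_combo.values():
        combo = sorted(combo, key=lambda p: (p.pos_a[1], p.gene_a))
        chain = []
        for p in combo:
            if valid(chain + [p]):
                chain.append(p)
            else:
                if len(chain) >= min_genes:
                    blocks.append(chain)
                chain = [p]
        if len(chain) >= min_genes:
            blocks.append(chain)
    return {tuple(p.gene_a for p in b) for b in blocks}


class TestChainSynteny:
    def test_collinear_single_block(self):
        pairs = [pair(i, i * 1000, i * 2000) for i in range(10)]
        (block,) = chain_synteny(pairs)
        assert len(block) == 10 and block.orientation == "same"

    def test_inverted_run_is_its_own_block(self):
        pb = [0, 1, 2, 3, 7, 6, 5, 4, 8, 9, 10, 11]
        pairs = [pair(i, i * 1000, pb[i] * 1000) for i in range(12)]
        blocks = chain_synteny(pairs)
        assert chain_oracle(pairs) == {tuple(p.gene_a for p in b.pairs) for b in blocks}
        assert sorted(b.orientation for b in blocks).count("inverted") >= 1

    def test_sparse_pairs_make_no_blocks(self):
        pairs = [pair(i, 1000, 1000, scaf=f"s{i}", chrom=f"c{i}") for i in range(5)]
        assert chain_synteny(pairs, min_genes=3) == []

    def test_max_gap_splits_chain(self):
        pairs = [pair(0, 0, 0), pair(1, 1000, 1000), pair(2, 2000, 2000),
                 pair(3, 5_000_000, 5_000_000), pair(4, 5_001_000, 5_001_000),
                 pair(5, 5_002_000, 5_002_000)]
        blocks = chain_synteny(pairs, max_gap=1_000_000)
        assert [len(b) for b in blocks] == [3, 3]

    def test_greedy_equals_exhaustive_on_random_small_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 13))
            pb = rng.permutation(n)
            pairs = [pair(i, i * 1000, int(pb[i]) * 1000) for i in range(n)]
            got = {tuple(p.gene_a for p in b.pairs) for b in chain_synteny(pairs)}
            assert got == chain_oracle(pairs)

    def test_every_gene_in_at_most_one_block(self, small_config):
        hom = simulate_homology(small_config)
        pairs = reciprocal_best_hits(
            hom.hits_ab, hom.hits_ba, pos_a=hom.truth.pos_a, pos_b=hom.truth.pos_b
        )
        blocks = chain_synteny(pairs)
        genes = [p.gene_a for b in blocks for p in b.pairs]
        assert len(genes) == len(set(genes))

    def test_planted_rearrangements_give_expected_block_counts(self, small_config):
        hom = simulate_homology(small_config)
        pairs = reciprocal_best_hits(
            hom.hits_ab, hom.hits_ba, pos_a=hom.truth.pos_a, pos_b=hom.truth.pos_b
        )
        blocks = chain_synteny(pairs)
        counts = {}
        for b in blocks:
            counts[(b.scaffold_a, b.chrom_b)] = counts.get((b.scaffold_a, b.chrom_b), 0) + 1
        assert counts == hom.truth.expected_blocks


class TestWriteLinks:
    def test_one_pair_one_line(self, tmp_path):
        p = pair(1, 150, 5050)
        path = tmp_path / "links.tsv"
        n = write_links([p], path)
        assert n == 1
        assert path.read_text() == "s1\t150\t151\tc1\t5050\t5051\n"

    def test_empty_input(self, tmp_path):
        path = tmp_path / "links.tsv"
        assert write_links([], path) == 0 and path.read_text() == ""

    def test_line_count_equals_pair_count(self, tmp_path, rng):
        pairs = [pair(i, int(rng.integers(1e6)), int(rng.integers(1e6))) for i in range(37)]
        path = tmp_path / "links.tsv"
        assert write_links(pairs, path) == 37
        assert len(path.read_text().splitlines()) == 37


class UnionFind:
    def __init__(self):
        self.parent = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


class TestParalogClusters:
    def test_transitive_chain_one_cluster(self):
        clusters, _ = paralog_clusters([hit("a", "b", 100), hit("b", "c", 100)])
        assert [c.members for c in clusters] == [frozenset({"a", "b", "c"})]

    def test_self_hits_only_are_singletons(self):
        clusters, singles = paralog_clusters([hit("a", "a", 500), hit("b", "b", 400)])
        assert clusters == [] and singles == ["a", "b"]

    def test_evalue_threshold_breaks_edges(self):
        clusters, singles = paralog_clusters(
            [hit("a", "b", 100, evalue=1e-5)], max_evalue=1e-10
        )
        assert clusters == [] and singles == ["a", "b"]

    def test_partition_matches_union_find_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            edges = [
                (f"g{rng.integers(n)}", f"g{rng.integers(n)}")
                for _ in range(int(rng.integers(1, 3 * n)))
            ]
            hits = [hit(a, b, 100) for a, b in edges]
            clusters, singles = paralog_clusters(hits)
            uf = UnionFind()
            seen = set()
            for a, b in edges:
                seen.update((a, b))
                if a != b:
                    uf.union(a, b)
            expected = {}
            for g in seen:
                expected.setdefault(uf.find(g), set()).add(g)
            expected_clusters = {frozenset(v) for v in expected.values() if len(v) > 1}
            expected_singles = sorted(g for v in expected.values() if len(v) == 1 for g in v)
            assert {c.members for c in clusters} == expected_clusters
            assert singles == expected_singles


class TestExpansionTable:
    def _cluster(self, members, species="A"):
        from annotqc.comparative import ParalogCluster

        return ParalogCluster(species=species, members=frozenset(members))

    def test_planted_family_counts(self):
        fam = {f"a{i}": "HIST" for i in range(20)} | {f"b{i}": "HIST" for i in range(2)}
        tab = expansion_table(
            [self._cluster([f"a{i}" for i in range(20)])],
            [self._cluster([f"b{i}" for i in range(2)], species="B")],
            fam,
        )
        assert tab.iloc[0].tolist() == ["HIST", 20, 2, 10.0]

    def test_family_absent_in_b_gives_inf(self):
        fam = {f"a{i}": "AFP" for i in range(3)}
        tab = expansion_table([self._cluster(["a0", "a1", "a2"])], [], fam)
        assert tab.iloc[0]["ratio"] == "inf"

    def test_empty_input(self):
        assert expansion_table([], [], {}).empty


class TestCdsLengthRegression:
    def test_identical_lengths_identity_line(self):
        lens = np.array([100.0, 500.0, 2000.0, 12.0])
        a, b, r2 = cds_length_regression(lens, lens)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert b == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_exact_log_line(self):
        a, b, r2 = cds_length_regression([1, 10, 100], [10, 100, 1000])
        assert (a, b, r2) == (pytest.approx(1.0), pytest.approx(1.0), pytest.approx(1.0))

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(2, 4, 500)
        y = 0.5 + 0.9 * x + rng.normal(0, 0.1, 500)
        a, b, r2 = cds_length_regression(10.0**x, 10.0**y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        assert b == pytest.approx(slope) and a == pytest.approx(intercept)
        ss_res = ((y - intercept - slope * x) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert r2 == pytest.approx(1 - ss_res / ss_tot)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            cds_length_regression([1, 2], [1, 2])
        with pytest.raises(ValueError):
            cds_length_regression([1, 0, 3], [1, 2, 3])
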
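import math

import numpy as np
import pytest

from cmline.cluster_filter import (
    AlignerParams,
    Cluster,
    build_clusters,
    filter_coding,
    filter_known,
    karlin_altschul_lambda,
    pairwise_hits,
    read_pvalue_table,
)
from cmline.io_formats import CmlineError, PairwiseHit, SeqRecord
from oracles import UnionFind


def _hit(query, subject, evalue=1e-20):
    return PairwiseHit(query, subject, 100.0, 50, 0, 0, 1, 50, 1, 50, evalue, 90.0)


def _random_record(rid, length, rng):
    return SeqRecord(rid, "".join("ACGU"[k] for k in rng.integers(0, 4, length)))


class TestAligner:
    def test_identical_sequences_give_strong_full_length_hit(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGU"[k] for k in rng.integers(0, 4, 100))
        (hit,) = pairwise_hits([SeqRecord("a", seq), SeqRecord("b", seq)])
        assert hit.evalue < 1e-30
        assert (hit.qstart, hit.qend) == (1, 100)
        assert hit.pident == 100.0

    def test_independent_random_sequences_rarely_hit(self):
        n_with_hit = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = _random_record("a", 100, rng)
            b = _random_record("b", 100, rng)
            n_with_hit += bool(pairwise_hits([a, b]))
        assert n_with_hit <= 1  # >= 99/100 trials hit-free at E <= 1e-6

    def test_lambda_satisfies_karlin_altschul_identity(self):
        lam = karlin_altschul_lambda(2, -3)
        # independent check: plug back into sum p_i p_j exp(lambda s_ij) = 1
        total = sum(
            0.0625 * math.exp(lam * (2 if i == j else -3))
            for i in range(4) for j in range(4)
        )
        assert abs(total - 1.0) < 1e-9
        # and against an independent bisection on the same identity
        lo, hi = 1e-9, 4.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            val = sum(0.0625 * math.exp(mid * (2 if i == j else -3))
                      for i in range(4) for j in range(4))
            lo, hi = (mid, hi) if val < 1.0 else (lo, mid)
        assert lam == pytest.approx(0.5 * (lo + hi), abs=1e-6)

    def test_all_n_record_skipped_with_warning(self):
        rng = np.random.default_rng(2)
        records = [_random_record("a", 60, rng), SeqRecord("n", "N" * 60)]
        with pytest.warns(UserWarning, match="all N"):
            pairwise_hits(records)

    def test_invalid_params_rejected(self):
        with pytest.raises(CmlineError):
            AlignerParams(word_size=3)
        with pytest.raises(CmlineError):
            AlignerParams(evalue_cutoff=0)


class TestClustering:
    def test_transitive_component(self):
        clusters = build_clusters([_hit("a", "b"), _hit("b", "c")])
        assert len(clusters) == 1
        assert clusters[0].members == ["a", "b", "c"]
        assert clusters[0].id == "cluster-a"

    def test_no_hits_no_clusters(self):
        assert build_clusters([]) == []

    def test_min_size_enforced(self):
        assert build_clusters([_hit("a", "b")], min_size=3) == []
        assert len(build_clusters([_hit("a", "b")], min_size=2)) == 1

    def test_matches_union_find_oracle_on_random_graphs(self):
        rng = np.random.default_rng(77)
        for _ in range(500):
            n = int(rng.integers(2, 30))
            nodes = [f"n{k}" for k in range(n)]
            edges = []
            for _ in range(rng.integers(0, 40)):
                a, b = rng.integers(0, n, 2)
                if a != b:
                    edges.append((nodes[a], nodes[b]))
            uf = UnionFind()
            for a, b in edges:
                uf.union(a, b)
            expected = {c for c in uf.components() if len(c) >= 3}
            got = {frozenset(c.members) for c in
                   build_clusters([_hit(a, b) for a, b in edges])}
            assert got == expected

    def test_order_independence(self):
        rng = np.random.default_rng(123)
        edges = [(f"n{rng.integers(0, 20)}", f"n{rng.integers(0, 20)}")
                 for _ in range(30)]
        edges = [(a, b) for a, b in edges if a != b]
        forward = build_clusters([_hit(a, b) for a, b in edges])
        backward = build_clusters([_hit(b, a) for a, b in reversed(edges)])
        assert [c.members for c in forward] == [c.members for c in backward]


class TestFilters:
    def test_known_rna_removal_cascades_to_min_size(self):
        clusters = [Cluster("c1", ["a", "b", "c"])]
        out = filter_known(clusters, [_hit("a", "RF00001", 1e-12)], min_size=3)
        assert out == []  # member removed, cluster falls below min_size

    def test_boundary_evalue_retains_member(self):
        clusters = [Cluster("c1", ["a", "b", "c"])]
        out = filter_known(clusters, [_hit("a", "RF00001", 1e-8)], min_size=3)
        assert out[0].members == ["a", "b", "c"]  # cutoff is <= 1e-9

    def test_known_filter_matches_set_difference_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            members = [f"m{k}" for k in range(int(rng.integers(3, 12)))]
            flagged = {m for m in members if rng.random() < 0.3}
            hits = [_hit(m, "lib", 1e-12) for m in flagged]
            out = filter_known([Cluster("c", list(members))], hits, min_size=1)
            assert out[0].members == [m for m in members if m not in flagged]

    @pytest.mark.parametrize("p,survives", [(0.0001, False), (0.5, True)])
    def test_coding_filter_threshold(self, p, survives):
        out = filter_coding([Cluster("c1", ["a", "b", "c"])], {"c1": p})
        assert bool(out) is survives

    def test_untested_cluster_retained_and_flagged(self):
        (out,) = filter_coding([Cluster("c1", ["a", "b", "c"])], {})
        assert any("untested" in entry[2] for entry in out.filter_log)

    def test_mixed_table_matches_filter_oracle(self):
        rng = np.random.default_rng(8)
        clusters = [Cluster(f"c{k}", [f"c{k}m{j}" for j in range(3)])
                    for k in range(20)]
        pvalues = {f"c{k}": float(rng.random() * 0.01) for k in range(20)}
        out = filter_coding(clusters, pvalues)
        expected = {k for k, v in pvalues.items() if v >= 0.001}
        assert {c.id for c in out} == expected

    def test_filters_only_remove_and_log_reconstructs_membership(self):
        cluster = Cluster("c1", ["a", "b", "c", "d"])
        (out,) = filter_known([cluster], [_hit("b", "lib", 1e-15)], min_size=2)
        removed = {m for _, ids, _ in out.filter_log for m in ids}
        assert sorted(set(out.members) | removed) == ["a", "b", "c", "d"]
        assert cluster.filter_log == []  # input untouched

    def test_pvalue_table_io(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("c1\t0.5\nc2\t1e-5\n")
        assert read_pvalue_table(path) == {"c1": 0.5, "c2": 1e-5}
        bad = tmp_path / "bad.tsv"
        bad.write_text("c1\tx\n")
        with pytest.raises(CmlineError):
            read_pvalue_table(bad)
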
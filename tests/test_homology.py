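"""Alignment statistics, role assignment, BBH pairing and clustering."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rmscape.homology import (AlignmentStats, ClusterConfig, ProteinAligner,
                              ReferenceEntry, ReferenceLibrary, assign_roles,
                              bbh_pairs, cluster_families, pairwise_align,
                              read_blast_tab)

AA = "ACDEFGHIKLMNPQRSTVWY"
aa_seq = st.text(alphabet=AA, min_size=10, max_size=40)


# ---------------------------------------------------------------------------
# independent quadratic Gotoh DP, the oracle for local alignment scores


def gotoh_local_score(a, b, matrix, open_=-11.0, ext=-1.0):
    n, m = len(a), len(b)
    NEG = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in b
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]   # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] + open_, X[i - 1][j] + ext)
            Y[i][j] = max(M[i][j - 1] + open_, Y[i][j - 1] + ext)
            sub = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1] + sub, X[i - 1][j - 1] + sub,
                          Y[i - 1][j - 1] + sub)
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


class TestPairwiseAlign:
    def test_identical_sequences(self):
        s = "MKLVANQRESTWYFAGHIDCPKLMNQRSTVWYAGHIKLMNPQRSTVWYAG"
        st_ = pairwise_align(s, s, "local")
        assert st_.identity == 1.0
        assert st_.query_coverage == 1.0
        assert st_.length_diff == 0.0

    def test_endgapfree_cterminal_extension(self):
        core = "MKLVANQRESTWYFAGHIDCPKLMNQRSTVWYAGHIKLMNPQRSTVWYAG"
        ext = core + "AAAAAAAAAA"
        st_ = pairwise_align(core, ext, "global_endgapfree")
        assert st_.identity == 1.0          # over aligned core columns
        assert st_.length_diff == pytest.approx(10 / 60)

    def test_local_score_equals_gotoh_oracle(self):
        rng = random.Random(17)
        al = ProteinAligner()
        from Bio.Align import substitution_matrices
        matrix = substitution_matrices.load("BLOSUM62")
        for _ in range(15):
            a = "".join(rng.choice(AA) for _ in range(30))
            b = "".join(rng.choice(AA) for _ in range(30))
            assert al.score(a, b, "local") == pytest.approx(
                gotoh_local_score(a, b, matrix))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(aa_seq, aa_seq)
    def test_score_symmetry_and_self_identity(self, a, b):
        al = ProteinAligner()
        assert al.score(a, b) == al.score(b, a)
        assert pairwise_align(a, a).identity == 1.0

    def test_empty_sequence_is_domain_error(self):
        with pytest.raises(ValueError):
            pairwise_align("", "MKL")

    def test_unknown_residue_warns(self):
        with pytest.warns(UserWarning):
            pairwise_align("MKLJJX", "MKLAAX")


class TestAssignRoles:
    def _library(self, rng):
        ref_m = "".join(rng.choice(AA) for _ in range(120))
        ref_r = "".join(rng.choice(AA) for _ in range(120))
        return ReferenceLibrary([
            ReferenceEntry("mt2", "MTase", "II", ref_m),
            ReferenceEntry("re2", "REase", "II", ref_r),
        ]), ref_m, ref_r

    def test_identical_to_reference_mtase(self):
        lib, ref_m, _ = self._library(random.Random(3))
        calls = assign_roles({"g1": ref_m}, lib)
        assert calls["g1"].role == "MTase"
        assert calls["g1"].rm_type == "II"

    def test_low_coverage_rease_hit_rejected(self):
        rng = random.Random(3)
        lib, _ref_m, ref_r = self._library(rng)
        # gene carrying only a third of the REase: subject coverage < 0.5
        frag = ref_r[:40] + "".join(rng.choice(AA) for _ in range(80))
        calls = assign_roles({"g1": frag}, lib, prefilter=False)
        assert not calls["g1"].has_flag("REase", "II")

    def test_gene_passing_rease_and_mtase_is_iic(self):
        rng = random.Random(3)
        lib, ref_m, ref_r = self._library(rng)
        calls = assign_roles({"g1": ref_r + ref_m}, lib)
        assert calls["g1"].role == "IIC"
        assert calls["g1"].rm_type == "none"
        assert calls["g1"].has_flag("REase", "II")
        assert calls["g1"].has_flag("MTase", "II")

    def test_no_hit_is_other(self):
        lib, _m, _r = self._library(random.Random(3))
        rng = random.Random(99)
        calls = assign_roles(
            {"bg": "".join(rng.choice(AA) for _ in range(120))}, lib)
        assert calls["bg"].role == "other"

    def test_empty_reference_is_configuration_error(self):
        with pytest.raises(ValueError):
            ReferenceLibrary([])


class TestBBH:
    def test_self_proteome_pairs_every_gene_with_itself(self):
        rng = random.Random(5)
        prot = {f"g{i}": "".join(rng.choice(AA) for _ in range(60))
                for i in range(6)}
        pairs = bbh_pairs(prot, dict(prot))
        assert sorted((p.query_id, p.subject_id) for p in pairs) == \
            sorted((g, g) for g in prot)

    def test_similarity_threshold_excludes_pair(self):
        rng = random.Random(5)
        base = "".join(rng.choice(AA) for _ in range(100))
        # ~60% identity mutant: similarity well below 0.8
        mut = list(base)
        for i in range(0, 100, 3):
            mut[i] = AA[(AA.index(mut[i]) + 7) % 20]
        pairs = bbh_pairs({"a": base}, {"b": "".join(mut)}, prefilter=False)
        assert pairs == []

    def test_matches_brute_force_best_hit_oracle(self):
        rng = random.Random(8)
        base = ["".join(rng.choice(AA) for _ in range(60)) for _ in range(5)]

        def mutate(s, k):
            out = list(s)
            for i in rng.sample(range(len(s)), k):
                out[i] = rng.choice(AA.replace(out[i], ""))
            return "".join(out)

        pa = {f"a{i}": s for i, s in enumerate(base)}
        pb = {f"b{i}": mutate(s, 5) for i, s in enumerate(base)}
        pairs = bbh_pairs(pa, pb, prefilter=False)
        al = ProteinAligner()
        # exhaustive all-vs-all reciprocal best hits
        score = {(i, j): al.score(pa[i], pb[j], "global_endgapfree")
                 for i in pa for j in pb}
        expect = set()
        for i in pa:
            j = max(pb, key=lambda j: (score[(i, j)], j < "z"))
            back = max(pa, key=lambda x: (score[(x, j)], x < "z"))
            if back == i:
                st_ = al.stats(pa[i], pb[j], "global_endgapfree")
                if st_.similarity >= 0.8 and st_.length_diff <= 0.2:
                    expect.add((i, j))
        assert {(p.query_id, p.subject_id) for p in pairs} == expect

    def test_symmetric_in_argument_order(self):
        rng = random.Random(9)
        pa = {f"a{i}": "".join(rng.choice(AA) for _ in range(50))
              for i in range(4)}
        pb = {f"b{i}": pa[f"a{i}"][:45] + "AAAAA" for i in range(4)}
        fwd = {(p.query_id, p.subject_id) for p in bbh_pairs(pa, pb)}
        rev = {(p.subject_id, p.query_id) for p in bbh_pairs(pb, pa)}
        assert fwd == rev


class TestClustering:
    @staticmethod
    def _hit(a, b, score=80.0, identity=0.9, cov=1.0):
        return AlignmentStats(a, b, identity, identity, cov, cov, score,
                              1e-12, 0.0)

    def test_two_cliques_both_methods(self):
        hits = [self._hit(a, b) for a, b in
                itertools.combinations(["a", "b", "c"], 2)]
        hits += [self._hit(a, b) for a, b in
                 itertools.combinations(["x", "y", "z"], 2)]
        for cfg in (ClusterConfig(method="mcl", inflation=1.4),
                    ClusterConfig(method="single_linkage", identity_min=0.8,
                                  coverage_min=0.8)):
            part = cluster_families(hits, cfg)
            assert len(set(part.values())) == 2
            assert part["a"] == part["b"] == part["c"]
            assert part["x"] == part["y"] == part["z"]

    def test_single_linkage_transitive_closure(self):
        hits = [self._hit("A", "B", identity=0.85),
                self._hit("B", "C", identity=0.82),
                self._hit("A", "C", identity=0.45)]
        part = cluster_families(hits, ClusterConfig(
            method="single_linkage", identity_min=0.8, coverage_min=0.5))
        assert part["A"] == part["B"] == part["C"]

    def test_stringent_families_refine_relaxed(self):
        rng = random.Random(4)
        ids = [f"s{i}" for i in range(15)]
        hits = [self._hit(a, b, identity=rng.uniform(0.3, 1.0))
                for a, b in itertools.combinations(ids, 2)
                if rng.random() < 0.4]
        tight = cluster_families(hits, ClusterConfig(
            method="single_linkage", identity_min=0.8, coverage_min=0.5),
            all_ids=ids)
        loose = cluster_families(hits, ClusterConfig(
            method="single_linkage", identity_min=0.4, coverage_min=0.5),
            all_ids=ids)
        for fam in set(tight.values()):
            members = [g for g, f in tight.items() if f == fam]
            assert len({loose[g] for g in members}) == 1

    def test_mcl_matches_reference_iteration_oracle(self):
        rng = random.Random(12)
        ids = [f"n{i}" for i in range(12)]
        weights = {}
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.3:
                weights[(a, b)] = rng.uniform(10, 100)
        hits = [self._hit(a, b, score=w) for (a, b), w in weights.items()]
        part = cluster_families(hits, ClusterConfig(method="mcl",
                                                    inflation=1.4),
                                all_ids=ids)
        # independent dense-matrix reference of expansion/inflation
        idx = {v: k for k, v in enumerate(ids)}
        m = np.zeros((12, 12))
        for (a, b), w in weights.items():
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
        d = m.max(axis=0)
        d[d == 0] = 1.0
        np.fill_diagonal(m, d)
        m /= m.sum(0, keepdims=True)
        for _ in range(200):
            new = np.power(m @ m, 1.4)
            new[new < 1e-12] = 0
            s = new.sum(0, keepdims=True)
            s[s == 0] = 1
            new /= s
            if np.abs(new - m).max() < 1e-6:
                m = new
                break
            m = new
        groups = {}
        for j in range(12):
            attr = tuple(sorted(np.nonzero(m[:, j] > 1e-6)[0]))
            groups.setdefault(attr, set()).add(ids[j])
        # nodes sharing an attractor set must share a family
        for a, b in itertools.combinations(ids, 2):
            if any(a in s and b in s for s in groups.values()):
                assert part[a] == part[b]

    def test_mcl_high_inflation_breaks_weak_bridge(self):
        hits = [self._hit("a", "b", 100.0), self._hit("c", "d", 100.0),
                self._hit("b", "c", 5.0)]
        part = cluster_families(hits, ClusterConfig(method="mcl",
                                                    inflation=8.0))
        assert part["a"] == part["b"]
        assert part["c"] == part["d"]
        assert part["a"] != part["c"]


def test_blast_tab_ingestion(tmp_path):
    p = tmp_path / "hits.tsv"
    p.write_text("q1\ts1\t95.0\t100\t5\t0\t1\t100\t1\t100\t1e-30\t180\n")
    hits = read_blast_tab(p, {"q1": 100, "s1": 120})
    assert hits[0].identity == pytest.approx(0.95)
    assert hits[0].subject_coverage == pytest.approx(100 / 120)
    assert hits[0].evalue_proxy == pytest.approx(1e-30)
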
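"""Mid-p hypergeometric test, cosine profiles, and downstream transforms."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from golink.association import (
    PValueMatrix,
    build_pvalue_matrix,
    cooccurrence_similarity,
    cosine_similarity,
    hypergeom_midp,
    hypergeom_midp_exact,
    hypergeom_midp_many,
    probit_transform,
    select_top_go,
    similarity_matrix,
    similarity_percentiles,
    weight_profile,
)
from golink.corpus import AbstractRecord, tally_counts


class TestHypergeomMidp:
    @pytest.mark.parametrize(
        "n_ij, n_i, n_j, n_tot, expected",
        [
            (4, 4, 5, 10, 1 / 84),     # upper tail empty, half the observed mass
            (2, 4, 5, 10, 0.5),        # symmetric case: (P(3)+P(4)) + P(2)/2
            (0, 0, 5, 10, 0.5),        # degenerate X == 0
            (0, 5, 0, 10, 0.5),        # degenerate the other way
        ],
    )
    def test_reference_values(self, n_ij, n_i, n_j, n_tot, expected):
        assert hypergeom_midp(n_ij, n_i, n_j, n_tot) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "args, margin",
        [
            ((5, 4, 5, 10), "n_ij"),
            ((0, 11, 5, 10), "n_i"),
            ((0, 4, 11, 10), "n_j"),
            ((0, 0, 0, 0), "n_tot"),
            ((-1, 4, 5, 10), "n_ij"),
        ],
    )
    def test_precondition_errors_name_the_margin(self, args, margin):
        with pytest.raises(ValueError, match=margin):
            hypergeom_midp(*args)

    @given(
        n_tot=st.integers(1, 25),
        data=st.data(),
    )
    def test_agrees_with_exact_enumeration(self, n_tot, data):
        n_i = data.draw(st.integers(0, n_tot))
        n_j = data.draw(st.integers(0, n_tot))
        n_ij = data.draw(st.integers(max(0, n_i + n_j - n_tot), min(n_i, n_j)))
        approx = hypergeom_midp(n_ij, n_i, n_j, n_tot)
        exact = float(hypergeom_midp_exact(n_ij, n_i, n_j, n_tot))
        assert approx == pytest.approx(exact, abs=1e-12)

    def test_strictly_decreasing_in_joint_count(self):
        for n_i, n_j, n_tot in [(4, 5, 10), (10, 12, 30), (7, 7, 14)]:
            kmin = max(0, n_i + n_j - n_tot)
            vals = [hypergeom_midp(k, n_i, n_j, n_tot) for k in range(kmin, min(n_i, n_j) + 1)]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_stable_at_literature_scale(self):
        # margins representative of a multi-million-abstract corpus
        p_strong = hypergeom_midp(900, 2000, 5000, 10**7)
        p_null = hypergeom_midp(1, 2000, 5000, 10**7)
        assert 0.0 < p_strong < 1e-300  # far beyond float sf() reach, still nonzero
        assert 0.1 < p_null < 1.0
        assert p_strong < p_null

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(7)
        n_tot = 500
        a = rng.integers(0, n_tot, 50)
        b = rng.integers(0, n_tot, 50)
        k = np.minimum(a, b) // 2
        k = np.maximum(k, np.maximum(0, a + b - n_tot))
        vec = hypergeom_midp_many(k, a, b, n_tot)
        for i in range(50):
            assert vec[i] == pytest.approx(
                hypergeom_midp(int(k[i]), int(a[i]), int(b[i]), n_tot), rel=1e-12
            )


class TestPValueMatrix:
    def test_build_stores_exactly_observed_pairs(self):
        records = [
            AbstractRecord("A1", {"g1"}, {"t1"}),
            AbstractRecord("A2", {"g1"}, set()),
            AbstractRecord("A3", {"g2"}, {"t2"}),
            AbstractRecord("A4", {"g2"}, {"t1", "t2"}),
        ]
        counts = tally_counts(records)
        pmat = build_pvalue_matrix(counts)
        assert set(pmat.p) == {("g1", "t1"), ("g2", "t1"), ("g2", "t2")}
        for (g, t), p in pmat.p.items():
            expected = hypergeom_midp(
                counts.n_joint[(g, t)], counts.n_gene[g], counts.n_go[t], counts.n_total
            )
            assert p == pytest.approx(expected, rel=1e-12)
        assert pmat.get("g1", "t2") is None  # n_ij = 0 pair is absent

    def test_reference_pair_value(self):
        # margins engineered so (g1, t1) has n_ij=4, n_i=4, n_j=5, n_tot=10
        records = (
            [AbstractRecord(f"A{i}", {"g1"}, {"t1"}) for i in range(4)]
            + [AbstractRecord("A4", set(), {"t1"})]
            + [AbstractRecord(f"B{i}", {"g2"}, set()) for i in range(5)]
        )
        pmat = build_pvalue_matrix(tally_counts(records))
        assert pmat.get("g1", "t1") == pytest.approx(1 / 84, abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            PValueMatrix(genes=("g",), gos=("t",), p={("g", "t"): 0.0})


class TestWeightsAndCosine:
    def test_floor_truncation(self):
        pmat = PValueMatrix(genes=("g",), gos=("t1", "t2", "t3"),
                            p={("g", "t1"): 1e-8, ("g", "t2"): 1.0, ("g", "t3"): 0.5})
        prof = weight_profile(pmat, "g")
        assert prof.weights["t1"] == pytest.approx(-math.log(1e-6), rel=1e-12)
        assert "t2" not in prof.weights  # p = 1 -> weight 0, not stored
        assert prof.weights["t3"] == pytest.approx(math.log(2), rel=1e-12)

    def test_cosine_reference_cases(self, tiny_pmat):
        a = weight_profile(tiny_pmat, "g1")
        b = weight_profile(tiny_pmat, "g2")
        c = weight_profile(tiny_pmat, "g3")
        assert cosine_similarity(a, a) == pytest.approx(1.0, abs=1e-12)
        assert cosine_similarity(a, b) == pytest.approx(0.8, abs=1e-12)
        assert cosine_similarity(a, c) == 0.0  # disjoint supports

    @given(
        ps_a=st.lists(st.floats(1e-9, 1.0, exclude_max=True), min_size=1, max_size=6),
        ps_b=st.lists(st.floats(1e-9, 1.0, exclude_max=True), min_size=1, max_size=6),
    )
    def test_cosine_properties(self, ps_a, ps_b):
        gos = tuple(f"t{i}" for i in range(max(len(ps_a), len(ps_b))))
        p = {("a", f"t{i}"): v for i, v in enumerate(ps_a)}
        p.update({("b", f"t{i}"): v for i, v in enumerate(ps_b)})
        pmat = PValueMatrix(genes=("a", "b"), gos=gos, p=p)
        pa = weight_profile(pmat, "a")
        pb = weight_profile(pmat, "b")
        g = cosine_similarity(pa, pb)
        assert g == cosine_similarity(pb, pa)
        assert 0.0 <= g <= 1.0
        # uniform rescaling of both profiles leaves the cosine unchanged
        from golink.association import WeightProfile

        scaled = WeightProfile("a", {k: 3.7 * v for k, v in pa.weights.items()})
        scaled_b = WeightProfile("b", {k: 3.7 * v for k, v in pb.weights.items()})
        assert cosine_similarity(scaled, scaled_b) == pytest.approx(g, abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    def test_log_base_invariance(self, seed):
        rng = np.random.default_rng(seed)
        genes = ("a", "b", "c")
        gos = tuple(f"t{i}" for i in range(8))
        p = {
            (g, t): float(rng.uniform(1e-8, 1.0))
            for g in genes
            for t in gos
            if rng.random() < 0.7
        }
        pmat = PValueMatrix(genes=genes, gos=gos, p=p)
        nat = similarity_matrix(pmat)                 # natural log
        ten = similarity_matrix(pmat, log_base=10.0)  # same ratios, same cosine
        np.testing.assert_allclose(nat.values, ten.values, atol=1e-12)

    def test_similarity_matrix_assembled(self, tiny_pmat):
        sim = similarity_matrix(tiny_pmat)
        expected = np.array([[1.0, 0.8, 0.0], [0.8, 1.0, 0.0], [0.0, 0.0, 1.0]])
        np.testing.assert_allclose(sim.values, expected, atol=1e-12)
        assert sim.undefined == frozenset()

    def test_all_zero_profile_flagged(self):
        pmat = PValueMatrix(genes=("a", "b"), gos=("t",), p={("a", "t"): 0.01})
        sim = similarity_matrix(pmat)
        assert sim.undefined == frozenset({"b"})
        assert sim.gamma("a", "b") == 0.0
        assert sim.gamma("b", "b") == 0.0
        assert sim.pair_values().size == 0  # undefined pairs excluded by default
        assert sim.pair_values(include_undefined=True).size == 1

    def test_unknown_gene_listed(self, tiny_pmat):
        with pytest.raises(ValueError, match="gX.*gY|gX, gY"):
            similarity_matrix(tiny_pmat, genes=["g1", "gX", "gY"])


class TestPercentiles:
    def test_linear_interpolation_bimodal(self):
        values = [0.1] * 50 + [0.9] * 50
        assert similarity_percentiles(values, [0.5]) == [pytest.approx(0.5)]

    def test_constant_values(self):
        assert similarity_percentiles([0.3] * 10, [0.0, 0.5, 0.99]) == [0.3, 0.3, 0.3]

    def test_q1_is_maximum(self):
        assert similarity_percentiles([0.2, 0.7, 0.4], [1.0]) == [pytest.approx(0.7)]

    def test_monotone_in_q(self):
        rng = np.random.default_rng(3)
        vals = rng.random(101)
        qs = [0.1, 0.25, 0.5, 0.9, 0.99]
        cuts = similarity_percentiles(vals, qs)
        assert cuts == sorted(cuts)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            similarity_percentiles([], [0.5])


class TestCooccurrenceBaseline:
    def test_reference_values(self):
        records = (
            [AbstractRecord(f"A{i}", {"g1", "g2"}, set()) for i in range(2)]
            + [AbstractRecord(f"B{i}", {"g1"}, set()) for i in range(2)]
            + [AbstractRecord(f"C{i}", {"g2"}, set()) for i in range(7)]
        )
        sim = cooccurrence_similarity(tally_counts(records))
        # n_12=2, n_1=4, n_2=9 -> 2 / 6
        assert sim.gamma("g1", "g2") == pytest.approx(2 / 6, rel=1e-12)

    def test_identical_incidence_gives_one(self):
        records = [AbstractRecord(f"A{i}", {"g1", "g2"}, set()) for i in range(5)]
        sim = cooccurrence_similarity(tally_counts(records))
        assert sim.gamma("g1", "g2") == pytest.approx(1.0)

    def test_never_comentioned_gives_zero(self):
        records = [AbstractRecord("A1", {"g1"}, set()), AbstractRecord("A2", {"g2"}, set())]
        sim = cooccurrence_similarity(tally_counts(records))
        assert sim.gamma("g1", "g2") == 0.0

    @given(seed=st.integers(0, 5_000))
    def test_equals_cosine_of_incidence_vectors(self, seed):
        rng = np.random.default_rng(seed)
        n_abs = 30
        genes = ["g1", "g2", "g3"]
        incidence = rng.random((n_abs, 3)) < 0.4
        records = [
            AbstractRecord(f"A{i}", {g for g, hit in zip(genes, row) if hit}, set())
            for i, row in enumerate(incidence)
        ]
        counts = tally_counts(records)
        sim = cooccurrence_similarity(counts)
        for i, gi in enumerate(genes):
            for j in range(i + 1, 3):
                gj = genes[j]
                vi, vj = incidence[:, i].astype(float), incidence[:, j].astype(float)
                ni, nj = vi.sum(), vj.sum()
                if ni == 0 or nj == 0:
                    assert not sim.is_defined(gi) or not sim.is_defined(gj)
                else:
                    expected = float(vi @ vj / math.sqrt(ni * nj))
                    assert sim.gamma(gi, gj) == pytest.approx(expected, abs=1e-12)


class TestProbitTransform:
    def test_reference_values(self):
        assert probit_transform(0.5) == pytest.approx(0.0, abs=1e-12)
        assert probit_transform(1e-9) == pytest.approx(-4.7534, abs=1e-4)
        assert probit_transform(None) == pytest.approx(4.7534, abs=1e-4)

    def test_array_with_missing(self):
        out = probit_transform(np.array([0.5, np.nan]))
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(4.7534, abs=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            probit_transform(bad)


class TestSelectTopGo:
    def test_smallest_average_wins(self, tiny_pmat):
        # averages over {g1, g2}: t1 = (0.01+0.1)/2, t2 same, t3 missing for both
        top = select_top_go(tiny_pmat, {"g1", "g2"}, k=1)
        assert top == ["t1"]  # tie with t2 broken lexicographically

    def test_missing_counts_as_one(self):
        pmat = PValueMatrix(genes=("g1", "g2"), gos=("t1",), p={("g1", "t1"): 0.01})
        from golink.association import average_go_pvalues

        assert average_go_pvalues(pmat, {"g1", "g2"})["t1"] == pytest.approx(0.505)
        assert select_top_go(pmat, {"g1", "g2"}, k=1) == ["t1"]

    def test_gene_order_invariant(self, tiny_pmat):
        assert select_top_go(tiny_pmat, ["g1", "g2", "g3"], k=3) == select_top_go(
            tiny_pmat, ["g3", "g2", "g1"], k=3
        )

    def test_oversized_k_warns_and_returns_all(self, tiny_pmat):
        with pytest.warns(UserWarning, match="returning all"):
            top = select_top_go(tiny_pmat, {"g1"}, k=10)
        assert top == ["t1", "t2"]  # g1 has stored pairs only for t1, t2

    def test_full_ranking_monotone(self, tiny_pmat):
        from golink.association import average_go_pvalues

        ranking = select_top_go(tiny_pmat, {"g1", "g2", "g3"}, k=3)
        avgs = average_go_pvalues(tiny_pmat, {"g1", "g2", "g3"})
        vals = [avgs[t] for t in ranking]
        assert vals == sorted(vals)
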
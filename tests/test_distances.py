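"""p-distances, pairwise ML distances and group summaries."""

import itertools

import numpy as np
import pytest

from gyrits.distances import (DistanceMatrix, Partition, PartitionedAlignment,
                              distance_matrix, estimate_model_params,
                              group_distance_summary, ml_distance,
                              pair_loglik, parse_partition_file, p_distance,
                              site_pattern_counts)
from gyrits.models import SubstitutionModel
from gyrits.synthetic_data import simulate_pair


def naive_p_distance(a, b):
    """Independent per-site loop oracle (pairwise deletion)."""
    diff = comp = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            comp += 1
            diff += x != y
    return diff / comp, comp


class TestPDistance:
    def test_simple_quarter(self):
        assert p_distance("ACGT", "ACGA")[0] == 0.25

    def test_gap_site_excluded(self):
        d, n = p_distance("AC-T", "ACGT")
        assert (d, n) == (0.0, 3)

    def test_zero_comparable_sites_is_error(self):
        with pytest.raises(ValueError):
            p_distance("--NN", "AC-T")

    def test_matches_per_site_loop_on_random_pairs(self, rng):
        alphabet = np.array(list("ACGT-N"))
        for _ in range(300):
            a = "".join(rng.choice(alphabet, 200, p=[.22, .22, .22, .22, .06, .06]))
            b = "".join(rng.choice(alphabet, 200, p=[.22, .22, .22, .22, .06, .06]))
            try:
                expected = naive_p_distance(a, b)
            except ZeroDivisionError:
                continue
            assert p_distance(a, b) == expected


class TestPairLoglik:
    def test_identical_data_maximized_at_zero(self, jc):
        counts = site_pattern_counts("ACGTACGTAC", "ACGTACGTAC")
        l0 = pair_loglik([counts], 1e-9, [jc])
        for t in (0.01, 0.1, 1.0):
            assert pair_loglik([counts], t, [jc]) < l0

    def test_jc_closed_form(self, jc):
        """Two-sequence JC likelihood has the textbook closed form."""
        jc1 = SubstitutionModel.jc()  # no gamma -> single category
        a, b = "ACGTACGTGG", "ACGAACGTGG"
        counts = site_pattern_counts(a, b)
        n, d, t = 10, 1, 0.23
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        closed = (n - d) * np.log(0.25 * p_same) + d * np.log(0.25 * p_diff)
        assert pair_loglik([counts], t, [jc1]) == pytest.approx(closed, abs=1e-9)

    def test_additive_over_partitions(self, jc, tvm_gamma):
        c1 = site_pattern_counts("ACGTAAGG", "ACGTAAGC")
        c2 = site_pattern_counts("TTTTCCCC", "TTTACCCC")
        joint = pair_loglik([c1, c2], 0.2, [jc, tvm_gamma])
        split = (pair_loglik([c1], 0.2, [jc])
                 + pair_loglik([c2], 0.2, [tvm_gamma]))
        assert joint == pytest.approx(split, abs=1e-10)

    def test_all_zero_counts_rejected(self, jc):
        with pytest.raises(ValueError):
            pair_loglik([np.zeros((4, 4))], 0.1, [jc])


class TestMLDistance:
    def test_identical_rows_hit_lower_bound(self, jc):
        parts = [Partition("ALL", 1, 40, jc)]
        t, info = ml_distance("ACGT" * 10, "ACGT" * 10, parts)
        assert t <= 1e-6
        assert not info["saturated"]

    def test_jc_closed_form_equivalence(self, jc):
        """t-hat equals -(3/4)ln(1-4p/3) under JC with one rate category."""
        pair = simulate_pair(SubstitutionModel.jc(), 0.1, 50_000, seed=17)
        p, _ = p_distance(pair.seq_a, pair.seq_b)
        parts = [Partition("ALL", 1, 50_000, SubstitutionModel.jc())]
        t, _ = ml_distance(pair.seq_a, pair.seq_b, parts)
        closed = -0.75 * np.log(1 - 4 * p / 3)
        assert t == pytest.approx(closed, abs=1e-6)

    def test_tvm_gamma_parameter_recovery(self, tvm_gamma):
        pair = simulate_pair(tvm_gamma, 0.5, 50_000, seed=23)
        parts = [Partition("ALL", 1, 50_000, tvm_gamma)]
        t, _ = ml_distance(pair.seq_a, pair.seq_b, parts)
        assert t == pytest.approx(0.5, abs=0.03)

    def test_monotone_in_p_for_jc(self, jc):
        """More observed differences never decrease the JC ML distance."""
        n = 200
        prev = -1.0
        parts = [Partition("ALL", 1, n, SubstitutionModel.jc())]
        for d in (0, 5, 20, 60, 100):
            a = "A" * n
            b = "C" * d + "A" * (n - d)
            t, _ = ml_distance(a, b, parts)
            assert t >= prev
            prev = t

    def test_no_comparable_sites_error(self, jc):
        parts = [Partition("ALL", 1, 4, jc)]
        with pytest.raises(ValueError):
            ml_distance("----", "ACGT", parts)


class TestDistanceMatrix:
    def test_symmetry_zero_diagonal_bounds(self, jc, rng):
        rows = ["".join(rng.choice(list("ACGT"), 120)) for _ in range(6)]
        aln = PartitionedAlignment(
            [f"s{i}" for i in range(6)], rows, [Partition("ALL", 1, 120, jc)])
        for method in ("p", "ml"):
            dm = distance_matrix(aln, method=method)
            assert np.allclose(dm.matrix, dm.matrix.T)
            assert np.all(np.diag(dm.matrix) == 0)
            assert np.all(dm.matrix >= 0)
            if method == "p":
                assert np.all(dm.matrix <= 1)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]), "p")


class TestEstimateModelParams:
    def test_uniform_random_rows_give_uniform_frequencies(self, rng):
        rows = ["".join(rng.choice(list("ACGT"), 4000)) for _ in range(3)]
        model = estimate_model_params(rows, kind="TVM", gamma=False,
                                      max_sweeps=1)
        assert np.allclose(model.pi, 0.25, atol=0.03)

    def test_empirical_frequencies_match_hand_count(self):
        rows = ["AAAACCGT", "AAAACCGG", "AAAACCTT"]
        model = estimate_model_params(rows, kind="TVM", gamma=False,
                                      max_sweeps=1)
        counts = {b: sum(r.count(b) for r in rows) for b in "ACGT"}
        total = sum(counts.values())
        assert np.allclose(model.pi, [counts[b] / total for b in "ACGT"])

    def test_degenerate_alignment_returns_jc_defaults(self):
        model = estimate_model_params(["ACGT" * 5] * 4, kind="SYM")
        assert model.kind == "JC"

    def test_sym_gamma_shape_recovery(self, sym_gamma):
        """Composite pairwise fit recovers the generating gamma shape.

        The gamma shape is weakly identified from pairwise data, so the
        check uses a long simulated alignment to keep its sampling
        variance well inside the assertion band.
        """
        from gyrits.synthetic_data import simulate_alignment_on_tree
        nwk = ("((a:0.05,b:0.05):0.1,(c:0.05,d:0.05):0.1,"
               "(e:0.05,f:0.05):0.1);")
        aln, _ = simulate_alignment_on_tree(nwk, [("P", 100_000, sym_gamma)],
                                            seed=11)
        model = estimate_model_params(aln.rows, kind="SYM")
        assert 0.6 <= model.gamma_shape <= 1.0
        # transition exchangeabilities (AG, CT) dominate transversions
        s = np.array(model.exchangeabilities) / model.exchangeabilities[-1]
        assert s[1] > 2 * max(s[0], s[2], s[3]) and s[4] > 2 * max(s[0], s[2], s[3])


class TestGroupSummary:
    def test_uniform_distances(self):
        ids = ["a1", "a2", "b1", "b2"]
        M = np.full((4, 4), 0.1)
        np.fill_diagonal(M, 0)
        dm = DistanceMatrix(ids, M, "p")
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        intra, inter = group_distance_summary(dm, groups)
        assert intra == {"A": pytest.approx(0.1), "B": pytest.approx(0.1)}
        assert inter[frozenset({"A", "B"})] == pytest.approx(0.1)

    def test_intra_mean_arithmetic(self):
        ids = ["x1", "x2", "x3"]
        M = np.zeros((3, 3))
        M[0, 1] = M[1, 0] = 0.08
        M[0, 2] = M[2, 0] = 0.10
        M[1, 2] = M[2, 1] = 0.06
        dm = DistanceMatrix(ids, M, "p")
        intra, _ = group_distance_summary(dm, {i: "X" for i in ids})
        assert intra["X"] == pytest.approx(0.08)

    def test_inter_exceeds_intra_preserved(self, rng):
        """If every cross-group pair exceeds every within-group pair, the
        summary keeps that ordering (the pattern seen between genera)."""
        ids = [f"g{g}s{i}" for g in range(3) for i in range(3)]
        groups = {x: x[:2] for x in ids}
        n = len(ids)
        M = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            same = ids[i][:2] == ids[j][:2]
            M[i, j] = M[j, i] = rng.uniform(0.01, 0.05) if same \
                else rng.uniform(0.3, 0.6)
        dm = DistanceMatrix(ids, M, "p")
        intra, inter = group_distance_summary(dm, groups)
        assert max(intra.values()) < min(inter.values())

    def test_unmapped_id_errors_with_offenders(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, .1], [.1, 0]]), "p")
        with pytest.raises(ValueError, match="b"):
            group_distance_summary(dm, {"a": "A"})


class TestPartitionParsing:
    def test_raxml_style(self):
        text = "DNA, ITS1 = 1-826\nDNA, 5.8S = 827-986\nDNA, ITS2 = 987-1590\n"
        parts = parse_partition_file(text)
        assert [(p.name, p.start, p.end) for p in parts] == [
            ("ITS1", 1, 826), ("5.8S", 827, 986), ("ITS2", 987, 1590)]

    def test_overlapping_partitions_rejected(self, jc):
        with pytest.raises(ValueError):
            PartitionedAlignment(["a", "b"], ["ACGTACGT", "ACGTACGT"],
                                 [Partition("P1", 1, 5, jc),
                                  Partition("P2", 4, 8, jc)])
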
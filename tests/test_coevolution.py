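"""Coevolution: concatenation, DCA scores, convolution, randomization, simulator."""

import numpy as np
import pytest

from lgt.coevolution import (
    CouplingMap,
    OrthologSet,
    compute_couplings,
    concat_by_species,
    gaussian_convolve,
    generate_coevolving_msa,
    precision_at_k,
    randomization_test,
    read_ortholog_fasta,
    top_fraction_threshold,
    top_pairs,
    write_ortholog_fasta,
)
from lgt.coevolution.randomize import outcome_from_counts


def _random_set(rng, species, length):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    return OrthologSet({
        sp: "".join(rng.choice(list(aas), size=length)) for sp in species
    })


class TestConcatBySpecies:
    def test_intersection_of_species(self, rng):
        a = _random_set(rng, ["h", "m", "r"], 4)
        b = _random_set(rng, ["m", "r", "c"], 6)
        cmsa = concat_by_species(a, b)
        assert cmsa.species == ["m", "r"]
        assert cmsa.n_cols == 10 and cmsa.boundary == 4

    def test_disjoint_species_rejected(self, rng):
        with pytest.raises(ValueError, match="shared species"):
            concat_by_species(_random_set(rng, ["a", "b"], 3),
                              _random_set(rng, ["c", "d"], 3))

    def test_generator_contract_row_count(self):
        sa, sb, _ = generate_coevolving_msa(8, 8, 120, 0, 0.0, seed=1)
        cmsa = concat_by_species(sa, sb)
        assert cmsa.n_rows == 120

    def test_misaligned_set_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            OrthologSet({"a": "ACD", "b": "AC"})


def _covarying_alignment(rng, n_rows=200):
    """A0 and B0 covary perfectly (two joint states, 50/50); rest i.i.d."""
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    half = n_rows // 2
    a0 = ["A"] * half + ["C"] * (n_rows - half)
    b0 = ["D"] * half + ["F"] * (n_rows - half)
    order = rng.permutation(n_rows)
    seq_a, seq_b = {}, {}
    for row, k in enumerate(order):
        sp = f"s{row:03d}"
        seq_a[sp] = a0[k] + "".join(rng.choice(aas, 2))
        seq_b[sp] = b0[k] + "".join(rng.choice(aas, 2))
    return OrthologSet(seq_a), OrthologSet(seq_b)


class TestComputeCouplings:
    def test_covarying_pair_dominates_and_iid_floor(self, rng):
        sa, sb = _covarying_alignment(rng)
        cmap = compute_couplings(concat_by_species(sa, sb))
        planted = cmap.raw[0, 0]
        others = cmap.raw.copy()
        others[0, 0] = -np.inf
        assert planted > others.max()
        # a fully independent alignment stays below the planted signal
        s1 = _random_set(rng, [f"t{i}" for i in range(500)], 3)
        s2 = _random_set(rng, [f"t{i}" for i in range(500)], 3)
        null_map = compute_couplings(concat_by_species(s1, s2))
        assert null_map.raw.max() < planted

    def test_row_order_invariance(self, rng):
        sa, sb = _covarying_alignment(rng, 100)
        cmap1 = compute_couplings(concat_by_species(sa, sb))
        shuffled_a = OrthologSet(dict(reversed(list(sa.sequences.items()))))
        cmap2 = compute_couplings(concat_by_species(shuffled_a, sb))
        np.testing.assert_array_equal(cmap1.raw, cmap2.raw)

    def test_apc_centres_independent_scores(self, rng):
        """APC leaves a near-zero mean over the full score matrix."""
        from lgt.coevolution.dca import (_frobenius_apc, _mean_field_couplings,
                                         sequence_weights)

        s1 = _random_set(rng, [f"u{i}" for i in range(300)], 10)
        s2 = _random_set(rng, [f"u{i}" for i in range(300)], 10)
        cmsa = concat_by_species(s1, s2)
        w = sequence_weights(cmsa.matrix)
        scores = _frobenius_apc(_mean_field_couplings(cmsa.matrix, w, 0.5))
        off = ~np.eye(scores.shape[0], dtype=bool)
        assert abs(scores[off].mean()) < 0.05 * scores[off].std()

    def test_gap_rich_columns_removed(self, rng):
        seqs_a = {f"v{i}": ("-" + "".join(rng.choice(list("ACDE"), 3))) for i in range(60)}
        sa = OrthologSet(seqs_a)
        sb = _random_set(rng, list(seqs_a), 4)
        with pytest.warns(UserWarning, match="gap-rich"):
            cmap = compute_couplings(concat_by_species(sa, sb))
        assert 0 not in cmap.cols_a
        assert cmap.raw.shape == (3, 4)

    def test_plm_and_mean_field_agree_on_planted_pair(self, rng):
        sa, sb = _covarying_alignment(rng, 120)
        mf = compute_couplings(concat_by_species(sa, sb), "mean_field")
        plm = compute_couplings(concat_by_species(sa, sb), "pseudolikelihood")
        assert np.unravel_index(mf.raw.argmax(), mf.raw.shape) == (0, 0)
        assert np.unravel_index(plm.raw.argmax(), plm.raw.shape) == (0, 0)


class TestGaussianConvolve:
    def _map(self, mat):
        mat = np.asarray(mat, dtype=float)
        return CouplingMap(mat, np.arange(mat.shape[0]), np.arange(mat.shape[1]),
                           "mean_field")

    def test_impulse_response_preserves_sum(self):
        delta = np.zeros((21, 21))
        delta[10, 10] = 1.0
        conv = gaussian_convolve(self._map(delta), 2.0)
        assert conv.convolved.sum() == pytest.approx(1.0, abs=1e-9)
        assert conv.convolved[10, 10] == conv.convolved.max()

    def test_sigma_zero_is_identity(self, rng):
        mat = rng.random((9, 9))
        conv = gaussian_convolve(self._map(mat), 0.0)
        np.testing.assert_allclose(conv.convolved, mat)

    def test_uniform_map_unchanged(self):
        conv = gaussian_convolve(self._map(np.full((8, 8), 3.3)), 2.0)
        np.testing.assert_allclose(conv.convolved, 3.3)


class TestTopFractionThreshold:
    def test_order_statistic_on_1_to_100(self):
        assert top_fraction_threshold(np.arange(1.0, 101.0), 0.05) == 96.0

    def test_n20_ceiling_gives_max(self):
        scores = np.arange(20.0)
        assert top_fraction_threshold(scores, 0.05) == scores.max()

    def test_boundary_ties_share_threshold(self):
        scores = np.concatenate([np.arange(95.0), np.full(5, 96.0)])
        assert top_fraction_threshold(scores, 0.05) == 96.0

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            top_fraction_threshold(np.arange(10.0), 0.05)


class TestRandomizationOutcome:
    def test_three_of_hundred_gives_p_003(self):
        out = outcome_from_counts(3, 100)
        assert out.p_value == 0.03  # the k/N counting convention, exactly
        assert out.p_value_add_one == pytest.approx(4 / 101)

    def test_zero_exceedances_give_p_zero(self):
        assert outcome_from_counts(0, 100).p_value == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            outcome_from_counts(5, 4)
        with pytest.raises(ValueError):
            outcome_from_counts(0, 0)


class TestRandomizationTest:
    def test_planted_signal_detected(self):
        sa, sb, _ = generate_coevolving_msa(16, 16, 120, [(4, 10)], 0.95, seed=3)
        out = randomization_test(sa, sb, n_replicates=10, sigma=1.5, seed=3)
        assert out.p_value <= 0.1
        assert out.exceed_count == int(
            (out.replicate_values > out.threshold).sum()
        )

    def test_null_is_conservative(self):
        """Independent genealogies: p not concentrated below 0.05."""
        ps = []
        for run in range(8):
            sa, sb, _ = generate_coevolving_msa(
                16, 16, 90, 0, 0.0, seed=50 + run, shared_tree=False
            )
            ps.append(randomization_test(sa, sb, n_replicates=10, sigma=1.5,
                                         seed=run).p_value)
        assert np.mean(ps) > 0.3
        assert sum(p < 0.05 for p in ps) <= 2

    def test_seeded_reproducibility(self):
        sa, sb, _ = generate_coevolving_msa(12, 12, 80, 0, 0.0, seed=9)
        o1 = randomization_test(sa, sb, n_replicates=5, seed=42)
        o2 = randomization_test(sa, sb, n_replicates=5, seed=42)
        np.testing.assert_array_equal(o1.replicate_values, o2.replicate_values)
        assert o1.p_value == o2.p_value


class TestSimulator:
    def test_same_seed_identical_alignments(self):
        a1, b1, t1 = generate_coevolving_msa(20, 20, 60, 3, 0.9, seed=5)
        a2, b2, t2 = generate_coevolving_msa(20, 20, 60, 3, 0.9, seed=5)
        assert a1.sequences == a2.sequences and b1.sequences == b2.sequences
        assert t1["planted_pairs"] == t2["planted_pairs"]

    def test_strong_coupling_recovered_at_small_scale(self):
        sa, sb, truth = generate_coevolving_msa(20, 20, 300, 3, 1.0, seed=6)
        cmap = compute_couplings(concat_by_species(sa, sb))
        pred = top_pairs(cmap, 3, use_convolved=False)
        assert precision_at_k(pred, truth["planted_pairs"]) == 1.0

    def test_zero_coupling_not_enriched(self):
        sa, sb, truth = generate_coevolving_msa(20, 20, 300, 3, 0.0, seed=6)
        cmap = compute_couplings(concat_by_species(sa, sb))
        pred = top_pairs(cmap, 3, use_convolved=False)
        # 3 of 400 cells planted; exact hits would be ~0 by chance
        assert precision_at_k(pred, truth["planted_pairs"]) <= 1 / 3

    def test_independent_trees_refuse_planted_pairs(self):
        with pytest.raises(ValueError, match="independent trees"):
            generate_coevolving_msa(10, 10, 50, 2, 0.5, seed=1, shared_tree=False)

    def test_gap_fraction_injects_gaps(self):
        sa, _, _ = generate_coevolving_msa(30, 30, 50, 0, 0.0, seed=7,
                                           gap_fraction=0.1)
        frac = np.mean([s.count("-") for s in sa.sequences.values()]) / 30
        assert 0.05 < frac < 0.15


class TestFastaRoundTrip:
    def test_write_then_read_preserves_sequences(self, tmp_path, rng):
        oset = _random_set(rng, ["HUMAN", "MOUSE", "CHICK"], 12)
        path = tmp_path / "orthologs.fasta"
        write_ortholog_fasta(oset, path)
        back = read_ortholog_fasta(path)
        assert back.sequences == oset.sequences
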
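import numpy as np
import pytest

from boostgrn import (
    ConfidenceMatrix,
    KnockoutMatrix,
    PriorConfig,
    ValidationError,
    compute_prior,
    fuse_prior,
    normalize_l2,
    rank_edges,
    variance_update,
)


def square_ko(values, genes):
    return KnockoutMatrix(knocked_gene_ids=list(genes),
                          measured_gene_ids=list(genes),
                          values=np.asarray(values, dtype=float))


def norm_cm(W, regs, tgts):
    return ConfidenceMatrix(regulator_ids=regs, target_ids=tgts,
                            W=np.asarray(W, dtype=float), stage="normalized")


class TestComputePrior:
    def test_hand_z_score(self):
        """Column [1,2,3] with sample sd 1 and mean 2: the knockout that
        measured 3 gets significance |3-2|/1 = 1."""
        genes = ["G1", "G2", "G3"]
        # column for target G2 across knockouts of G1,G2,G3 is [1,2,3]
        ko = square_ko([[9, 1, 9], [9, 2, 9], [9, 3, 9]], genes)
        prior = compute_prior(ko, genes, genes,
                              PriorConfig(fuse_knockout=True, sd_mode="sample"))
        assert prior.I[2, 1] == pytest.approx(1.0)   # G3 knockout -> G2
        assert prior.I[0, 1] == pytest.approx(1.0)   # |1-2|/1
        assert prior.I[1, 1] == 0.0                  # self-pair

    def test_value_at_mean_is_zero(self):
        genes = ["A", "B", "C"]
        # target B's column across the three knockouts is [2, 1, 3]:
        # A's knockout measured exactly the column mean (2)
        ko = square_ko([[9, 2, 9], [9, 1, 9], [9, 3, 9]], genes)
        prior = compute_prior(ko, genes, genes, PriorConfig(fuse_knockout=True))
        assert prior.I[0, 1] == pytest.approx(0.0, abs=1e-12)
        genes2 = ["A", "B"]
        ko2 = square_ko([[0.0, 5.0], [1.0, 5.0]], genes2)
        # column A: mean 0.5, sample sd ~0.707
        p2 = compute_prior(ko2, genes2, genes2, PriorConfig(fuse_knockout=True))
        assert p2.I[1, 0] == pytest.approx(abs(1.0 - 0.5) / np.std([0, 1], ddof=1))

    def test_disabled_prior_is_identity(self):
        genes = ["G1", "G2"]
        ko = square_ko([[1, 2], [3, 4]], genes)
        prior = compute_prior(ko, genes, genes, PriorConfig(fuse_knockout=False))
        expected = np.ones((2, 2))
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_array_equal(prior.I, expected)

    def test_zero_sd_column_neutral_with_warning(self, caplog):
        genes = ["G1", "G2", "G3"]
        ko = square_ko([[5, 1, 9], [5, 2, 8], [5, 3, 7]], genes)
        with caplog.at_level("WARNING"):
            prior = compute_prior(ko, genes, genes, PriorConfig(fuse_knockout=True))
        np.testing.assert_array_equal(prior.I[[1, 2], 0], [1.0, 1.0])
        assert any("zero knockout spread" in r.message for r in caplog.records)

    def test_regulator_without_knockout_row_is_neutral(self):
        ko = KnockoutMatrix(["G1", "G2"], ["G1", "G2", "G3"],
                            np.array([[0.0, 1.0, 2.0], [1.0, 3.0, 4.0]]))
        genes = ["G1", "G2", "G3"]
        prior = compute_prior(ko, genes, genes, PriorConfig(fuse_knockout=True))
        np.testing.assert_array_equal(prior.I[2, :2], [1.0, 1.0])

    def test_location_shift_and_scale_invariance(self):
        """Adding a constant to a gene's knockout column, or scaling it by
        c > 0, leaves the significance factors unchanged."""
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(5)]
        V = rng.uniform(0, 2, size=(5, 5))
        base = compute_prior(square_ko(V, genes), genes, genes,
                             PriorConfig(fuse_knockout=True))
        V2 = V.copy()
        V2[:, 3] += 7.5
        shifted = compute_prior(square_ko(V2, genes), genes, genes,
                                PriorConfig(fuse_knockout=True))
        np.testing.assert_allclose(shifted.I, base.I, atol=1e-10)
        V3 = V.copy()
        V3[:, 3] *= 3.25
        scaled = compute_prior(square_ko(V3, genes), genes, genes,
                               PriorConfig(fuse_knockout=True))
        np.testing.assert_allclose(scaled.I, base.I, atol=1e-10)

    def test_exclude_self_knockout_changes_stats(self):
        genes = ["G1", "G2"]
        ko = square_ko([[0.0, 2.0], [1.0, 0.0]], genes)
        with_self = compute_prior(ko, genes, genes, PriorConfig(fuse_knockout=True))
        without = compute_prior(
            ko, genes, genes,
            PriorConfig(fuse_knockout=True, exclude_self_knockout=True),
        )
        assert not np.allclose(with_self.I, without.I)

    def test_single_knockout_rejected(self):
        ko = KnockoutMatrix(["G1"], ["G1", "G2"], np.array([[0.0, 1.0]]))
        with pytest.raises(ValidationError):
            compute_prior(ko, ["G1", "G2"], ["G1", "G2"],
                          PriorConfig(fuse_knockout=True))


class TestFusePrior:
    def test_elementwise_product(self):
        regs, tgts = ["a", "b"], ["c"]
        conf = norm_cm([[0.6], [0.8]], regs, tgts)
        prior_mat = compute_prior(None, regs, tgts, PriorConfig(fuse_knockout=False))
        prior_mat.I[0, 0] = 2.0
        fused = fuse_prior(conf, prior_mat)
        assert fused.W[0, 0] == pytest.approx(1.2)
        assert fused.stage == "prior_fused"

    def test_identity_prior_is_noop(self):
        regs, tgts = ["a", "b"], ["c", "d"]
        rng = np.random.default_rng(1)
        conf = norm_cm(rng.uniform(0, 1, (2, 2)), regs, tgts)
        prior_mat = compute_prior(None, regs, tgts, PriorConfig(fuse_knockout=False))
        np.testing.assert_array_equal(fuse_prior(conf, prior_mat).W, conf.W)

    def test_zeros_preserved(self):
        regs, tgts = ["a", "b"], ["c"]
        conf = norm_cm([[0.0], [1.0]], regs, tgts)
        prior_mat = compute_prior(None, regs, tgts, PriorConfig(fuse_knockout=False))
        prior_mat.I[:] = 5.0
        assert fuse_prior(conf, prior_mat).W[0, 0] == 0.0

    def test_axis_mismatch_rejected(self):
        conf = norm_cm([[0.5]], ["a"], ["b"])
        prior_mat = compute_prior(None, ["x"], ["b"], PriorConfig())
        with pytest.raises(ValidationError):
            fuse_prior(conf, prior_mat)

    def test_raising_prior_never_lowers_rank(self):
        """Increasing one significance factor can only move that edge up
        the global ranking."""
        rng = np.random.default_rng(2)
        regs = [f"r{i}" for i in range(4)]
        tgts = [f"t{i}" for i in range(4)]
        W = rng.uniform(0, 1, size=(4, 4))
        conf = norm_cm(W, regs, tgts)
        for trial in range(20):
            I = rng.uniform(0.1, 2.0, size=(4, 4))
            i, j = rng.integers(4), rng.integers(4)
            pm1 = compute_prior(None, regs, tgts, PriorConfig())
            pm1.I = I
            pm2 = compute_prior(None, regs, tgts, PriorConfig())
            pm2.I = I.copy()
            pm2.I[i, j] *= 3.0
            edge = (regs[i], tgts[j])
            r1 = [(r, t) for r, t, _ in rank_edges(fuse_prior(conf, pm1)).entries]
            r2 = [(r, t) for r, t, _ in rank_edges(fuse_prior(conf, pm2)).entries]
            assert r2.index(edge) <= r1.index(edge)


class TestVarianceUpdate:
    def test_zero_row_stays_zero(self):
        conf = norm_cm([[0.0, 0.0], [0.3, 0.9]], ["a", "b"], ["c", "d"])
        out = variance_update(conf)
        np.testing.assert_array_equal(out.W[0], [0.0, 0.0])
        assert out.stage == "variance_scaled"

    def test_uniform_row_zeroed(self):
        conf = norm_cm([[0.4, 0.4, 0.4], [0.1, 0.5, 0.9]],
                       ["a", "b"], ["c", "d", "e"])
        out = variance_update(conf)
        np.testing.assert_array_equal(out.W[0], [0.0, 0.0, 0.0])

    def test_concentrated_row_beats_uniform_row_of_equal_sum(self):
        """A regulator holding one strong edge among near-zeros outranks a
        regulator spreading the same total weight uniformly."""
        regs, tgts = ["hub", "flat"], ["t1", "t2", "t3", "t4"]
        W = np.array([[0.97, 0.01, 0.01, 0.01],
                      [0.25, 0.25, 0.25, 0.25]])
        out = variance_update(norm_cm(W, regs, tgts))
        assert out.W[0, 0] > out.W[1, :].max()

    def test_row_rank_order_preserved(self):
        rng = np.random.default_rng(3)
        W = rng.uniform(0, 1, size=(3, 5))
        conf = norm_cm(W, ["a", "b", "c"], [f"t{i}" for i in range(5)])
        out = variance_update(conf)
        for i in range(3):
            np.testing.assert_array_equal(np.argsort(W[i]), np.argsort(out.W[i]))

    def test_self_column_excluded_from_variance(self):
        genes = ["a", "b", "c"]
        W = np.array([[0.0, 0.5, 0.5],
                      [0.2, 0.0, 0.8],
                      [0.3, 0.6, 0.0]])
        out = variance_update(norm_cm(W, genes, genes))
        # row a weights over {b, c} are constant -> variance 0 -> zero row
        np.testing.assert_array_equal(out.W[0], [0.0, 0.0, 0.0])
        assert out.W[1, 2] > 0

    def test_population_variance_convention(self):
        conf = norm_cm([[0.2, 0.8]], ["r"], ["t1", "t2"])
        out = variance_update(conf)
        assert out.W[0, 1] == pytest.approx(np.var([0.2, 0.8]) * 0.8)

    def test_stage_gate(self):
        raw = ConfidenceMatrix(regulator_ids=["a"], target_ids=["b"],
                               W=np.array([[1.0]]), stage="raw")
        with pytest.raises(ValidationError):
            variance_update(raw)
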
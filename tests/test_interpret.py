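"""PWM construction, MEME serialization, kernel motif extraction and
integrated-gradients properties."""

import numpy as np
import pytest

from transbind import (
    PositionWeightMatrix,
    attribution_to_pwm,
    integrated_gradients,
    kernel_to_pwm_activations,
    kernel_to_pwm_weights,
    read_meme,
    write_meme,
)
from transbind.interpret import AttributionMap, integrated_gradients_batch
from transbind.nn import Tensor


class TestPWM:
    def test_row_sum_validation(self):
        with pytest.raises(ValueError):
            PositionWeightMatrix("m", np.array([[0.5, 0.5, 0.5, 0.5]]))

    def test_from_counts_and_consensus(self):
        counts = np.array([[8, 1, 1, 0], [0, 0, 10, 0]])
        pwm = PositionWeightMatrix.from_counts("m", counts)
        assert pwm.consensus() == "AG"
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert pwm.nsites == 10

    def test_reverse_complement_involution(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(4), size=6)
        pwm = PositionWeightMatrix("m", probs)
        assert np.allclose(pwm.reverse_complement().reverse_complement().probs,
                           probs)

    def test_total_variation_zero_for_self(self):
        probs = np.full((3, 4), 0.25)
        pwm = PositionWeightMatrix("m", probs)
        assert np.allclose(pwm.column_total_variation(pwm), 0.0)


class TestMeme:
    def test_uniform_motif_block(self):
        pwm = PositionWeightMatrix("uniform", np.full((2, 4), 0.25))
        text = write_meme([pwm])
        assert "MEME version 4" in text
        assert "MOTIF uniform" in text
        assert "w= 2" in text
        assert text.count("0.250000") >= 8

    def test_write_read_write_idempotent(self):
        rng = np.random.default_rng(1)
        pwms = [
            PositionWeightMatrix(f"m{i}", rng.dirichlet(np.ones(4), size=5))
            for i in range(3)
        ]
        text1 = write_meme(pwms)
        back = read_meme(text1)
        text2 = write_meme(back)
        assert text1 == text2
        for orig, rt in zip(pwms, back):
            assert np.allclose(orig.probs, rt.probs, atol=1e-6)

    def test_block_count_matches_kernel_count(self):
        rng = np.random.default_rng(2)
        pwms = [
            kernel_to_pwm_weights(rng.normal(size=(8, 4)), name=f"kernel_{i}")
            for i in range(320)
        ]
        text = write_meme(pwms)
        assert text.count("MOTIF ") == 320
        names = [ln.split()[1] for ln in text.splitlines()
                 if ln.startswith("MOTIF")]
        assert names == [f"kernel_{i}" for i in range(320)]


class TestKernelToPWM:
    def test_softmax_saturation(self):
        k = np.zeros((4, 5))
        k[0, :] = 10.0
        pwm = kernel_to_pwm_weights(k)
        # e^10 / (e^10 + 3) = 1 - 1.36e-4
        assert np.all(pwm.probs[:, 0] > 1 - 2e-4)

    def test_flat_column_uniform(self):
        pwm = kernel_to_pwm_weights(np.zeros((4, 3)))
        assert np.allclose(pwm.probs, 0.25)

    def test_single_unit_weight(self):
        k = np.zeros((4, 1))
        k[0, 0] = 1.0
        pwm = kernel_to_pwm_weights(k)
        e = np.e
        assert pwm.probs[0, 0] == pytest.approx(e / (e + 3))
        assert pwm.probs[0, 1] == pytest.approx(1 / (e + 3))

    def test_activation_route_on_constant_sequences(self):
        # kernel maximal exactly on the prefix ACGT of every sequence
        kernel = np.eye(4)  # width 4, matches "ACGT"
        seqs = ["ACGTAAAA"] * 5
        pwm = kernel_to_pwm_activations(kernel, seqs, frac_of_max=1.0)
        assert pwm.consensus() == "ACGT"
        assert np.allclose(pwm.probs, np.eye(4))

    def test_unique_maximizer_single_site(self):
        kernel = np.eye(4) * 5
        seqs = ["ACGTTTTT", "TTTTTTTT"]
        pwm = kernel_to_pwm_activations(kernel, seqs, frac_of_max=1.0)
        assert pwm.counts.sum() == 4  # one site, one count per column

    def test_no_qualifying_site_errors(self):
        kernel = np.eye(4)  # positive max activation on "ACGT"
        with pytest.raises(ValueError):
            kernel_to_pwm_activations(kernel, ["ACGTAAAA"], frac_of_max=2.0)


class TestIntegratedGradients:
    def affine_forward(self, w, b=0.0):
        wt = Tensor(w)

        def forward(x):
            return (x * wt).sum() + Tensor(np.array(b))

        return forward

    def test_affine_closed_form_any_steps(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=(6, 4))
        x = rng.random((6, 4))
        base = rng.random((6, 4))
        for steps in (1, 7, 64):
            amap = integrated_gradients(self.affine_forward(w, 1.5), x,
                                        baseline=base, steps=steps)
            assert np.allclose(amap.matrix, (x - base) * w, atol=1e-12)
            assert amap.convergence_gap == pytest.approx(0.0, abs=1e-9)

    def test_zero_at_baseline(self):
        w = np.ones((4, 4))
        amap = integrated_gradients(self.affine_forward(w), np.zeros((4, 4)),
                                    steps=4)
        assert np.allclose(amap.matrix, 0.0)

    def test_gap_shrinks_with_steps_on_nonlinear_model(self):
        from transbind import PairwiseTransBind
        from transbind.interpret import pairwise_logit_fn
        from tests.test_model import tiny_config

        cfg = tiny_config(n_labels=1)
        model = PairwiseTransBind(cfg)
        rng = np.random.default_rng(4)
        idx = rng.integers(0, 4, cfg.input_len)
        x = np.zeros((cfg.input_len, 4))
        x[np.arange(cfg.input_len), idx] = 1
        fn = pairwise_logit_fn(model, rng.normal(size=cfg.d2))
        gap_small = integrated_gradients(fn, x, steps=4).convergence_gap
        gap_large = integrated_gradients(fn, x, steps=256).convergence_gap
        assert gap_large <= gap_small + 1e-9

    def test_batched_matches_sequential(self):
        rng = np.random.default_rng(5)
        w = rng.normal(size=(5, 4))
        wt = Tensor(w)

        def forward_one(x):
            return (x * wt * x).sum()  # quadratic, so steps matter

        def forward_batch(xb):
            return (xb * wt * xb).sum(axis=(1, 2))

        X = rng.random((3, 5, 4))
        singles = [integrated_gradients(forward_one, X[i], steps=16)
                   for i in range(3)]
        batched = integrated_gradients_batch(forward_batch, X, steps=16)
        for s, b in zip(singles, batched):
            assert np.allclose(s.matrix, b.matrix, atol=1e-10)
            assert s.convergence_gap == pytest.approx(b.convergence_gap,
                                                      abs=1e-9)


class TestAttributionToPWM:
    def map_for(self, seq, hot_start, width, strength=5.0):
        m = np.zeros((len(seq), 4))
        for i in range(hot_start, hot_start + width):
            m[i, "ACGT".index(seq[i])] = strength
        return AttributionMap(m, 0.0, 1.0)

    def test_concentrated_window_recovers_subsequence(self):
        seq = "AAAACGTGAAAA"
        amap = self.map_for(seq, 4, 4)
        pwm = attribution_to_pwm([amap], [seq], window_width=4, top_frac=1.0)
        assert pwm.consensus() == "CGTG"
        assert np.allclose(pwm.probs.max(axis=1), 1.0)

    def test_top_frac_zero_errors(self):
        seq = "ACGTACGT"
        with pytest.raises(ValueError):
            attribution_to_pwm([self.map_for(seq, 0, 4)], [seq],
                               window_width=4, top_frac=0.0)

    def test_mismatched_lengths_error(self):
        seq = "ACGTACGT"
        with pytest.raises(ValueError):
            attribution_to_pwm([self.map_for(seq, 0, 4)], [seq, seq],
                               window_width=4)

    def test_strand_mixture_is_canonicalized(self):
        # same motif planted forward in half the inputs and as reverse
        # complement in the other half: orientation EM must fold them onto
        # one strand so the PFM is not a 50/50 mixture
        fwd = "AAACGTAGGAAA"  # motif CGTAGG at position 3
        rc_motif = "CCTACG"
        rev = "AAA" + rc_motif + "AAA"
        maps = [self.map_for(fwd, 3, 6)] * 3 + [self.map_for(rev, 3, 6)] * 3
        seqs = [fwd] * 3 + [rev] * 3
        pwm = attribution_to_pwm(maps, seqs, window_width=6, top_frac=1.0)
        assert pwm.consensus() in ("CGTAGG", "CCTACG")
        assert np.allclose(pwm.probs.max(axis=1), 1.0)
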
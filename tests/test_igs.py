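"""Image stage: patch losses, feature matching, architecture contracts."""

import numpy as np
import pytest

from busynth import diffaug, igs
from busynth.nn import Tensor


class TestPatchLosses:
    def test_uniform_half_map(self):
        scores = np.full((2, 4, 4), 0.5)
        assert igs.igs_g_adv_loss(scores).item() == pytest.approx(np.log(0.5), abs=1e-12)

    def test_mixed_quarters_map(self):
        scores = np.array([[0.25, 0.75], [0.75, 0.25]])[None]
        expected = (np.log(0.75) + np.log(0.25)) / 2
        assert igs.igs_g_adv_loss(scores).item() == pytest.approx(expected, abs=1e-12)

    def test_single_patch_reduces_to_scalar_gan_loss(self):
        s = np.array([[[0.3]]])
        assert igs.igs_g_adv_loss(s).item() == pytest.approx(np.log(0.7), abs=1e-12)

    def test_d_loss_at_half(self):
        half = np.full((1, 3, 3), 0.5)
        assert igs.igs_d_loss(half, half).item() == pytest.approx(-2 * np.log(0.5), abs=1e-12)

    def test_d_loss_perfect_maps(self):
        real = np.full((1, 2, 2), 1 - 1e-12)
        fake = np.full((1, 2, 2), 1e-12)
        assert igs.igs_d_loss(real, fake).item() == pytest.approx(0.0, abs=1e-9)

    def test_d_loss_matches_per_patch_oracle(self):
        rng = np.random.default_rng(0)
        real = rng.uniform(0.1, 0.9, (2, 4, 4))
        fake = rng.uniform(0.1, 0.9, (2, 4, 4))
        expected = -np.mean(np.log(real)) - np.mean(np.log(1 - fake))
        assert igs.igs_d_loss(real, fake).item() == pytest.approx(expected, abs=1e-12)


class TestFeatureMatching:
    def _stacks(self, rng, shapes):
        return [rng.normal(size=s) for s in shapes]

    def test_identical_stacks_zero(self):
        rng = np.random.default_rng(1)
        feats = self._stacks(rng, [(2, 3, 4, 4), (2, 6, 2, 2)])
        assert igs.feature_matching_loss(feats, [f.copy() for f in feats]).item() == 0.0

    def test_constant_offset_gives_m_times_c(self):
        rng = np.random.default_rng(2)
        c = 0.37
        real = self._stacks(rng, [(2, 3, 4, 4), (2, 6, 2, 2), (2, 2, 8, 8)])
        fake = [f + c for f in real]
        assert igs.feature_matching_loss(real, fake).item() == pytest.approx(3 * c, rel=1e-9)

    def test_matches_brute_force_l1_oracle(self):
        rng = np.random.default_rng(3)
        shapes = [(3, 2, 3, 3), (3, 4, 2, 2)]
        real = self._stacks(rng, shapes)
        fake = self._stacks(rng, shapes)
        expected = 0.0
        for fr, ff in zip(real, fake):
            n_i = fr[0].size
            expected += np.abs(fr - ff).sum() / (n_i * fr.shape[0])
        assert igs.feature_matching_loss(real, fake).item() == pytest.approx(expected, abs=1e-9)

    def test_layer_count_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            igs.feature_matching_loss(self._stacks(rng, [(1, 2, 2, 2)]), [])

    def test_total_loss_linear_in_lambda(self):
        assert igs.igs_total_g_loss(-0.693147, 0.0, 10.0).item() == pytest.approx(-0.693147)
        assert igs.igs_total_g_loss(0.0, 0.2, 10.0).item() == pytest.approx(2.0)
        assert igs.igs_total_g_loss(-0.5, 0.13, 10.0).item() == pytest.approx(0.8)
        fm = 0.31
        vals = [igs.igs_total_g_loss(0.0, fm, lam).item() for lam in (0.0, 1.0, 2.0, 10.0)]
        assert vals == pytest.approx([0.0, fm, 2 * fm, 10 * fm])


@pytest.fixture(scope="module")
def small_igs():
    rng = np.random.default_rng(0)
    cfg = igs.IgsConfig(image_size=32, g2_widths=(6, 8, 10), d2_widths=(6, 8, 10), n_residual_blocks=2)
    return cfg, igs.Generator2(cfg, rng), igs.Discriminator2(cfg, rng)


class TestArchitecture:
    def test_paper_scale_contracts(self):
        cfg = igs.IgsConfig.paper_scale()
        assert cfg.bottleneck_size == 16  # 256 / 2^4
        assert cfg.patch_map_size == 16
        assert cfg.n_residual_blocks == 5
        assert cfg.lambda_fm == 10.0

    def test_patch_map_16_at_256(self):
        cfg = igs.IgsConfig(image_size=256, g2_widths=(3, 4, 5, 6), d2_widths=(3, 4, 5, 6))
        d2 = igs.Discriminator2(cfg, np.random.default_rng(1))
        m = np.zeros((1, 1, 256, 256), dtype=np.float32)
        x = np.zeros((1, 1, 256, 256), dtype=np.float32)
        psm = igs.d2_patch_scores(d2, m, x)
        assert psm.scores.shape == (1, 16, 16)
        assert psm.n_layers == 4  # one tap per down-sampling block

    def test_translate_output_shape_and_range(self, small_igs):
        cfg, g2, _ = small_igs
        masks = np.sign(np.random.default_rng(2).uniform(-1, 1, (3, 1, 32, 32))).astype(np.float32)
        out = igs.g2_translate(g2, masks)
        assert out.shape == (3, 1, 32, 32)
        assert np.all(np.abs(out.data) <= 1.0)

    def test_zeroed_residual_block_is_identity(self):
        rng = np.random.default_rng(3)
        block = igs._ResidualBlock(4, rng)
        block.conv1.weight.data[:] = 0
        block.conv1.bias.data[:] = 0
        block.conv2.weight.data[:] = 0
        block.conv2.bias.data[:] = 0
        block.norm2.gamma.data[:] = 0  # kill the normalized branch entirely
        x = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        assert np.allclose(block(x).data, x.data)

    def test_scores_in_unit_interval_and_features_retained(self, small_igs):
        cfg, g2, d2 = small_igs
        rng = np.random.default_rng(4)
        m = np.sign(rng.uniform(-1, 1, (2, 1, 32, 32))).astype(np.float32)
        x = rng.uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        psm = igs.d2_patch_scores(d2, m, x)
        assert np.all((psm.scores.data > 0) & (psm.scores.data < 1))
        assert psm.n_layers == len(cfg.d2_widths)

    def test_pair_shape_mismatch_rejected(self, small_igs):
        _, _, d2 = small_igs
        with pytest.raises(ValueError):
            igs.d2_patch_scores(d2, np.zeros((1, 1, 32, 32)), np.zeros((1, 1, 16, 16)))


class TestDamCoupling:
    def test_identity_policy_reduces_to_plain_losses(self, small_igs):
        cfg, g2, d2 = small_igs
        g2.eval(), d2.eval()
        rng = np.random.default_rng(5)
        m = np.sign(rng.uniform(-1, 1, (2, 1, 32, 32))).astype(np.float32)
        x = rng.uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        adv_dam, d_dam = igs.igs_losses_with_dam(g2, d2, m, x, diffaug.identity_policy(), rng)
        fake = igs.g2_translate(g2, m)
        adv_plain = igs.igs_g_adv_loss(d2(igs._pair(m, fake)))
        d_plain = igs.igs_d_loss(d2(igs._pair(m, x)), d2(igs._pair(m, fake.detach())))
        g2.train(), d2.train()
        assert adv_dam.item() == adv_plain.item()
        assert d_dam.item() == d_plain.item()

    def test_translation_moves_pair_coherently(self):
        """Under a spatial op the mask and image channels shift together."""
        rng = np.random.default_rng(6)
        pol = diffaug.AugPolicy(ops=("translation",), translation_fraction=0.25)
        mask = np.zeros((1, 1, 16, 16), dtype=np.float64)
        mask[0, 0, 4:8, 4:8] = 1.0
        pair = np.concatenate([mask, mask * 0.5], axis=1)
        out = diffaug.apply(pol, pair, rng, intensity_channels=slice(1, 2)).data
        assert np.array_equal(out[0, 0] * 0.5, out[0, 1])

    def test_fixed_seed_reproducible(self, small_igs):
        cfg, g2, d2 = small_igs
        g2.eval(), d2.eval()
        rng_data = np.random.default_rng(7)
        m = np.sign(rng_data.uniform(-1, 1, (2, 1, 32, 32))).astype(np.float32)
        x = rng_data.uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        pol = diffaug.default_policy()
        a = igs.igs_losses_with_dam(g2, d2, m, x, pol, np.random.default_rng(8))
        b = igs.igs_losses_with_dam(g2, d2, m, x, pol, np.random.default_rng(8))
        g2.train(), d2.train()
        assert a[0].item() == b[0].item() and a[1].item() == b[1].item()

    def test_fml_nonnegative_and_zero_iff_identical(self, small_igs):
        cfg, g2, d2 = small_igs
        d2.eval()
        rng = np.random.default_rng(9)
        m = np.sign(rng.uniform(-1, 1, (2, 1, 32, 32))).astype(np.float32)
        x = rng.uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        y = rng.uniform(-1, 1, (2, 1, 32, 32)).astype(np.float32)
        _, feats_x = d2.forward_features(igs._pair(m, x))
        _, feats_y = d2.forward_features(igs._pair(m, y))
        d2.train()
        assert igs.feature_matching_loss(feats_x, feats_x).item() == 0.0
        assert igs.feature_matching_loss(feats_x, feats_y).item() > 0.0
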
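"""Conditional VAE: posterior heads, KL, ELBO, training behaviour."""

import numpy as np
import pytest

import seqforge as sf
from seqforge.cvae import (
    ConditionalVAE,
    LatentPosterior,
    kl_divergence,
    reparameterize,
)


def _built_model(latent_dim=4, hidden=(8, 6, 4), max_length=5, attr_dim=3, seed=0):
    """A constructed (untrained) model for architectural checks."""
    model = ConditionalVAE(
        latent_dim=latent_dim, hidden_dims=hidden, max_length=max_length
    )
    model._build(max_length * 22, attr_dim, np.random.default_rng(seed))
    return model


class TestEncode:
    def test_identical_inputs_identical_posteriors(self):
        model = _built_model()
        x = np.ones(110) / 22
        a = np.zeros(3)
        p1, p2 = model.encode(x, a), model.encode(x, a)
        assert np.array_equal(p1.mu, p2.mu)
        assert np.array_equal(p1.sigma2, p2.sigma2)

    def test_sigma2_strictly_positive(self):
        model = _built_model()
        rng = np.random.default_rng(0)
        for _ in range(10):
            p = model.encode(rng.random(110), rng.random(3))
            assert np.all(p.sigma2 > 0)

    def test_zeroed_network_returns_head_biases(self):
        """With all weights zero, mu equals the mu-head bias and sigma2
        equals softplus of the sigma-head bias for any input."""
        model = _built_model()
        for arr in model._all_params().values():
            arr[...] = 0.0
        model.mu_head_.b[...] = [1.0, -2.0, 0.5, 0.0]
        model.sigma_head_.b[...] = [0.0, 1.0, -1.0, 2.0]
        p = model.encode(np.random.default_rng(1).random(110), np.zeros(3))
        assert p.mu == pytest.approx([1.0, -2.0, 0.5, 0.0])
        assert p.sigma2 == pytest.approx(np.logaddexp(0, model.sigma_head_.b), abs=1e-7)

    def test_dimension_mismatch_raises(self):
        model = _built_model()
        with pytest.raises(ValueError, match="features"):
            model.encode(np.zeros(100), np.zeros(3))
        with pytest.raises(ValueError, match="attribute"):
            model.encode(np.zeros(110), np.zeros(5))


class TestDecode:
    def test_output_in_open_unit_interval_and_right_length(self):
        model = _built_model()
        out = model.decode(np.zeros(4), np.zeros(3))
        assert out.shape == (1, 110)
        assert np.all(out > 0) and np.all(out < 1)

    def test_decoded_string_within_length_budget(self):
        model = _built_model()
        s = sf.decode_sequence(model.decode(np.ones(4), np.zeros(3))[0])
        assert len(s) <= 5


class TestReparameterize:
    def test_zero_variance_limit_returns_mean(self):
        p = LatentPosterior(np.array([1.0, -2.0]), np.array([1e-30, 1e-30]))
        z = reparameterize(p, 0)
        assert z == pytest.approx([1.0, -2.0], abs=1e-10)

    def test_same_seed_same_draw(self):
        p = LatentPosterior(np.zeros(16), np.ones(16))
        assert np.array_equal(reparameterize(p, 7), reparameterize(p, 7))

    def test_sample_mean_near_mu(self):
        """Mean of 100,000 draws within 4 sigma/sqrt(n) per coordinate."""
        mu = np.array([0.5, -1.0, 2.0])
        sigma2 = np.array([1.0, 4.0, 0.25])
        p = LatentPosterior(np.tile(mu, (100_000, 1)), np.tile(sigma2, (100_000, 1)))
        z = reparameterize(p, 123)
        bound = 4 * np.sqrt(sigma2) / np.sqrt(100_000)
        assert np.all(np.abs(z.mean(axis=0) - mu) < bound)


class TestKLDivergence:
    def test_zero_at_prior(self):
        assert kl_divergence(LatentPosterior(np.zeros(16), np.ones(16))) == 0.0

    def test_unit_mean_shift_is_half(self):
        assert kl_divergence(
            LatentPosterior(np.array([1.0]), np.array([1.0]))
        ) == pytest.approx(0.5)

    def test_nonnegative_on_random_posteriors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = LatentPosterior(rng.normal(size=8), rng.gamma(2.0, 1.0, size=8))
            assert kl_divergence(p) >= 0

    def test_matches_monte_carlo_estimate(self):
        """Closed form agrees with E_q[ln q - ln p] estimated from 10^6
        draws, within 3 standard errors."""
        rng = np.random.default_rng(5)
        mu = rng.normal(size=4)
        sigma2 = rng.gamma(2.0, 0.5, size=4)
        n = 1_000_000
        z = mu + np.sqrt(sigma2) * rng.standard_normal((n, 4))
        ln_q = -0.5 * (
            ((z - mu) ** 2) / sigma2 + np.log(2 * np.pi * sigma2)
        ).sum(axis=1)
        ln_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
        diff = ln_q - ln_p
        mc, se = diff.mean(), diff.std(ddof=1) / np.sqrt(n)
        exact = kl_divergence(LatentPosterior(mu, sigma2))
        assert abs(exact - mc) < 3 * se

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(LatentPosterior(np.zeros(2), np.array([1.0, 0.0])))


class TestElboLoss:
    def test_burnin_zero_total_equals_reconstruction(self):
        model = _built_model()
        rng = np.random.default_rng(2)
        X = np.stack([sf.encode_sequence("ACDEF", max_length=5)] * 3)
        A = rng.random((3, 3))
        total, recon, kl = model.elbo_loss(X, A, burnin_factor=0.0, rng_seed=0)
        assert total == recon
        assert kl >= 0

    def test_full_burnin_at_least_reconstruction(self):
        model = _built_model()
        X = np.stack([sf.encode_sequence("ACDEF", max_length=5)] * 3)
        A = np.zeros((3, 3))
        t1, r1, _ = model.elbo_loss(X, A, burnin_factor=1.0, rng_seed=0)
        t0, _, _ = model.elbo_loss(X, A, burnin_factor=0.0, rng_seed=0)
        assert t1 >= t0

    def test_invalid_burnin_rejected(self):
        model = _built_model()
        with pytest.raises(ValueError):
            model.elbo_loss(np.zeros((1, 110)), np.zeros((1, 3)), burnin_factor=1.5)


class TestTraining:
    def _family_arrays(self, n=120, length=40, seed=0):
        # families carry at most 50 homologues each, so stack several
        recs = []
        fam = 0
        while len(recs) < n:
            recs.extend(
                sf.generate_family(
                    sf.FamilySpec(f"fam{fam}", length=length, n_homologues=49,
                                  conservation=0.8, metal="Cu"),
                    rng_seed=seed + fam,
                )
            )
            fam += 1
        recs = recs[:n]
        return sf.build_training_arrays(recs, "metal", max_length=length), recs

    def test_same_seed_identical_traces(self):
        (X, A), _ = self._family_arrays()
        kw = dict(hidden_dims=(16, 12, 8), latent_dim=4, max_length=40,
                  batch_size=64, kl_burnin_epochs=3, max_epochs=8, random_state=3)
        m1 = ConditionalVAE(**kw).fit(X, A)
        m2 = ConditionalVAE(**kw).fit(X, A)
        assert m1.loss_trace_ == m2.loss_trace_

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            ConditionalVAE(max_length=5).fit(np.zeros((0, 110)), np.zeros((0, 3)))

    def test_burnin_factor_ramps_from_zero_to_one(self):
        (X, A), _ = self._family_arrays()
        m = ConditionalVAE(hidden_dims=(16, 12, 8), latent_dim=4, max_length=40,
                           batch_size=64, kl_burnin_epochs=5, max_epochs=10,
                           random_state=0).fit(X, A)
        factors = [row["burnin"] for row in m.loss_trace_]
        assert factors[0] < 1.0
        assert factors[-1] == 1.0
        assert factors == sorted(factors)

    def test_memorization_approaches_longer_run(self):
        """Reconstruction identity after the standard run reaches >= 90%
        of the level a 5x-epochs run attains on the same family (oracle
        = the longer run)."""
        (X, A), recs = self._family_arrays(n=100, length=36, seed=1)
        kw = dict(hidden_dims=(32, 24, 16), latent_dim=8, max_length=36,
                  batch_size=128, kl_burnin_epochs=20, random_state=0,
                  patience=10**6)

        def mean_identity(model):
            soft = model.reconstruct(X, A)
            idents = [
                sf.sequence_identity(r.sequence, sf.decode_sequence(row))
                for r, row in zip(recs, soft)
                if sf.decode_sequence(row)
            ]
            return np.mean(idents) if idents else 0.0

        short = ConditionalVAE(max_epochs=300, **kw).fit(X, A)
        long = ConditionalVAE(max_epochs=1500, **kw).fit(X, A)
        assert mean_identity(short) >= 0.9 * mean_identity(long)

    def test_loss_nonincreasing_across_windows(self, metal_cvae):
        """Epoch-mean total loss decreases within noise over 10-epoch
        windows once the KL weight is fully on."""
        trace = [
            row["total"] for row in metal_cvae.loss_trace_ if row["burnin"] >= 1.0
        ]
        windows = [
            np.mean(trace[i : i + 10]) for i in range(0, len(trace) - 9, 10)
        ]
        for earlier, later in zip(windows, windows[1:]):
            assert later <= earlier * 1.02  # 2% noise allowance

    def test_latent_space_clusters_families_with_two_dims(self):
        """A 2-dimensional latent model embeds same-family sequences
        closer together than across-family pairs."""
        recs = sf.generate_dataset(
            8, rng_seed=9, length=30, n_homologues=19, conservation=0.85,
            metals=(None,), with_negatives=False,
        )
        X, A = sf.build_training_arrays(recs, "metal", max_length=30)
        model = ConditionalVAE(
            hidden_dims=(32, 24, 16), latent_dim=2, max_length=30,
            batch_size=160, kl_burnin_epochs=20, max_epochs=120, random_state=0,
        ).fit(X, A)
        Z = model.transform(X, A)
        fams = np.array([r.family for r in recs])
        d = np.linalg.norm(Z[:, None, :] - Z[None, :, :], axis=-1)
        same = fams[:, None] == fams[None, :]
        off_diag = ~np.eye(len(recs), dtype=bool)
        within = d[same & off_diag].mean()
        across = d[~same].mean()
        assert within < across


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        model = _built_model()
        model.loss_trace_ = []
        path = tmp_path / "model.npz"
        model.save(path)
        back = ConditionalVAE.load(path)
        x = np.random.default_rng(0).random(110)
        a = np.zeros(3)
        p1, p2 = model.encode(x, a), back.encode(x, a)
        assert np.allclose(p1.mu, p2.mu)
        assert np.allclose(p1.sigma2, p2.sigma2)
        assert np.allclose(model.decode(p1.mu, a), back.decode(p2.mu, a))
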
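"""Metal-binding discriminator: loss, splits, early stopping, ranking."""

import numpy as np
import pytest

import seqforge as sf
from seqforge.discriminator import (
    MetalBindingClassifier,
    family_split,
    inverse_frequency_weights,
    weighted_bce,
)


def _built_classifier(max_length=5, hidden=(16, 8), seed=0):
    clf = MetalBindingClassifier(hidden_dims=hidden)
    clf._build(max_length * 22, np.random.default_rng(seed))
    return clf


class TestPredict:
    def test_output_is_8_probabilities(self):
        clf = _built_classifier()
        p = clf.predict_proba(np.random.default_rng(0).random(110))
        assert p.shape == (1, 8)
        assert np.all((p > 0) & (p < 1))

    def test_deterministic(self):
        clf = _built_classifier()
        x = np.random.default_rng(1).random((4, 110))
        assert np.array_equal(clf.predict_proba(x), clf.predict_proba(x))

    def test_zeroed_weights_give_constant_sigmoid_bias(self):
        clf = _built_classifier()
        for arr in clf._arrays().values():
            arr[...] = 0.0
        clf.head_.b[...] = np.linspace(-2, 2, 8)
        rng = np.random.default_rng(2)
        p1 = clf.predict_proba(rng.random(110))
        p2 = clf.predict_proba(rng.random(110))
        expected = 1 / (1 + np.exp(-clf.head_.b))
        assert p1[0] == pytest.approx(expected)
        assert np.array_equal(p1, p2)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="features"):
            _built_classifier().predict_proba(np.zeros(50))


class TestWeightedBCE:
    def test_perfect_prediction_near_zero(self):
        t = np.array([1, 0, 1, 0, 0, 0, 1, 0], float)
        assert weighted_bce(t, t) < 1e-5

    def test_uniform_half_prediction_is_8_ln2(self):
        pred = np.full(8, 0.5)
        target = np.zeros(8)
        assert weighted_bce(pred, target) == pytest.approx(8 * np.log(2))

    def test_doubling_a_weight_doubles_its_contribution(self):
        pred = np.full(8, 0.3)
        target = np.ones(8)
        w = np.ones(8)
        base = weighted_bce(pred, target, w)
        w2 = w.copy()
        w2[2] *= 2
        per_class = -np.log(0.3)
        assert weighted_bce(pred, target, w2) == pytest.approx(base + per_class)

    def test_extreme_predictions_are_clamped(self):
        assert np.isfinite(weighted_bce(np.zeros(8), np.ones(8)))


class TestClassWeights:
    def test_inverse_frequency_and_mean_one(self):
        Y = np.zeros((100, 8))
        Y[:50, 0] = 1  # common metal
        Y[:5, 1] = 1   # rare metal
        Y[:10, 2:] = 1
        w = inverse_frequency_weights(Y)
        assert w.mean() == pytest.approx(1.0)
        assert w[1] / w[0] == pytest.approx(10.0)  # 50/5

    def test_weighting_improves_rare_class_recall(self):
        """On a 1:9 imbalanced single-metal problem the weighted model
        recalls more rare positives than the unweighted one, same seed."""
        rng = np.random.default_rng(0)
        specs = []
        for f in range(20):
            metal = "Ni" if f < 2 else None  # 1:9 families
            specs.append(
                sf.FamilySpec(f"fam{f}", length=48, n_homologues=17,
                              conservation=0.8, metal=metal)
            )
        recs = [
            r for i, s in enumerate(specs) for r in sf.generate_family(s, 100 + i)
        ]
        X = np.stack([sf.encode_sequence(r.sequence, max_length=48) for r in recs])
        Y = np.stack([np.asarray(r.metal_flags, float) for r in recs])
        order = rng.permutation(len(recs))
        cut = int(0.75 * len(recs))
        tr, te = order[:cut], order[cut:]
        kw = dict(hidden_dims=(32, 16), batch_size=128, max_epochs=8,
                  random_state=0)
        m_w = MetalBindingClassifier(class_weight="inverse_frequency", **kw)
        m_u = MetalBindingClassifier(class_weight=None, **kw)
        m_w.fit(X[tr], Y[tr], validation=(X[te], Y[te]))
        m_u.fit(X[tr], Y[tr], validation=(X[te], Y[te]))
        ni = sf.METALS.index("Ni")
        pos = Y[te][:, ni] == 1
        if pos.sum() == 0:
            pytest.skip("no rare positives in the holdout draw")
        recall_w = m_w.predict(X[te])[pos, ni].mean()
        recall_u = m_u.predict(X[te])[pos, ni].mean()
        assert recall_w >= recall_u


class TestFamilySplit:
    def _records(self, sizes, seed=0):
        recs = []
        for f, size in enumerate(sizes):
            for k in range(size):
                recs.append(
                    sf.SequenceRecord(id=f"f{f}_r{k}", sequence="ACDEFGHIK",
                                      family=f"fam{f}")
                )
        return recs

    def test_families_are_atomic(self):
        recs = self._records([30, 20, 10, 10, 5, 5, 5, 5, 5, 5])
        train_ids, val_ids = family_split(recs, fraction=0.2, rng_seed=1)
        by_id = {r.id: r.family for r in recs}
        assert {by_id[i] for i in train_ids}.isdisjoint({by_id[i] for i in val_ids})
        assert sorted(train_ids + val_ids) == sorted(r.id for r in recs)

    def test_two_families_never_straddle(self):
        recs = self._records([4, 4])
        train_ids, val_ids = family_split(recs, fraction=0.5, rng_seed=0)
        fams = lambda ids: {i.split("_")[0] for i in ids}
        assert fams(train_ids).isdisjoint(fams(val_ids))

    def test_forced_id_drags_whole_family(self):
        recs = self._records([10, 10, 10, 10, 10])
        _, val_ids = family_split(
            recs, fraction=0.2, rng_seed=0, force_validation=("f3_r7",)
        )
        assert {i for i in val_ids if i.startswith("f3_")} == {
            f"f3_r{k}" for k in range(10)
        }

    def test_deterministic(self):
        recs = self._records([8, 8, 8, 8, 8])
        assert family_split(recs, rng_seed=4) == family_split(recs, rng_seed=4)

    def test_validation_fraction_approximate(self):
        recs = self._records([10] * 20)
        _, val_ids = family_split(recs, fraction=0.1, rng_seed=0)
        assert 0.05 <= len(val_ids) / len(recs) <= 0.2

    def test_missing_family_label_rejected(self):
        recs = [sf.SequenceRecord(id="x", sequence="ACD")]
        with pytest.raises(ValueError, match="family"):
            family_split(recs)


class TestTraining:
    def test_early_stopping_keeps_argmin_checkpoint(self, trained_discriminator):
        clf = trained_discriminator
        assert clf.best_epoch_ == int(np.argmin(clf.validation_losses_))

    def test_restored_model_attains_best_validation_loss(self, discriminator_split):
        X_tr, Y_tr, X_val, Y_val = discriminator_split
        clf = MetalBindingClassifier(
            hidden_dims=(32, 16), batch_size=256, max_epochs=10, random_state=1
        ).fit(X_tr, Y_tr, validation=(X_val, Y_val))
        loss = weighted_bce(clf.predict_proba(X_val), Y_val, clf.class_weights_)
        assert loss == pytest.approx(min(clf.validation_losses_), rel=1e-9)

    def test_same_seed_same_checkpoint(self, discriminator_split):
        X_tr, Y_tr, X_val, Y_val = discriminator_split
        kw = dict(hidden_dims=(32, 16), batch_size=256, max_epochs=5,
                  random_state=2)
        c1 = MetalBindingClassifier(**kw).fit(X_tr, Y_tr, validation=(X_val, Y_val))
        c2 = MetalBindingClassifier(**kw).fit(X_tr, Y_tr, validation=(X_val, Y_val))
        assert c1.best_epoch_ == c2.best_epoch_
        assert np.array_equal(c1.predict_proba(X_val), c2.predict_proba(X_val))


class TestRanking:
    def test_singleton_list(self, trained_discriminator):
        seq = "ACDEFGHIKLMNPQRSTVWY" * 3
        ranked = trained_discriminator.rank_candidates(
            [seq], "Cu",
            encode=lambda s: sf.encode_sequence(s, max_length=60),
        )
        assert [s for s, _ in ranked] == [seq]

    def test_duplicates_stay_adjacent_and_top_is_max(self, trained_discriminator):
        rng = np.random.default_rng(0)
        aas = sf.codec.STANDARD_AA
        seqs = ["".join(rng.choice(list(aas), 60)) for _ in range(6)]
        seqs = [seqs[0]] + seqs + [seqs[0]]  # duplicate first sequence
        enc = lambda s: sf.encode_sequence(s, max_length=60)
        ranked = trained_discriminator.rank_candidates(seqs, "Cu", encode=enc)
        probs = [p for _, p in ranked]
        assert probs == sorted(probs, reverse=True)
        dup_idx = [i for i, (s, _) in enumerate(ranked) if s == seqs[0]]
        assert dup_idx == list(range(dup_idx[0], dup_idx[0] + 3))

    def test_unknown_metal_rejected(self, trained_discriminator):
        with pytest.raises(ValueError, match="unknown metal"):
            trained_discriminator.rank_candidates(["ACD"], "Pb")


def test_save_load_round_trip(tmp_path, trained_discriminator):
    path = tmp_path / "clf.npz"
    trained_discriminator.save(path)
    back = MetalBindingClassifier.load(path)
    x = np.random.default_rng(0).random((3, trained_discriminator.n_features_in_))
    assert np.allclose(trained_discriminator.predict_proba(x), back.predict_proba(x))
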
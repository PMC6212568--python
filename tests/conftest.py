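"""Shared fixtures: synthetic datasets and small trained models.

Training fixtures are session-scoped because fitting even the reduced
networks takes on the order of a minute; every test that needs a fitted
model shares the same deterministic run (fixed seeds throughout).
"""

import numpy as np
import pytest

import seqforge as sf

# Reduced study scale used by all training fixtures: 60-residue
# sequences, narrow MLPs, ~1000-2000 records.
TINY_LENGTH = 60
TINY_HIDDEN = (128, 64, 32)


@pytest.fixture(scope="session")
def metal_records():
    """~2000 records: 25 copper families (native + 39 homologues each)
    plus the negative twin of every flagged record."""
    return sf.generate_dataset(
        25, rng_seed=7, length=TINY_LENGTH, n_homologues=39,
        conservation=0.8, metals=("Cu",),
    )


@pytest.fixture(scope="session")
def metal_arrays(metal_records):
    return sf.build_training_arrays(metal_records, "metal", max_length=TINY_LENGTH)


@pytest.fixture(scope="session")
def metal_cvae(metal_arrays):
    """Metal-conditioned CVAE trained to convergence at desk scale."""
    X, A = metal_arrays
    model = sf.ConditionalVAE(
        hidden_dims=TINY_HIDDEN, latent_dim=16, max_length=TINY_LENGTH,
        batch_size=256, kl_burnin_epochs=50, max_epochs=300,
        tol=1e-4, patience=20, random_state=0,
    )
    return model.fit(X, A)


@pytest.fixture(scope="session")
def grammar_records():
    """Topology-labelled families for the grammar-conditioned model.

    Four distinct folds shared by four families each, so the topology
    attribute narrows generation to a fold while the latent code must
    still identify the family — mirroring real fold space, where one
    topology string covers many families."""
    return sf.generate_dataset(
        16, rng_seed=21, length=TINY_LENGTH, n_homologues=30,
        conservation=0.8, metals=(None,), with_topologies=True,
        n_topologies=4, with_negatives=False,
    )


@pytest.fixture(scope="session")
def grammar_cvae(grammar_records):
    X, A = sf.build_training_arrays(
        grammar_records, "grammar", max_length=TINY_LENGTH
    )
    model = sf.ConditionalVAE(
        hidden_dims=TINY_HIDDEN, latent_dim=16, max_length=TINY_LENGTH,
        batch_size=256, kl_burnin_epochs=40, max_epochs=150,
        tol=1e-4, patience=20, random_state=1,
    )
    return model.fit(X, A)


@pytest.fixture(scope="session")
def mixed_metal_records():
    """Families cycling through all 8 metals, for the discriminator."""
    return sf.generate_dataset(
        32, rng_seed=3, length=TINY_LENGTH, n_homologues=20,
        conservation=0.8, metals=sf.METALS,
    )


@pytest.fixture(scope="session")
def discriminator_split(mixed_metal_records):
    """Family-disjoint arrays (X_tr, Y_tr, X_val, Y_val)."""
    records = mixed_metal_records
    train_ids, val_ids = sf.family_split(records, fraction=0.25, rng_seed=0)
    by_id = {r.id: r for r in records}

    def arrays(ids):
        X = np.stack(
            [sf.encode_sequence(by_id[i].sequence, max_length=TINY_LENGTH)
             for i in ids]
        )
        Y = np.stack([np.asarray(by_id[i].metal_flags, float) for i in ids])
        return X, Y

    return (*arrays(train_ids), *arrays(val_ids))


@pytest.fixture(scope="session")
def trained_discriminator(discriminator_split):
    X_tr, Y_tr, X_val, Y_val = discriminator_split
    clf = sf.MetalBindingClassifier(
        hidden_dims=TINY_HIDDEN, batch_size=256, max_epochs=60, random_state=0,
    )
    return clf.fit(X_tr, Y_tr, validation=(X_val, Y_val))
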
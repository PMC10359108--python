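import numpy as np
import pytest

import synpair as sp


@pytest.fixture(scope="session")
def tiny_world():
    """A small, fast synthetic world with low measurement noise."""
    cfg = sp.WorldConfig(
        n_genes=40,
        n_ccls=6,
        n_drugs=8,
        landmark_dim=6,
        latent_dim=3,
        noise_sd=0.02,
        inconsistent_fraction=0.1,
        seed=3,
    )
    return sp.generate_world(cfg)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_world):
    """Augmented model-ready samples plus per-sample ground truth."""
    measurements, _ = sp.sample_measurements(tiny_world, 120)
    samples, truth, report = sp.make_model_ready(tiny_world, measurements)
    return samples, truth, report


@pytest.fixture(scope="session")
def tiny_estimator(tiny_dataset):
    """A quickly trained small estimator (not meant to be accurate)."""
    samples, _, _ = tiny_dataset
    X, Y, _ = sp.samples_to_arrays(samples)
    est = sp.SynergyRegressor(
        drug_dim=samples[0].drug_dim,
        width_scale=0.02,
        max_epochs=3,
        batch_size=32,
        random_state=0,
    )
    est.fit(X, Y)
    return est


def make_toy_samples(n_drugs=5, n_ccls=3, drug_dim=2, ccl_dim=2, seed=0):
    """Cheap TripleSamples over all pairs x CCLs with tiny feature vectors."""
    rng = np.random.default_rng(seed)
    drugs = [f"d{i}" for i in range(n_drugs)]
    ccls = [f"c{j}" for j in range(n_ccls)]
    feats = {d: rng.normal(size=drug_dim) for d in drugs}
    cfeats = {c: rng.normal(size=ccl_dim) for c in ccls}
    samples = []
    for i in range(n_drugs):
        for j in range(i + 1, n_drugs):
            for c in ccls:
                d1, d2 = drugs[i], drugs[j]
                x_pair = np.concatenate([feats[d1], feats[d2]])
                samples.append(
                    sp.TripleSample(
                        pair_key=(d1, d2),
                        ccl_id=c,
                        ordered_drugs=(d1, d2),
                        x_pair=x_pair,
                        x_triple=np.concatenate([x_pair, cfeats[c]]),
                        y=rng.normal(size=3),
                    )
                )
    return samples
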
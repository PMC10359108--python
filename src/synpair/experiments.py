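"""Reference desk-scale experiments bundled with the package.

These compose the synthetic generator, the preprocessing pipeline and the
scaled-down model into reproducible studies: a learnability / parameter
recovery check (can the network recover a known synergy function from a
few thousand noisy samples?) and its label-shuffled null control.
"""

from __future__ import annotations

import numpy as np

from .data import samples_to_arrays
from .evaluation import regression_metrics, split_leave_triple_out
from .model import SynergyRegressor
from .synthetic import generate_world, learnability_config, make_model_ready, sample_measurements

__all__ = ["run_learnability_study"]


def run_learnability_study(
    seed: int = 1,
    n_triples: int = 2300,
    n_samples: int = 4000,
    width_scale: float = 1 / 8,
    max_epochs: int = 120,
    patience: int = 12,
    include_null: bool = True,
    include_single_task: bool = True,
) -> dict:
    """Train the scaled-down model on synthetic data and score recovery.

    Generates a low-noise world, runs the full preprocessing pipeline,
    keeps ``n_samples`` augmented samples, holds out one leave-triple-out
    fold and reports the held-out metrics against the *ground-truth*
    synergy (not the noisy measurements). Optionally adds a label-shuffled
    null control and a single-task variant for comparison.
    """
    world = generate_world(learnability_config(seed=seed))
    measurements, _ = sample_measurements(world, n_triples)
    samples, truth, _ = make_model_ready(world, measurements)
    if len(samples) < n_samples:
        raise RuntimeError(
            f"pipeline kept only {len(samples)} samples; need {n_samples}"
        )
    samples, truth = samples[:n_samples], truth[:n_samples]
    X, Y, _ = samples_to_arrays(samples)
    fold = split_leave_triple_out(samples, k=5, seed=seed)
    tr, te = fold.train_indices(0), fold.test_indices(0)

    est = SynergyRegressor(
        drug_dim=samples[0].drug_dim,
        width_scale=width_scale,
        max_epochs=max_epochs,
        patience=patience,
        random_state=seed,
    )
    est.fit(X[tr], Y[tr])
    pred = est.predict(X[te])[:, 0]
    metrics = regression_metrics(truth[te], pred)
    out = {
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "pcc_vs_truth": metrics["pcc"],
        "scc_vs_truth": metrics["scc"],
        "rmse_vs_truth": metrics["rmse"],
        "multitask_synergy_mse": float(np.mean((pred - Y[te, 0]) ** 2)),
        "best_epoch": est.history_["best_epoch"],
    }

    if include_null:
        rng = np.random.default_rng(seed + 1000)
        Y_null = Y[tr][rng.permutation(len(tr))]
        null = SynergyRegressor(
            drug_dim=samples[0].drug_dim,
            width_scale=width_scale,
            max_epochs=max_epochs,
            patience=patience,
            random_state=seed,
        )
        null.fit(X[tr], Y_null)
        null_pred = null.predict(X[te])[:, 0]
        out["null_pcc_vs_truth"] = regression_metrics(truth[te], null_pred)["pcc"]

    if include_single_task:
        single = SynergyRegressor(
            variant="single_task",
            drug_dim=samples[0].drug_dim,
            width_scale=width_scale,
            max_epochs=max(10, max_epochs // 3),
            patience=patience,
            random_state=seed,
        )
        single.fit(X[tr], Y[tr, 0])
        single_pred = single.predict(X[te])
        out["single_task_synergy_mse"] = float(np.mean((single_pred - Y[te, 0]) ** 2))
        out["single_task_final_train_loss"] = float(single.history_["train_loss"][-1])

    return out
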
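"""Seeded synthetic worlds with a known ground-truth synergy function.

The generator emulates the statistical shape of the three real inputs --
a baseline expression matrix, per-drug landmark signatures with replicates,
and a replicate-structured synergy screen -- from a low-dimensional latent
model, so that every pipeline stage is testable without downloads and
learning can be asserted against ground truth.

Latent model
------------
Each drug d carries a latent factor ``f(d)`` and each cell line c a latent
factor ``g(c)`` (standard normal, ``latent_dim`` components). Ground-truth
synergy is the symmetric bilinear-plus-additive form

    s(d1, d2, c) = scale * ( f(d1)^T W f(d2) + g(c)^T (f(d1) + f(d2)) )

with W symmetric, rescaled once per world so scores have a standard
deviation of about 10 (spanning roughly [-30, 30], matching the magnitude
range of the binarization thresholds). Single-drug response is
``r(d, c) = 50 + scale_r * g(c)^T B f(d)``, on a 0-100-like scale.

Observables are noisy views of the latents: signatures are linear images of
drug factors per signature cell line (plus replicate noise), and expressed
genes are affine images of CCL factors on a non-negative log2(RPKM+1)-like
scale. A fraction of genes is lowly expressed and a fraction low-variance,
so the gene filters have a nontrivial effect. A fraction of measurement
groups is corrupted (sign flips or inflated spread) so the
replicate-consistency filters have real work to do.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import (
    DrugSignatureSet,
    ExpressionMatrix,
    FilterConfig,
    SynergyRecord,
    TripleSample,
    ValidationError,
    assemble_dataset,
    augment_order_swap,
    filter_genes,
    filter_synergy_replicates,
    write_expression_matrix,
    write_signature_table,
    write_synergy_table,
    zscore_genes,
)

__all__ = [
    "WorldConfig",
    "SyntheticWorld",
    "generate_world",
    "sample_measurements",
    "make_model_ready",
    "write_world_files",
    "learnability_config",
]

_SYNERGY_TARGET_SD = 10.0
_RI_CENTER = 50.0
_RI_TARGET_SD = 15.0
_SIGNATURE_NOISE_SD = 0.05
_SPREAD_CORRUPTION_SD = 2.0

#: gene class mix: informative / lowly expressed / low variance
_GENE_CLASS_FRACS = (0.60, 0.25, 0.15)


@dataclass(frozen=True)
class WorldConfig:
    """Sizes, noise levels and seed of a synthetic world."""

    n_genes: int = 200
    n_ccls: int = 12
    n_drugs: int = 30
    landmark_dim: int = 50
    n_signature_ccls: int = 2
    latent_dim: int = 8
    noise_sd: float = 1.0
    replicate_count_range: tuple[int, int] = (1, 4)
    inconsistent_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_ccls", "n_drugs", "landmark_dim", "n_signature_ccls", "latent_dim"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        lo, hi = self.replicate_count_range
        if not (1 <= lo <= hi):
            raise ValidationError("replicate_count_range must satisfy 1 <= lo <= hi")
        if not (0.0 <= self.inconsistent_fraction <= 1.0):
            raise ValidationError("inconsistent_fraction must lie in [0, 1]")


def learnability_config(seed: int = 0) -> WorldConfig:
    """The low-noise study configuration used for learning-recovery experiments.

    Measurement noise is kept below the replicate-std gate so the
    consistency filters retain the consistent groups, and the drug/CCL
    counts afford a few thousand kept triples.
    """
    return WorldConfig(
        n_genes=200,
        n_ccls=15,
        n_drugs=40,
        landmark_dim=50,
        n_signature_ccls=2,
        latent_dim=8,
        noise_sd=0.05,
        replicate_count_range=(1, 4),
        inconsistent_fraction=0.05,
        seed=seed,
    )


@dataclass
class SyntheticWorld:
    """A generated world: observable inputs plus the latent ground truth."""

    config: WorldConfig
    expression: ExpressionMatrix
    signatures: DrugSignatureSet
    drug_ids: tuple[str, ...]
    ccl_ids: tuple[str, ...]
    drug_latents: dict[str, np.ndarray]
    ccl_latents: dict[str, np.ndarray]
    interaction: np.ndarray  # symmetric latent x latent
    ri_coupling: np.ndarray
    synergy_scale: float
    ri_scale: float

    def true_synergy(self, drug1_id: str, drug2_id: str, ccl_id: str) -> float:
        f1 = self.drug_latents[drug1_id]
        f2 = self.drug_latents[drug2_id]
        g = self.ccl_latents[ccl_id]
        raw = f1 @ self.interaction @ f2 + g @ (f1 + f2)
        return float(self.synergy_scale * raw)

    def true_ri(self, drug_id: str, ccl_id: str) -> float:
        f = self.drug_latents[drug_id]
        g = self.ccl_latents[ccl_id]
        return float(_RI_CENTER + self.ri_scale * (g @ self.ri_coupling @ f))

    def all_triples(self) -> list[tuple[str, str, str]]:
        return [
            (d1, d2, c)
            for d1, d2 in itertools.combinations(self.drug_ids, 2)
            for c in self.ccl_ids
        ]


def _expression_frame(cfg: WorldConfig, ccl_latents: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Genes x CCLs on a non-negative log2(RPKM+1)-like scale."""
    n_info = int(round(_GENE_CLASS_FRACS[0] * cfg.n_genes))
    n_low = int(round(_GENE_CLASS_FRACS[1] * cfg.n_genes))
    n_flat = cfg.n_genes - n_info - n_low
    values = np.empty((cfg.n_genes, cfg.n_ccls))
    classes = np.array(["info"] * n_info + ["low"] * n_low + ["flat"] * n_flat)
    rng.shuffle(classes)
    loadings = rng.normal(size=(cfg.n_genes, cfg.latent_dim))
    for i, cls in enumerate(classes):
        if cls == "info":
            row = 4.0 + loadings[i] @ ccl_latents.T + rng.normal(0.0, 0.3, cfg.n_ccls)
            values[i] = np.clip(row, 0.0, None)
        elif cls == "low":
            values[i] = np.abs(rng.normal(0.35, 0.25, cfg.n_ccls))
        else:  # expressed but nearly constant -> fails the variance gate
            values[i] = rng.uniform(1.5, 4.0) + rng.normal(0.0, 0.15, cfg.n_ccls)
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    ccls = [f"CCL{j:03d}" for j in range(cfg.n_ccls)]
    return pd.DataFrame(values, index=genes, columns=ccls)


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Deterministically generate a world from its configuration."""
    root = np.random.SeedSequence(cfg.seed)
    rng_latent, rng_expr, rng_sig = (np.random.default_rng(s) for s in root.spawn(3))

    drug_ids = tuple(f"drug{i:03d}" for i in range(cfg.n_drugs))
    ccl_ids = tuple(f"CCL{j:03d}" for j in range(cfg.n_ccls))
    F = rng_latent.normal(size=(cfg.n_drugs, cfg.latent_dim))
    G = rng_latent.normal(size=(cfg.n_ccls, cfg.latent_dim))
    A = rng_latent.normal(size=(cfg.latent_dim, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)
    W = 0.5 * (A + A.T)
    B = rng_latent.normal(size=(cfg.latent_dim, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)

    # one-off rescale so synergy scores have sd ~ 10 across the full universe
    bilinear = np.einsum("ik,kl,jl->ij", F, W, F)
    GF = G @ F.T  # (n_ccls, n_drugs)
    iu = np.triu_indices(cfg.n_drugs, k=1)
    raw = bilinear[iu][None, :] + GF[:, iu[0]] + GF[:, iu[1]]
    synergy_scale = _SYNERGY_TARGET_SD / max(raw.std(), 1e-12)
    ri_raw = np.einsum("ck,kl,dl->cd", G, B, F)
    ri_scale = _RI_TARGET_SD / max(ri_raw.std(), 1e-12)

    expression = ExpressionMatrix(_expression_frame(cfg, G, rng_expr), normalized=False)

    sig_ccls = tuple(f"SIG{k}" for k in range(cfg.n_signature_ccls))
    entries: dict[tuple[str, str, str], np.ndarray] = {}
    projections = [
        rng_sig.normal(size=(cfg.landmark_dim, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)
        for _ in sig_ccls
    ]
    for d_idx, drug in enumerate(drug_ids):
        for k, sig_ccl in enumerate(sig_ccls):
            n_rep = int(rng_sig.integers(1, 4))
            base = projections[k] @ F[d_idx]
            for r in range(n_rep):
                entries[(drug, sig_ccl, f"rep{r}")] = base + rng_sig.normal(
                    0.0, _SIGNATURE_NOISE_SD, cfg.landmark_dim
                )
    signatures = DrugSignatureSet(entries, landmark_dim=cfg.landmark_dim, signature_ccl_order=sig_ccls)

    return SyntheticWorld(
        config=cfg,
        expression=expression,
        signatures=signatures,
        drug_ids=drug_ids,
        ccl_ids=ccl_ids,
        drug_latents={d: F[i] for i, d in enumerate(drug_ids)},
        ccl_latents={c: G[j] for j, c in enumerate(ccl_ids)},
        interaction=W,
        ri_coupling=B,
        synergy_scale=synergy_scale,
        ri_scale=ri_scale,
    )


def sample_measurements(
    world: SyntheticWorld,
    n_triples: int,
    score_type: str = "ZIP",
) -> tuple[list[SynergyRecord], dict[tuple[tuple[str, str], str], bool]]:
    """Draw replicate measurement groups for ``n_triples`` distinct triples.

    Consistent groups get 1-4 replicates of truth + N(0, noise_sd).
    A fraction ``inconsistent_fraction`` of groups is corrupted (always with
    at least two replicates, since a singleton cannot violate either filter
    rule): half by flipping the sign of about half the replicates, half by
    inflating the replicate spread. Returns the records plus a ground-truth
    map (pair_key, ccl) -> should_pass for oracle tests.
    """
    cfg = world.config
    universe = world.all_triples()
    if n_triples > len(universe):
        raise ValidationError(f"n_triples={n_triples} exceeds the {len(universe)} available triples")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    chosen = rng.choice(len(universe), size=n_triples, replace=False)
    lo, hi = cfg.replicate_count_range
    records: list[SynergyRecord] = []
    should_pass: dict[tuple[tuple[str, str], str], bool] = {}
    for idx in chosen:
        d1, d2, ccl = universe[idx]
        truth = world.true_synergy(d1, d2, ccl)
        ri1, ri2 = world.true_ri(d1, ccl), world.true_ri(d2, ccl)
        corrupt = rng.random() < cfg.inconsistent_fraction
        n_rep = int(rng.integers(max(2, lo) if corrupt else lo, hi + 1))
        scores = truth + rng.normal(0.0, cfg.noise_sd, n_rep)
        if corrupt:
            if rng.random() < 0.5:  # sign flips on ~half the replicates
                n_flip = max(1, n_rep // 2)
                flip_idx = rng.choice(n_rep, size=n_flip, replace=False)
                scores[flip_idx] = -scores[flip_idx]
            else:  # inflated spread
                scores = scores + rng.normal(0.0, _SPREAD_CORRUPTION_SD, n_rep)
        should_pass[((d1, d2) if d1 < d2 else (d2, d1), ccl)] = not corrupt
        for r, score in enumerate(scores):
            swap = bool(rng.random() < 0.5)  # randomize reporting order of the drugs
            a, b = (d2, d1) if swap else (d1, d2)
            ra, rb = (ri2, ri1) if swap else (ri1, ri2)
            records.append(
                SynergyRecord(
                    drug1_id=a,
                    drug2_id=b,
                    ccl_id=ccl,
                    score_type=score_type,
                    score=float(score),
                    ri1=float(ra + rng.normal(0.0, cfg.noise_sd)),
                    ri2=float(rb + rng.normal(0.0, cfg.noise_sd)),
                    replicate_id=f"rep{r}",
                )
            )
    return records, should_pass


def make_model_ready(
    world: SyntheticWorld,
    measurements: Sequence[SynergyRecord],
    filter_cfg: FilterConfig | None = None,
    score_type: str = "ZIP",
) -> tuple[list[TripleSample], np.ndarray, dict]:
    """Run the full pipeline end-to-end on synthetic inputs.

    filter genes -> z-score -> replicate consensus -> assemble -> augment.
    Returns (augmented samples, ground-truth synergy per sample, report).
    Ground truth is identical for a sample and its mirror.
    """
    filter_cfg = filter_cfg or FilterConfig()
    expr = zscore_genes(filter_genes(world.expression, filter_cfg), ddof=filter_cfg.ddof)
    consensus, filt_report = filter_synergy_replicates(measurements, filter_cfg)
    samples, asm_report = assemble_dataset(expr, world.signatures, consensus, score_type)
    augmented = augment_order_swap(samples)
    truth = np.array(
        [world.true_synergy(s.pair_key[0], s.pair_key[1], s.ccl_id) for s in augmented]
    )
    report = {"filtering": filt_report.as_dict(), "assembly": asm_report.as_dict()}
    report["filtering"].pop("dropped_groups", None)
    return augmented, truth, report


def write_world_files(
    world: SyntheticWorld,
    measurements: Sequence[SynergyRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the three raw input files plus a ground-truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "signatures": out / "signatures.tsv",
        "synergy": out / "synergy.tsv",
        "ground_truth": out / "ground_truth.tsv",
    }
    write_expression_matrix(world.expression, paths["expression"])
    write_signature_table(world.signatures, paths["signatures"])
    write_synergy_table(measurements, paths["synergy"])
    rows = [
        {"drug1": d1, "drug2": d2, "ccl": c, "true_synergy": world.true_synergy(d1, d2, c)}
        for d1, d2, c in world.all_triples()
    ]
    pd.DataFrame(rows).to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
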
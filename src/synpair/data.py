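"""Domain containers and the preprocessing pipeline for drug-pair synergy data.

The pipeline turns three raw inputs -- a baseline gene-expression matrix of
cancer cell lines (CCLs), per-drug transcriptomic signatures over a small set
of reference cell lines, and a long table of replicate synergy measurements --
into model-ready triple samples:

1.  gene filtering (low expression, then low variance),
2.  per-gene z-score normalization over all CCLs,
3.  consensus of replicate drug signatures (mean) and per-drug feature
    concatenation across the configured signature cell lines,
4.  replicate-consistency filtering of synergy measurements (sign-majority
    and standard-deviation gates) with median consensus,
5.  three-way intersection into :class:`TripleSample` records, and
6.  order-swap augmentation so that each unordered drug pair is presented to
    a downstream model in both orders with per-drug targets swapped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ParseError",
    "FilterConfig",
    "ExpressionMatrix",
    "DrugSignatureSet",
    "SynergyRecord",
    "TripleSample",
    "FilterReport",
    "AssemblyReport",
    "pair_key",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_signature_table",
    "write_signature_table",
    "read_synergy_table",
    "write_synergy_table",
    "filter_genes",
    "zscore_genes",
    "consensus_signature",
    "build_drug_feature",
    "filter_synergy_replicates",
    "assemble_dataset",
    "augment_order_swap",
    "sparsity_report",
    "samples_to_arrays",
    "write_dataset_bundle",
    "read_dataset_bundle",
]


class ValidationError(ValueError):
    """Input violates a documented invariant (duplicates, NaNs, bad config)."""


class ParseError(ValueError):
    """A file could not be parsed into the expected tabular layout."""


def pair_key(drug1_id: str, drug2_id: str) -> tuple[str, str]:
    """Canonical unordered key for a drug pair (lexicographically sorted)."""
    if drug1_id == drug2_id:
        raise ValidationError(f"a drug pair needs two distinct drugs, got {drug1_id!r} twice")
    return (drug1_id, drug2_id) if drug1_id < drug2_id else (drug2_id, drug1_id)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the preprocessing filters.

    Parameters
    ----------
    low_expr_threshold
        Expression level (log2(RPKM+1) units) below which a value counts as
        "lowly expressed".
    low_expr_frac
        A gene is removed when *strictly more than* this fraction of CCLs is
        below ``low_expr_threshold``.
    min_variance
        A gene is removed when its variance across CCLs is *strictly smaller*
        than this value.
    sign_consensus_frac
        Minimum fraction of replicates sharing the majority synergy-score
        sign for a measurement group to be kept. Zero scores count toward
        the non-negative class.
    max_replicate_std
        Maximum allowed standard deviation of the synergy score across
        replicates. Singleton groups are assigned a standard deviation of 0.
    ddof
        Delta degrees of freedom for every variance / standard deviation in
        the pipeline (1 = sample convention, 0 = population).
    """

    low_expr_threshold: float = 1.0
    low_expr_frac: float = 0.75
    min_variance: float = 0.8
    sign_consensus_frac: float = 0.6
    max_replicate_std: float = 0.1
    ddof: int = 1

    def __post_init__(self) -> None:
        for name in ("low_expr_frac", "sign_consensus_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        for name in ("low_expr_threshold", "min_variance", "max_replicate_std"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.ddof not in (0, 1):
            raise ValidationError("ddof must be 0 or 1")


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene x CCL expression grid with identifiers.

    ``frame`` holds genes as rows and cell lines as columns; values are
    log2(RPKM+1) before normalization and z-score units afterwards.
    """

    frame: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        idx, cols = self.frame.index, self.frame.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate CCL identifiers: {dupes[:5]}")
        values = self.frame.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix must be numeric")
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return self.frame.index.tolist()

    @property
    def ccl_ids(self) -> list[str]:
        return self.frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    @property
    def n_ccls(self) -> int:
        return self.frame.shape[1]

    def ccl_vector(self, ccl_id: str) -> np.ndarray:
        if ccl_id not in self.frame.columns:
            raise KeyError(f"CCL {ccl_id!r} absent from expression matrix")
        return self.frame[ccl_id].to_numpy(dtype=float)


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("tsv", "csv"):
            raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
        return "\t" if dialect == "tsv" else ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a genes x CCLs matrix (identifiers in the first row and column)."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: no data columns found")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ParseError(f"{path}: malformed numeric value at gene {gene!r}, CCL {col!r}")
    if numeric.isna().to_numpy().any():
        raise ValidationError(f"{path}: missing values are not supported")
    return ExpressionMatrix(numeric.astype(float), normalized=False)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    m.frame.to_csv(path, sep=_sep_for(path, dialect))


def filter_genes(m: ExpressionMatrix, cfg: FilterConfig | None = None) -> ExpressionMatrix:
    """Drop lowly expressed genes, then low-variance genes among the survivors.

    A gene is removed when strictly more than ``low_expr_frac`` of CCLs fall
    below ``low_expr_threshold``, and (among the remaining genes) when its
    across-CCL variance is strictly below ``min_variance``. Gene and CCL
    order is preserved; the operation is idempotent.
    """
    cfg = cfg or FilterConfig()
    if m.normalized:
        raise ValidationError("filter_genes expects an unnormalized matrix")
    if m.n_ccls < 2:
        raise ValidationError("gene variance is undefined with fewer than 2 CCLs")
    values = m.values
    frac_low = (values < cfg.low_expr_threshold).mean(axis=1)
    keep_expr = frac_low <= cfg.low_expr_frac
    survivors = m.frame.loc[keep_expr]
    var = survivors.to_numpy(dtype=float).var(axis=1, ddof=cfg.ddof)
    keep_var = var >= cfg.min_variance
    return ExpressionMatrix(survivors.loc[keep_var].copy(), normalized=False)


def zscore_genes(m: ExpressionMatrix, ddof: int = 1) -> ExpressionMatrix:
    """Z-score each gene over all CCLs (one gene at a time)."""
    if m.normalized:
        raise ValidationError("matrix is already normalized")
    if m.n_ccls < 2:
        raise ValidationError("z-scoring needs at least 2 CCLs")
    values = m.values
    std = values.std(axis=1, ddof=ddof)
    if (std == 0).any():
        offending = [g for g, s in zip(m.gene_ids, std) if s == 0][:5]
        raise ValidationError(
            f"zero-variance genes {offending}; run filter_genes before z-scoring"
        )
    z = (values - values.mean(axis=1, keepdims=True)) / std[:, None]
    frame = pd.DataFrame(z, index=m.frame.index, columns=m.frame.columns)
    return ExpressionMatrix(frame, normalized=True)


# ---------------------------------------------------------------------------
# drug signatures
# ---------------------------------------------------------------------------


def consensus_signature(replicates: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of replicate signature vectors."""
    if len(replicates) == 0:
        raise ValidationError("cannot build a consensus from zero replicates")
    arrays = [np.asarray(r, dtype=float) for r in replicates]
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1:
        raise ValidationError(f"replicate length mismatch: {sorted(lengths)}")
    return np.mean(arrays, axis=0)


@dataclass
class DrugSignatureSet:
    """Per-drug landmark-gene signatures keyed by (drug, signature CCL, replicate).

    ``signature_ccl_order`` fixes the concatenation order of per-cell-line
    consensus signatures when a drug feature vector is assembled; with two
    signature cell lines and 978 landmark genes the per-drug feature has
    length 1956 and a drug pair 3912.
    """

    entries: dict[tuple[str, str, str], np.ndarray]
    landmark_dim: int
    signature_ccl_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.landmark_dim <= 0:
            raise ValidationError("landmark_dim must be positive")
        order = tuple(self.signature_ccl_order)
        if not order or len(set(order)) != len(order):
            raise ValidationError("signature_ccl_order must be non-empty and duplicate-free")
        object.__setattr__(self, "signature_ccl_order", order)
        for key, vec in self.entries.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (self.landmark_dim,):
                raise ValidationError(
                    f"signature {key} has length {vec.shape}, expected ({self.landmark_dim},)"
                )
            self.entries[key] = vec

    @property
    def drug_feature_dim(self) -> int:
        return self.landmark_dim * len(self.signature_ccl_order)

    def drugs(self) -> list[str]:
        return sorted({d for d, _, _ in self.entries})

    def replicates(self, drug_id: str, sig_ccl: str) -> list[np.ndarray]:
        return [v for (d, c, _), v in sorted(self.entries.items()) if d == drug_id and c == sig_ccl]

    def consensus(self, drug_id: str, sig_ccl: str) -> np.ndarray:
        reps = self.replicates(drug_id, sig_ccl)
        if not reps:
            raise KeyError(f"no signature for drug {drug_id!r} in cell line {sig_ccl!r}")
        return consensus_signature(reps)

    def drug_feature(self, drug_id: str) -> np.ndarray:
        parts = [self.consensus(drug_id, ccl) for ccl in self.signature_ccl_order]
        return np.concatenate(parts)


def build_drug_feature(sigs: DrugSignatureSet, drug_id: str) -> np.ndarray:
    """Concatenate the drug's consensus signatures in ``signature_ccl_order``."""
    return sigs.drug_feature(drug_id)


def read_signature_table(path: str | Path, dialect: str | None = None) -> DrugSignatureSet:
    """Read a long signature table: drug_id, signature_ccl, replicate_id, v0..v{d-1}."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect))
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    required = ["drug_id", "signature_ccl", "replicate_id"]
    if df.columns.tolist()[:3] != required:
        raise ParseError(f"{path}: first columns must be {required}")
    value_cols = df.columns[3:]
    if len(value_cols) == 0:
        raise ParseError(f"{path}: no signature value columns")
    entries: dict[tuple[str, str, str], np.ndarray] = {}
    sig_ccls: list[str] = []
    for _, row in df.iterrows():
        key = (str(row["drug_id"]), str(row["signature_ccl"]), str(row["replicate_id"]))
        if key in entries:
            raise ValidationError(f"{path}: duplicate signature row {key}")
        if key[1] not in sig_ccls:
            sig_ccls.append(key[1])
        entries[key] = row[value_cols].to_numpy(dtype=float)
    return DrugSignatureSet(entries, landmark_dim=len(value_cols), signature_ccl_order=tuple(sorted(sig_ccls)))


def write_signature_table(sigs: DrugSignatureSet, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    rows = []
    for (drug, ccl, rep), vec in sorted(sigs.entries.items()):
        rows.append([drug, ccl, rep, *vec.tolist()])
    cols = ["drug_id", "signature_ccl", "replicate_id"] + [f"v{i}" for i in range(sigs.landmark_dim)]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=_sep_for(path, dialect), index=False)


# ---------------------------------------------------------------------------
# synergy records and replicate filtering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynergyRecord:
    """One replicate measurement of a (drug1, drug2, CCL) triple."""

    drug1_id: str
    drug2_id: str
    ccl_id: str
    score_type: str
    score: float
    ri1: float
    ri2: float
    replicate_id: str

    def __post_init__(self) -> None:
        if self.drug1_id == self.drug2_id:
            raise ValidationError(f"drug pair needs distinct drugs, got {self.drug1_id!r} twice")
        for name in ("score", "ri1", "ri2"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    @property
    def pair_key(self) -> tuple[str, str]:
        return pair_key(self.drug1_id, self.drug2_id)

    def canonical(self) -> "SynergyRecord":
        """Orient the record so that drug1 < drug2, swapping the RI values."""
        if self.drug1_id < self.drug2_id:
            return self
        return replace(self, drug1_id=self.drug2_id, drug2_id=self.drug1_id, ri1=self.ri2, ri2=self.ri1)


_SYNERGY_COLS = ["drug1", "drug2", "ccl", "score_type", "score", "ri1", "ri2", "replicate_id"]


def read_synergy_table(path: str | Path, dialect: str | None = None) -> list[SynergyRecord]:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect))
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    missing = [c for c in _SYNERGY_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            SynergyRecord(
                drug1_id=str(row["drug1"]),
                drug2_id=str(row["drug2"]),
                ccl_id=str(row["ccl"]),
                score_type=str(row["score_type"]),
                score=float(row["score"]),
                ri1=float(row["ri1"]),
                ri2=float(row["ri2"]),
                replicate_id=str(row["replicate_id"]),
            )
        )
    return records


def write_synergy_table(records: Iterable[SynergyRecord], path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    rows = [
        [r.drug1_id, r.drug2_id, r.ccl_id, r.score_type, r.score, r.ri1, r.ri2, r.replicate_id]
        for r in records
    ]
    pd.DataFrame(rows, columns=_SYNERGY_COLS).to_csv(path, sep=_sep_for(path, dialect), index=False)


@dataclass
class FilterReport:
    """Counts and per-group reasons from replicate-consistency filtering."""

    kept: int = 0
    dropped_sign: int = 0
    dropped_std: int = 0
    details: list[tuple[tuple[str, str], str, str, str]] = field(default_factory=list)

    @property
    def dropped(self) -> int:
        return self.dropped_sign + self.dropped_std

    def as_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped_sign": self.dropped_sign,
            "dropped_std": self.dropped_std,
            "dropped_groups": [
                {"pair": list(pk), "ccl": ccl, "score_type": st, "reason": reason}
                for pk, ccl, st, reason in self.details
            ],
        }


def _group_std(scores: np.ndarray, ddof: int) -> float:
    # singleton measurements carry no inconsistency evidence
    if scores.size == 1:
        return 0.0
    return float(scores.std(ddof=ddof))


def filter_synergy_replicates(
    records: Iterable[SynergyRecord], cfg: FilterConfig | None = None
) -> tuple[list[SynergyRecord], FilterReport]:
    """Collapse replicate measurements into consensus records.

    Groups records by (unordered drug pair, CCL, score type). A group
    survives iff (a) the majority sign -- zeros counting as non-negative --
    covers at least ``sign_consensus_frac`` of replicates, and (b) the
    replicate standard deviation does not exceed ``max_replicate_std``.
    Surviving groups emit a single record whose score and RI values are the
    replicate medians.
    """
    cfg = cfg or FilterConfig()
    groups: dict[tuple[tuple[str, str], str, str], list[SynergyRecord]] = {}
    for rec in records:
        canon = rec.canonical()
        groups.setdefault((canon.pair_key, canon.ccl_id, canon.score_type), []).append(canon)

    consensus: list[SynergyRecord] = []
    report = FilterReport()
    for (pk, ccl, score_type), members in sorted(groups.items()):
        scores = np.array([m.score for m in members], dtype=float)
        n = scores.size
        nonneg = int((scores >= 0).sum())
        majority_frac = max(nonneg, n - nonneg) / n
        if majority_frac < cfg.sign_consensus_frac:
            report.dropped_sign += 1
            report.details.append((pk, ccl, score_type, "sign_consensus"))
            continue
        if _group_std(scores, cfg.ddof) > cfg.max_replicate_std:
            report.dropped_std += 1
            report.details.append((pk, ccl, score_type, "replicate_std"))
            continue
        report.kept += 1
        consensus.append(
            SynergyRecord(
                drug1_id=pk[0],
                drug2_id=pk[1],
                ccl_id=ccl,
                score_type=score_type,
                score=float(np.median(scores)),
                ri1=float(np.median([m.ri1 for m in members])),
                ri2=float(np.median([m.ri2 for m in members])),
                replicate_id="consensus",
            )
        )
    return consensus, report


# ---------------------------------------------------------------------------
# triple samples
# ---------------------------------------------------------------------------


@dataclass
class TripleSample:
    """One model-ready sample for a (drug, drug, CCL) triple.

    ``x_pair`` concatenates the two per-drug feature vectors in
    ``ordered_drugs`` order; ``x_triple`` appends the CCL feature vector.
    ``y`` holds (synergy, RI_first, RI_second).
    """

    pair_key: tuple[str, str]
    ccl_id: str
    ordered_drugs: tuple[str, str]
    x_pair: np.ndarray
    x_triple: np.ndarray
    y: np.ndarray
    is_swap: bool = False

    def __post_init__(self) -> None:
        self.x_pair = np.asarray(self.x_pair, dtype=float)
        self.x_triple = np.asarray(self.x_triple, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x_pair.ndim != 1 or self.x_triple.ndim != 1:
            raise ValidationError("feature vectors must be one-dimensional")
        if self.x_pair.size % 2 != 0:
            raise ValidationError("x_pair must hold two equal-length drug blocks")
        if self.x_triple.size < self.x_pair.size:
            raise ValidationError("x_triple must extend x_pair with the CCL block")
        if not np.isfinite(self.y).all():
            raise ValidationError("targets must be finite")
        if set(self.ordered_drugs) != set(self.pair_key):
            raise ValidationError("ordered_drugs must contain the drugs of pair_key")

    @property
    def drug_dim(self) -> int:
        return self.x_pair.size // 2

    @property
    def ccl_dim(self) -> int:
        return self.x_triple.size - self.x_pair.size


@dataclass
class AssemblyReport:
    """Three-way intersection diagnostics from :func:`assemble_dataset`."""

    kept: int = 0
    missing_drug_feature: int = 0
    missing_ccl: int = 0
    wrong_score_type: int = 0

    def as_dict(self) -> dict:
        return {
            "kept": self.kept,
            "missing_drug_feature": self.missing_drug_feature,
            "missing_ccl": self.missing_ccl,
            "wrong_score_type": self.wrong_score_type,
        }


def assemble_dataset(
    expr: ExpressionMatrix,
    sigs: DrugSignatureSet,
    consensus: Sequence[SynergyRecord],
    score_type: str = "ZIP",
) -> tuple[list[TripleSample], AssemblyReport]:
    """Build one TripleSample per consensus record present in all three sources."""
    if not expr.normalized:
        raise ValidationError("expression matrix must be z-scored before assembly")
    report = AssemblyReport()
    feature_cache: dict[str, np.ndarray | None] = {}

    def drug_feat(drug: str) -> np.ndarray | None:
        if drug not in feature_cache:
            try:
                feature_cache[drug] = sigs.drug_feature(drug)
            except KeyError:
                feature_cache[drug] = None
        return feature_cache[drug]

    samples: list[TripleSample] = []
    for rec in consensus:
        if rec.score_type != score_type:
            report.wrong_score_type += 1
            continue
        rec = rec.canonical()
        f1, f2 = drug_feat(rec.drug1_id), drug_feat(rec.drug2_id)
        if f1 is None or f2 is None:
            report.missing_drug_feature += 1
            continue
        if rec.ccl_id not in expr.frame.columns:
            report.missing_ccl += 1
            continue
        x_pair = np.concatenate([f1, f2])
        x_triple = np.concatenate([x_pair, expr.ccl_vector(rec.ccl_id)])
        samples.append(
            TripleSample(
                pair_key=rec.pair_key,
                ccl_id=rec.ccl_id,
                ordered_drugs=(rec.drug1_id, rec.drug2_id),
                x_pair=x_pair,
                x_triple=x_triple,
                y=np.array([rec.score, rec.ri1, rec.ri2], dtype=float),
            )
        )
        report.kept += 1
    if not samples:
        raise ValidationError(f"empty three-way intersection: {report.as_dict()}")
    return samples, report


def mirror_sample(sample: TripleSample) -> TripleSample:
    """The order-swapped twin of a sample (drug blocks and per-drug RIs swapped)."""
    m = sample.drug_dim
    u, v = sample.x_pair[:m], sample.x_pair[m:]
    x_pair = np.concatenate([v, u])
    x_triple = np.concatenate([x_pair, sample.x_triple[2 * m:]])
    return TripleSample(
        pair_key=sample.pair_key,
        ccl_id=sample.ccl_id,
        ordered_drugs=(sample.ordered_drugs[1], sample.ordered_drugs[0]),
        x_pair=x_pair,
        x_triple=x_triple,
        y=np.array([sample.y[0], sample.y[2], sample.y[1]], dtype=float),
        is_swap=not sample.is_swap,
    )


def augment_order_swap(samples: Sequence[TripleSample]) -> list[TripleSample]:
    """Double the dataset by adding the order-swapped mirror of every sample."""
    if any(s.is_swap for s in samples):
        raise ValidationError("input already contains order-swap mirrors")
    out: list[TripleSample] = []
    for s in samples:
        out.append(s)
        out.append(mirror_sample(s))
    return out


def sparsity_report(samples: Sequence[TripleSample] | int, n_drugs: int, n_ccls: int) -> float:
    """Percentage of the ordered-pair x CCL universe covered by measured triples.

    Returns ``100 * n_triples / (n_drugs * (n_drugs - 1) * n_ccls)`` where
    ``n_triples`` counts unique unaugmented (pair, CCL) triples.
    """
    if n_drugs < 2:
        raise ValidationError("need at least two drugs")
    if n_ccls < 1:
        raise ValidationError("need at least one CCL")
    if isinstance(samples, (int, np.integer)):
        n_triples = int(samples)
    else:
        n_triples = len({(s.pair_key, s.ccl_id) for s in samples if not s.is_swap})
    return 100.0 * n_triples / (n_drugs * (n_drugs - 1) * n_ccls)


# ---------------------------------------------------------------------------
# array conversion and on-disk bundle
# ---------------------------------------------------------------------------


def samples_to_arrays(
    samples: Sequence[TripleSample],
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Stack samples into (X, Y, meta). X rows are ``x_triple`` vectors."""
    if not samples:
        raise ValidationError("no samples to convert")
    X = np.stack([s.x_triple for s in samples])
    Y = np.stack([s.y for s in samples])
    meta = pd.DataFrame(
        {
            "pair_key": ["|".join(s.pair_key) for s in samples],
            "ccl_id": [s.ccl_id for s in samples],
            "drug_first": [s.ordered_drugs[0] for s in samples],
            "drug_second": [s.ordered_drugs[1] for s in samples],
            "is_swap": [s.is_swap for s in samples],
        }
    )
    return X, Y, meta


def write_dataset_bundle(
    out_dir: str | Path,
    samples: Sequence[TripleSample],
    drug_features: Mapping[str, np.ndarray] | None = None,
    ccl_features: Mapping[str, np.ndarray] | None = None,
    report: Mapping | None = None,
) -> None:
    """Write a processed dataset directory (manifest TSV + feature arrays)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X, Y, meta = samples_to_arrays(samples)
    manifest = meta.copy()
    manifest.insert(0, "sample_id", np.arange(len(samples)))
    manifest["y_synergy"] = Y[:, 0]
    if Y.shape[1] > 2:
        manifest["y_ri_first"] = Y[:, 1]
        manifest["y_ri_second"] = Y[:, 2]
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    np.savez(out / "features.npz", X=X, Y=Y, drug_dim=np.array(samples[0].drug_dim))
    if drug_features is not None:
        pd.DataFrame({d: v for d, v in sorted(drug_features.items())}).T.to_csv(
            out / "drug_features.tsv", sep="\t", header=False
        )
    if ccl_features is not None:
        pd.DataFrame({c: v for c, v in sorted(ccl_features.items())}).T.to_csv(
            out / "ccl_features.tsv", sep="\t", header=False
        )
    if report is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def read_dataset_bundle(in_dir: str | Path) -> list[TripleSample]:
    """Reconstruct TripleSamples from a bundle written by write_dataset_bundle."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.tsv", sep="\t")
    arrays = np.load(in_dir / "features.npz")
    X, Y, drug_dim = arrays["X"], arrays["Y"], int(arrays["drug_dim"])
    samples = []
    for i, row in manifest.iterrows():
        pk = tuple(str(row["pair_key"]).split("|"))
        samples.append(
            TripleSample(
                pair_key=(pk[0], pk[1]),
                ccl_id=str(row["ccl_id"]),
                ordered_drugs=(str(row["drug_first"]), str(row["drug_second"])),
                x_pair=X[i, : 2 * drug_dim],
                x_triple=X[i],
                y=Y[i],
                is_swap=bool(row["is_swap"]),
            )
        )
    return samples


def read_feature_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read an id -> vector table (id in the first column, no header)."""
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return {str(idx): row.to_numpy(dtype=float) for idx, row in df.iterrows()}
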
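"""Downstream synergy screening over imputed (drug pair, CCL) triples.

Given a trained order-symmetrized predictor, this module enumerates triples
absent from the measured screen, imputes their synergy scores, and supports
two screening questions: which pairs are synergistic across every cell line
(pan-CCL screen), and which pairs are synergistic specifically within one
tissue (ranked by mean difference, with a one-sided Mann-Whitney U test and
Benjamini-Hochberg FDR control across the ranked family).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import TripleSample, ValidationError, pair_key
from .model import predict_synergy_symmetric

__all__ = [
    "PredictionTable",
    "select_frequent_drugs",
    "enumerate_novel_triples",
    "impute",
    "screen_pan_ccl",
    "rank_tissue_specific",
    "subtype_contrast",
    "mann_whitney_one_sided",
    "benjamini_hochberg",
]


@dataclass
class PredictionTable:
    """Predicted synergy per unordered (drug pair, CCL) triple.

    ``frame`` columns: drug1, drug2 (canonical order), ccl, score,
    provenance ("measured" or "imputed"). ``tissue_map`` maps CCL id to a
    tissue label for tissue-specific analyses.
    """

    frame: pd.DataFrame
    tissue_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        required = ["drug1", "drug2", "ccl", "score", "provenance"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValidationError(f"prediction table missing columns {missing}")
        if (self.frame["drug1"] >= self.frame["drug2"]).any():
            raise ValidationError("rows must use the canonical drug order (drug1 < drug2)")
        keys = self.frame[["drug1", "drug2", "ccl"]]
        if keys.duplicated().any():
            raise ValidationError("duplicate (pair, CCL) rows in prediction table")
        if not np.isfinite(self.frame["score"].to_numpy(dtype=float)).all():
            raise ValidationError("predicted scores must be finite")


def select_frequent_drugs(
    samples: Sequence[TripleSample], min_pair_frac: float = 0.10
) -> list[str]:
    """Drugs appearing in at least ``min_pair_frac`` of the distinct drug pairs."""
    if not samples:
        raise ValidationError("no samples")
    pairs = {s.pair_key for s in samples}
    counts: dict[str, int] = {}
    for a, b in pairs:
        counts[a] = counts.get(a, 0) + 1
        counts[b] = counts.get(b, 0) + 1
    threshold = min_pair_frac * len(pairs)
    return sorted(d for d, c in counts.items() if c >= threshold)


def enumerate_novel_triples(
    drugs: Sequence[str],
    ccls: Sequence[str],
    measured: set[tuple[str, str, str]] | None = None,
) -> list[tuple[str, str, str]]:
    """All unordered drug pairs x CCLs, minus measured triples, in lexicographic order.

    ``measured`` entries are (drug1, drug2, ccl) with the pair in canonical
    (sorted) order.
    """
    drugs = list(drugs)
    if len(set(drugs)) != len(drugs):
        raise ValidationError("drug list contains duplicates")
    if len(drugs) < 2:
        raise ValidationError("need at least two drugs")
    measured = measured or set()
    out = []
    for d1, d2 in itertools.combinations(sorted(drugs), 2):
        for ccl in sorted(set(ccls)):
            if (d1, d2, ccl) not in measured:
                out.append((d1, d2, ccl))
    return out


def impute(
    model,
    triples: Sequence[tuple[str, str, str]],
    drug_features: Mapping[str, np.ndarray],
    ccl_features: Mapping[str, np.ndarray],
    tissue_map: dict[str, str] | None = None,
    batch_size: int = 2048,
) -> tuple[PredictionTable, list[tuple[str, str, str]]]:
    """Predict synergy for each triple with order-symmetrized inference.

    Triples with a missing drug or CCL feature are skipped and returned in
    the second element.
    """
    rows, skipped = [], []
    feats, keys = [], []
    for d1, d2, ccl in triples:
        d1, d2 = pair_key(d1, d2)
        if d1 not in drug_features or d2 not in drug_features or ccl not in ccl_features:
            skipped.append((d1, d2, ccl))
            continue
        feats.append(
            np.concatenate([drug_features[d1], drug_features[d2], ccl_features[ccl]])
        )
        keys.append((d1, d2, ccl))
    if feats:
        X = np.stack(feats)
        drug_dim = len(next(iter(drug_features.values())))
        scores = np.empty(len(X))
        for start in range(0, len(X), batch_size):
            scores[start : start + batch_size] = predict_synergy_symmetric(
                model, X[start : start + batch_size], drug_dim=drug_dim
            )
        for (d1, d2, ccl), s in zip(keys, scores):
            rows.append({"drug1": d1, "drug2": d2, "ccl": ccl, "score": float(s), "provenance": "imputed"})
    frame = pd.DataFrame(rows, columns=["drug1", "drug2", "ccl", "score", "provenance"])
    return PredictionTable(frame, tissue_map=tissue_map), skipped


def screen_pan_ccl(
    table: PredictionTable, min_score: float = 2.0, ccls: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairs whose minimum predicted score across all CCLs is strictly above ``min_score``.

    Pairs lacking full CCL coverage are excluded with a warning. Returns a
    frame (drug1, drug2, min_score, mean_score) sorted by mean descending.
    """
    frame = table.frame
    universe = set(ccls) if ccls is not None else set(frame["ccl"].unique())
    rows = []
    for (d1, d2), grp in frame.groupby(["drug1", "drug2"], sort=True):
        covered = set(grp["ccl"])
        if covered != universe:
            warnings.warn(
                f"pair ({d1}, {d2}) covers {len(covered)}/{len(universe)} CCLs; excluded",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        scores = grp["score"].to_numpy(dtype=float)
        if scores.min() > min_score:
            rows.append(
                {"drug1": d1, "drug2": d2, "min_score": float(scores.min()), "mean_score": float(scores.mean())}
            )
    out = pd.DataFrame(rows, columns=["drug1", "drug2", "min_score", "mean_score"])
    return out.sort_values("mean_score", ascending=False).reset_index(drop=True)


def mann_whitney_one_sided(within: np.ndarray, outside: np.ndarray) -> tuple[float, float]:
    """One-sided Mann-Whitney U (alternative: ``within`` stochastically greater).

    Uses the exact null distribution when both groups have at most 8
    observations and no ties span the groups; otherwise the normal
    approximation with continuity and tie correction.
    """
    within = np.asarray(within, dtype=float)
    outside = np.asarray(outside, dtype=float)
    if within.size == 0 or outside.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([within, outside])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (within.size <= 8 and outside.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(within, outside, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_tissue_specific(table: PredictionTable, tissue: str) -> pd.DataFrame:
    """Rank pairs synergistic specifically within ``tissue``.

    Pairs whose minimum score within the tissue is strictly positive are
    retained, then ranked by (mean within - mean outside) descending. Each
    retained pair gets a one-sided Mann-Whitney p-value (within greater)
    and a BH-adjusted FDR across the retained family.
    """
    if table.tissue_map is None:
        raise ValidationError("prediction table carries no tissue map")
    in_ccls = {c for c, t in table.tissue_map.items() if t == tissue}
    out_ccls = {c for c, t in table.tissue_map.items() if t != tissue}
    if not in_ccls:
        raise ValidationError(f"tissue {tissue!r} absent from tissue map")
    if not out_ccls:
        raise ValidationError("no CCLs outside the queried tissue")
    rows = []
    for (d1, d2), grp in table.frame.groupby(["drug1", "drug2"], sort=True):
        within = grp.loc[grp["ccl"].isin(in_ccls), "score"].to_numpy(dtype=float)
        outside = grp.loc[grp["ccl"].isin(out_ccls), "score"].to_numpy(dtype=float)
        if within.size == 0 or outside.size == 0:
            continue
        if within.min() <= 0:  # must not be antagonistic in any tissue CCL
            continue
        u, p = mann_whitney_one_sided(within, outside)
        rows.append(
            {
                "drug1": d1,
                "drug2": d2,
                "mean_within": float(within.mean()),
                "mean_outside": float(outside.mean()),
                "difference": float(within.mean() - outside.mean()),
                "min_within": float(within.min()),
                "u_statistic": u,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "drug1",
            "drug2",
            "mean_within",
            "mean_outside",
            "difference",
            "min_within",
            "u_statistic",
            "p_value",
        ],
    )
    if out.empty:
        warnings.warn("no pairs pass the within-tissue minimum filter", RuntimeWarning, stacklevel=2)
        out["fdr"] = pd.Series(dtype=float)
        return out
    out["fdr"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out.sort_values("difference", ascending=False).reset_index(drop=True)


def subtype_contrast(
    table: PredictionTable,
    subtype_map: Mapping[str, str],
    pair: tuple[str, str],
    subtype: str,
) -> float:
    """Mean score in the subtype's CCLs minus the mean in the other mapped CCLs."""
    d1, d2 = pair_key(*pair)
    grp = table.frame[(table.frame["drug1"] == d1) & (table.frame["drug2"] == d2)]
    in_ccls = [c for c, s in subtype_map.items() if s == subtype]
    out_ccls = [c for c, s in subtype_map.items() if s != subtype]
    within = grp.loc[grp["ccl"].isin(in_ccls), "score"].to_numpy(dtype=float)
    others = grp.loc[grp["ccl"].isin(out_ccls), "score"].to_numpy(dtype=float)
    if within.size == 0 or others.size == 0:
        raise ValidationError("both subtype groups must be non-empty for the contrast")
    return float(within.mean() - others.mean())
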
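"""Per-label and aggregate evaluation: AUROC, AUPRC, recall@k, coverage
error, the de-novo first-occurrence protocol, paired model comparisons and
chapter-level summaries with false-discovery-rate control.

AUROC is the Mann-Whitney concordance probability (ties half credit);
AUPRC is the average-precision summation without interpolation. The two
ranking metrics treat each encounter's score vector as a ranked label list,
with ties broken by lexicographic label order for cross-platform
determinism. De-novo evaluation restricts each (patient, label) pair to
encounters up to and including the label's first occurrence, so repeat
occurrences — which are easy to predict — are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "auroc",
    "auprc",
    "recall_at_k",
    "coverage_error",
    "denovo_mask",
    "per_label_metrics",
    "compare_models",
    "chapter_summary",
    "brier_score",
]


def auroc(scores: np.ndarray, truth: np.ndarray) -> float | None:
    """Probability that a random positive outranks a random negative
    (ties count one half). ``None`` when truth is single-class."""
    truth = np.asarray(truth).ravel()
    if truth.min() == truth.max():
        return None
    return float(roc_auc_score(truth, np.asarray(scores).ravel()))


def auprc(scores: np.ndarray, truth: np.ndarray) -> float | None:
    """Average precision (step-curve area, no interpolation); ``None`` with
    zero positives."""
    truth = np.asarray(truth).ravel()
    if truth.sum() == 0:
        return None
    return float(average_precision_score(truth, np.asarray(scores).ravel()))


def brier_score(scores: np.ndarray, truth: np.ndarray) -> float:
    s = np.asarray(scores, float).ravel()
    t = np.asarray(truth, float).ravel()
    return float(np.mean((s - t) ** 2))


def _rank_order(score_row: np.ndarray) -> np.ndarray:
    """Label indices from best to worst: descending score, ties broken by
    lexicographic (column) order."""
    L = len(score_row)
    return np.lexsort((np.arange(L), -score_row))


def recall_at_k(scores: np.ndarray, labels: np.ndarray | sp.spmatrix, k: int) -> float:
    """Mean over rows of |true labels among the k top-scored| / |true labels|.

    Rows without any true label are excluded (and logged). ``k`` greater
    than the label count is clamped with a warning.
    """
    Y = labels.toarray() if sp.issparse(labels) else np.asarray(labels)
    S = np.asarray(scores, float)
    n, L = S.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > L:
        logger.warning("k=%d exceeds label count %d; clamped", k, L)
        k = L
    vals = []
    skipped = 0
    for i in range(n):
        true = np.flatnonzero(Y[i] > 0)
        if len(true) == 0:
            skipped += 1
            continue
        top = _rank_order(S[i])[:k]
        vals.append(len(np.intersect1d(true, top, assume_unique=True)) / len(true))
    if skipped:
        logger.info("recall_at_k: %d rows without true labels excluded", skipped)
    return float(np.mean(vals))


def coverage_error(scores: np.ndarray, labels: np.ndarray | sp.spmatrix) -> float:
    """Mean over rows of the 1-based rank of the worst-ranked true label."""
    Y = labels.toarray() if sp.issparse(labels) else np.asarray(labels)
    S = np.asarray(scores, float)
    vals = []
    skipped = 0
    for i in range(S.shape[0]):
        true = set(np.flatnonzero(Y[i] > 0))
        if not true:
            skipped += 1
            continue
        order = _rank_order(S[i])
        worst = max(np.flatnonzero(np.isin(order, list(true)))) + 1
        vals.append(worst)
    if skipped:
        logger.info("coverage_error: %d rows without true labels excluded", skipped)
    return float(np.mean(vals))


def denovo_mask(
    encounters: pd.DataFrame,
    encounter_ids: list[str],
    labels: np.ndarray | sp.spmatrix,
    label_ids: list[str],
) -> np.ndarray:
    """Boolean eligibility matrix for de-novo evaluation.

    For each (patient, label): eligible encounters are those dated up to and
    including the patient's first positive encounter for that label
    (same-date ties with the first positive all eligible); patients never
    positive keep all encounters eligible.
    """
    Y = labels.toarray() if sp.issparse(labels) else np.asarray(labels)
    enc = encounters.set_index("encounter_id").loc[encounter_ids]
    pat = enc["patient_id"].to_numpy()
    day = pd.to_datetime(enc["date"]).to_numpy().astype("datetime64[D]").astype(np.int64)
    n, L = Y.shape
    mask = np.ones((n, L), dtype=bool)
    order = np.argsort(pat, kind="mergesort")
    for _, idx in pd.Series(np.arange(n)[order]).groupby(pat[order]):
        rows = idx.to_numpy()
        for l in range(L):
            pos = rows[Y[rows, l] > 0]
            if len(pos):
                first_day = day[pos].min()
                mask[rows[day[rows] > first_day], l] = False
    return mask


def per_label_metrics(
    scores: np.ndarray,
    labels: np.ndarray | sp.spmatrix,
    label_ids: list[str],
    mask: np.ndarray | None = None,
    mode: str = "overall",
) -> pd.DataFrame:
    """Per-label AUROC/AUPRC/prevalence table.

    With a de-novo ``mask``, each label is scored only on its eligible
    encounters. Undefined metrics are recorded as missing, never as zero.
    """
    Y = labels.toarray() if sp.issparse(labels) else np.asarray(labels)
    S = np.asarray(scores, float)
    rows = []
    for l, lid in enumerate(label_ids):
        sel = mask[:, l] if mask is not None else np.ones(len(Y), bool)
        y, s = Y[sel, l], S[sel, l]
        rows.append({
            "label": lid,
            "letter": lid[0],
            "mode": mode,
            "n_eval_encounters": int(sel.sum()),
            "prevalence": float(y.mean()) if len(y) else np.nan,
            "auroc": auroc(s, y) if len(y) else None,
            "auprc": auprc(s, y) if len(y) else None,
        })
    df = pd.DataFrame(rows)
    df["auroc"] = df["auroc"].astype(float)
    df["auprc"] = df["auprc"].astype(float)
    return df


def summarize(metrics: pd.DataFrame, column: str = "auroc") -> dict[str, float]:
    """Median and IQR of a per-label metric across labels (defined values only)."""
    v = metrics[column].dropna()
    return {
        "median": float(v.median()),
        "q25": float(v.quantile(0.25)),
        "q75": float(v.quantile(0.75)),
        "n_labels": int(v.size),
    }


def compare_models(
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on per-label metrics.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 pairs, otherwise the normal approximation with continuity
    correction. All-zero differences yield (0, 1).
    """
    a = np.asarray(metric_a, float)
    b = np.asarray(metric_b, float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors must have equal length")
    d = b - a
    d = d[~np.isnan(d)]
    nz = d[d != 0]
    if len(nz) == 0:
        return 0.0, 1.0
    method = "exact" if len(nz) <= 25 else "approx"
    res = stats.wilcoxon(nz, alternative=alternative, zero_method="wilcox",
                         correction=True, method=method)
    return float(res.statistic), float(res.pvalue)


def chapter_summary(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    metric: str = "auroc",
    alternative: str = "less",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Letter-prefix summary comparing two models label by label.

    Groups labels by their first letter; reports the label count, each
    model's mean metric, a per-letter paired Wilcoxon p-value (default
    alternative: model B greater, i.e. A "less"), and Benjamini-Hochberg
    adjusted p-values across letters with significance flags at the given
    false-discovery rate. Letters with fewer than two labels are reported
    without a test.
    """
    a = metrics_a.set_index("label")[metric]
    b = metrics_b.set_index("label")[metric]
    common = a.index.intersection(b.index)
    letters = sorted({l[0] for l in common})
    rows = []
    for letter in letters:
        labs = [l for l in common if l[0] == letter]
        va, vb = a.loc[labs].to_numpy(), b.loc[labs].to_numpy()
        ok = ~(np.isnan(va) | np.isnan(vb))
        row = {
            "letter": letter,
            "label_count": len(labs),
            f"{metric}_a": float(np.nanmean(va)) if ok.any() else np.nan,
            f"{metric}_b": float(np.nanmean(vb)) if ok.any() else np.nan,
        }
        if ok.sum() >= 2:
            _, row["p_value"] = compare_models(va[ok], vb[ok], alternative=alternative)
        else:
            row["p_value"] = np.nan
            logger.info("letter %s has < 2 comparable labels; test skipped", letter)
        rows.append(row)
    df = pd.DataFrame(rows)
    tested = df["p_value"].notna()
    df["p_adjusted"] = np.nan
    df["significant"] = False
    if tested.any():
        rej, padj, *_ = multipletests(df.loc[tested, "p_value"], alpha=fdr,
                                      method="fdr_bh")
        df.loc[tested, "p_adjusted"] = padj
        df.loc[tested, "significant"] = rej
    return df


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p_values, float), method="fdr_bh")[1]


def write_metrics_tsv(metrics: pd.DataFrame, path) -> None:
    """Serialize a metrics table with fixed formatting (byte-reproducible)."""
    metrics.to_csv(path, sep="\t", index=False, float_format="%.10g")
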
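"""Evaluation suite: confusion statistics, ROC/AUC over a threshold grid,
operating-point selection, GO enrichment around encoding-space neighbors,
per-class true-positive rates, interaction propensities, and PCA of
encoding vectors.

Scores (sn for residues, tn for protogroups) live in [0, 1]; a positive
call at threshold t means score >= t, evaluated on a 0.00..1.00 grid with
step 0.01.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence as TypingSequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = np.round(np.arange(0, 101) * 0.01, 2)


def _ratio(num: float, den: float) -> tuple[float, bool]:
    """num/den, with zero denominators reported as (0, flagged)."""
    if den == 0:
        return 0.0, True
    return num / den, False


@dataclass(frozen=True)
class ConfusionMetrics:
    """A 2x2 confusion matrix and its derived statistics.

    sensitivity (TPR) = TP/(TP+FN); specificity = TN/(TN+FP);
    precision = TP/(TP+FP); FPR = FP/(FP+TN); accuracy = (TP+TN)/total;
    F = harmonic mean of precision and sensitivity;
    PLR = sensitivity / FPR (positive likelihood ratio);
    chi2_neglog10p = -log10 of the 2x2 chi-square test P-value
    (Yates continuity correction by default).
    Ratios with a zero denominator are reported as 0 and flagged in
    ``undefined``.
    """

    TP: int
    FP: int
    FN: int
    TN: int
    threshold: float | None = None
    sensitivity: float = 0.0
    specificity: float = 0.0
    precision: float = 0.0
    FPR: float = 0.0
    accuracy: float = 0.0
    f_measure: float = 0.0
    PLR: float = 0.0
    chi2_neglog10p: float = 0.0
    undefined: frozenset[str] = frozenset()


def confusion_metrics(
    TP: int, FP: int, FN: int, TN: int,
    threshold: float | None = None,
    continuity_correction: bool = True,
) -> ConfusionMetrics:
    """Derived statistics for one confusion matrix.

    PLR is infinite when FPR = 0 with nonzero sensitivity; the chi-square
    P-value uses Yates correction unless disabled.
    """
    counts = (TP, FP, FN, TN)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("all-zero confusion matrix")
    undefined: set[str] = set()
    sen, bad = _ratio(TP, TP + FN)
    if bad:
        undefined.add("sensitivity")
    spe, bad = _ratio(TN, TN + FP)
    if bad:
        undefined.add("specificity")
    pre, bad = _ratio(TP, TP + FP)
    if bad:
        undefined.add("precision")
    fpr, bad = _ratio(FP, FP + TN)
    if bad:
        undefined.add("FPR")
    acc = (TP + TN) / total
    if pre + sen > 0:
        f_measure = 2 * pre * sen / (pre + sen)
    else:
        f_measure = 0.0
        undefined.add("f_measure")
    if fpr > 0:
        plr = sen / fpr
    elif sen > 0:
        plr = float("inf")
    else:
        plr = 0.0
        undefined.add("PLR")
    table = np.array([[TP, FN], [FP, TN]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        neglog10p = 0.0
        undefined.add("chi2_neglog10p")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = stats.chi2_contingency(table, correction=continuity_correction)
        pvalue = max(float(result.pvalue), 1e-300)
        neglog10p = -np.log10(pvalue)
    return ConfusionMetrics(
        TP=TP, FP=FP, FN=FN, TN=TN, threshold=threshold,
        sensitivity=sen, specificity=spe, precision=pre, FPR=fpr,
        accuracy=acc, f_measure=f_measure, PLR=plr,
        chi2_neglog10p=neglog10p, undefined=frozenset(undefined),
    )


def report_rounding(value: float, decimals: int = 3) -> float:
    """Half-up rounding used only when formatting report tables.

    Non-finite values (an infinite likelihood ratio at zero FPR) pass
    through unchanged.
    """
    from decimal import Decimal, ROUND_HALF_UP

    value = float(value)
    if not np.isfinite(value):
        return value
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RocCurve:
    """ROC points over the threshold grid plus trapezoidal AUC."""

    thresholds: np.ndarray
    points: np.ndarray  # (n, 2) columns FPR, TPR ordered by threshold
    auc: float
    matrices: tuple[ConfusionMetrics, ...] = ()


def threshold_confusions(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
    continuity_correction: bool = True,
) -> list[ConfusionMetrics]:
    """Confusion matrices over the grid (positive call: score >= threshold)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    out = []
    for t in thresholds:
        called = scores >= t
        out.append(
            confusion_metrics(
                TP=int((called & labels).sum()),
                FP=int((called & ~labels).sum()),
                FN=int((~called & labels).sum()),
                TN=int((~called & ~labels).sum()),
                threshold=float(t),
                continuity_correction=continuity_correction,
            )
        )
    return out


def roc_curve(
    scores: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> RocCurve:
    """ROC over the threshold grid with (0,0) and (1,1) anchors.

    Requires at least one positive and one negative label; AUC is the
    trapezoidal area under the FPR-sorted curve.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("ROC needs both classes present")
    matrices = threshold_confusions(scores, labels, thresholds)
    points = np.array([(m.FPR, m.sensitivity) for m in matrices])
    xs = np.concatenate([[0.0], points[:, 0], [1.0]])
    ys = np.concatenate([[0.0], points[:, 1], [1.0]])
    order = np.lexsort((ys, xs))
    auc = float(np.trapezoid(ys[order], xs[order]))
    return RocCurve(
        thresholds=np.asarray(thresholds), points=points, auc=auc,
        matrices=tuple(matrices),
    )


def best_threshold(
    matrices: TypingSequence[ConfusionMetrics], criterion: str = "plr"
) -> float:
    """Operating-point selection: argmax of PLR or of the chi-square
    -log10 P, ties resolved toward the higher threshold."""
    if criterion not in ("plr", "chi2"):
        raise ValueError(f"criterion must be 'plr' or 'chi2', got {criterion!r}")
    best: tuple[float, float] | None = None
    for m in matrices:
        if criterion == "plr":
            if "PLR" in m.undefined or (m.TP + m.FP) == 0:
                continue
            value = m.PLR
        else:
            if "chi2_neglog10p" in m.undefined:
                continue
            value = m.chi2_neglog10p
        key = (value, m.threshold if m.threshold is not None else 0.0)
        if best is None or key >= best:
            best = key
    if best is None:
        raise ValueError(f"criterion {criterion!r} undefined at every threshold")
    return best[1]


# ---------------------------------------------------------------------------
# GO enrichment in the encoding space


@dataclass(frozen=True)
class EnrichmentResult:
    go_term: str
    neighborhood_size: int
    hits: int
    background_rate: float
    pvalue: float


def _neighborhood(
    query: np.ndarray,
    corpus_vectors: np.ndarray,
    gene_ids: TypingSequence[str],
    exclusions: set[str],
    k: int,
) -> list[str]:
    distances = np.linalg.norm(corpus_vectors - query[None, :], axis=1)
    neighbors: list[str] = []
    seen: set[str] = set()
    for idx in np.argsort(distances, kind="stable"):
        gene = gene_ids[idx]
        if gene in exclusions or gene in seen:
            continue
        seen.add(gene)
        neighbors.append(gene)
        if len(neighbors) == k:
            break
    if len(neighbors) < k:
        raise ValueError(
            f"corpus holds only {len(neighbors)} usable entries for a "
            f"{k}-neighborhood"
        )
    return neighbors


def go_enrichment(
    queries: Mapping[str, np.ndarray],
    corpus_vectors: np.ndarray,
    gene_ids: TypingSequence[str],
    annotations: Mapping[str, set[str]],
    exclusions: Mapping[str, set[str]] | None = None,
    k: int = 2000,
    top: int = 20,
) -> dict[str, list[EnrichmentResult]]:
    """Per-query GO enrichment among encoding-space nearest neighbors.

    For each query, its *k* nearest corpus sequences by Euclidean distance
    (excluding per-query homolog hit lists and duplicate gene ids) form the
    neighborhood.  Each GO term's background rate is its frequency across
    all queries' neighborhoods pooled together, and the P-value is the
    one-sided (greater) exact binomial tail P(X >= x | n, p).  No
    multiple-testing correction is applied; the *top* lowest P-values are
    returned per query.
    """
    if not annotations:
        raise ValueError("empty annotation table")
    corpus_vectors = np.asarray(corpus_vectors, dtype=np.float64)
    exclusions = exclusions or {}
    neighborhoods = {
        name: _neighborhood(
            np.asarray(vec, dtype=np.float64), corpus_vectors, gene_ids,
            set(exclusions.get(name, set())), k,
        )
        for name, vec in queries.items()
    }
    pooled = [gene for genes in neighborhoods.values() for gene in genes]
    term_background: dict[str, int] = {}
    for gene in pooled:
        for term in annotations.get(gene, set()):
            term_background[term] = term_background.get(term, 0) + 1
    pooled_n = len(pooled)
    results: dict[str, list[EnrichmentResult]] = {}
    for name, genes in neighborhoods.items():
        n = len(genes)
        term_hits: dict[str, int] = {}
        for gene in genes:
            for term in annotations.get(gene, set()):
                term_hits[term] = term_hits.get(term, 0) + 1
        rows = []
        for term, background_count in term_background.items():
            x = term_hits.get(term, 0)
            p = background_count / pooled_n
            pvalue = 1.0 if x == 0 else float(stats.binom.sf(x - 1, n, p))
            rows.append(
                EnrichmentResult(
                    go_term=term, neighborhood_size=n, hits=x,
                    background_rate=p, pvalue=pvalue,
                )
            )
        rows.sort(key=lambda r: (r.pvalue, -r.hits, r.go_term))
        results[name] = rows[:top]
    return results


# ---------------------------------------------------------------------------
# Per-class aggregation


def per_class_tpr(
    scores: np.ndarray,
    labels: np.ndarray,
    classes: TypingSequence,
    thresholds: np.ndarray = DEFAULT_THRESHOLDS,
) -> dict:
    """Class-wise TPR aggregated over the threshold grid.

    For class c, TPR_c = sum_t TP_c(t) / (sum_t TP_c(t) + sum_t FN_c(t));
    classes never appearing as true positives or false negatives are
    omitted.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(bool)
    classes = np.asarray(classes)
    out: dict = {}
    for c in np.unique(classes):
        mask = (classes == c) & labels
        if not mask.any():
            continue
        tp = sum(int((scores[mask] >= t).sum()) for t in thresholds)
        fn = sum(int((scores[mask] < t).sum()) for t in thresholds)
        if tp + fn == 0:
            continue
        out[c.item() if hasattr(c, "item") else c] = tp / (tp + fn)
    return out


def idr_propensity(
    case_counts: Mapping, total_counts: Mapping, background_rates: Mapping
) -> dict:
    """Class-wise interaction propensity, min-max scaled to [0, 1].

    raw_c = (case_c / total_c) / background_c; classes with zero totals are
    excluded with a warning; a constant raw profile scales to all zeros.
    """
    raw: dict = {}
    for c, total in total_counts.items():
        if total <= 0:
            warnings.warn(f"class {c!r} has zero total occurrences; excluded", stacklevel=2)
            continue
        background = background_rates[c]
        if background <= 0:
            raise ValueError(f"background rate for class {c!r} must be positive")
        raw[c] = (case_counts.get(c, 0) / total) / background
    if not raw:
        return {}
    values = np.array(list(raw.values()))
    lo, hi = values.min(), values.max()
    if hi == lo:
        return {c: 0.0 for c in raw}
    return {c: float((v - lo) / (hi - lo)) for c, v in raw.items()}


# ---------------------------------------------------------------------------
# PCA of encoding vectors


def pca_project(vectors: TypingSequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project encoding vectors onto their first two principal components.

    Mean-centered covariance eigendecomposition; each component's sign is
    fixed so its largest-magnitude loading is positive.  Returns
    (coordinates (n, 2), components (2, d), explained-variance ratios (2,)).
    Degenerate input (all vectors identical) raises.
    """
    x = np.asarray(vectors, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 vectors")
    centered = x - x.mean(axis=0)
    if not centered.any():
        raise ValueError("PCA undefined for identical vectors")
    cov = centered.T @ centered / (x.shape[0] - 1)
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1][:2]
    components = eigenvectors[:, order].T
    for i in range(2):
        peak = np.argmax(np.abs(components[i]))
        if components[i, peak] < 0:
            components[i] = -components[i]
    coords = centered @ components.T
    total = eigenvalues.sum()
    explained = eigenvalues[order] / total if total > 0 else np.zeros(2)
    return coords, components, explained
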
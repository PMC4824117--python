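"""Evaluation machinery: protein-level splits, ROC/PR curves with vertical
averaging, precision-vs-confidence, and score-bin enrichment analysis.

Splits are always made at the protein level — every variant of a protein
falls wholly in the training or the testing side — so performance
estimates are not inflated by sequence/fold leakage.  The area under the
ROC curve is integrated by trapezoid; the area under the precision-recall
curve uses step-wise integration of the precision envelope, which avoids
the optimistic linear interpolation between PR points.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import config
from .classifier import LabeledDataset


class DegenerateCurveError(ValueError):
    """Curve computation needs both labels present."""


@dataclass(frozen=True)
class EvalCurves:
    roc_points: tuple[tuple[float, float], ...]   # (FPR, TPR)
    pr_points: tuple[tuple[float, float], ...]    # (recall, precision)
    auroc: float
    aupr: float


@dataclass(frozen=True)
class EnrichmentTable:
    bin_edges: tuple[float, ...]
    counts_a: tuple[int, ...]
    counts_b: tuple[int, ...]
    ratios: tuple[float, ...]                     # NaN where counts_b == 0
    background: float
    spearman: float
    spearman_p: float
    pearson: float
    pearson_p: float

    @property
    def undefined_bins(self) -> tuple[int, ...]:
        return tuple(i for i, r in enumerate(self.ratios) if math.isnan(r))


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def protein_level_splits(data: LabeledDataset, n_splits: int = config.N_SPLITS,
                         train_frac: float = config.TRAIN_FRAC,
                         seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Random train/test index splits made over proteins, not variants."""
    proteins = data.proteins
    if len(proteins) < 5:
        raise ValueError(f"need >= 5 proteins to split, got {len(proteins)}")
    rng = np.random.default_rng(seed)
    n_train = int(round(train_frac * len(proteins)))
    n_train = min(max(n_train, 1), len(proteins) - 1)
    splits = []
    for _ in range(n_splits):
        order = rng.permutation(proteins)
        train_set = set(order[:n_train])
        mask = np.asarray([g in train_set for g in data.groups])
        splits.append((np.flatnonzero(mask), np.flatnonzero(~mask)))
    return splits


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------


def roc_pr(scores, labels) -> EvalCurves:
    """ROC and PR curves from a threshold sweep over the unique scores.

    AUROC is integrated by trapezoid (ties handled by grouping equal
    scores); AUPR integrates the step-wise precision envelope over recall.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned 1-d arrays")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateCurveError("both labels must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    fp = np.cumsum(1 - y_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp, fp = tp[distinct], fp[distinct]

    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auroc = float(np.trapezoid(tpr, fpr))

    recall = tp / n_pos
    precision = tp / (tp + fp)
    pr_recall = np.r_[0.0, recall]
    pr_precision = np.r_[1.0, precision]      # convention: precision 1 at recall 0
    # precision envelope: best precision achievable at recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    widths = np.diff(np.r_[0.0, recall])
    aupr = float(np.sum(widths * envelope))

    return EvalCurves(
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
        pr_points=tuple(zip(pr_recall.tolist(), pr_precision.tolist())),
        auroc=auroc,
        aupr=aupr,
    )


def average_curves(curves: list[EvalCurves],
                   n_grid: int = config.AVERAGE_GRID_POINTS) -> EvalCurves:
    """Vertical averaging of curves on a fixed sweep grid.

    ROC curves are averaged as TPR over an FPR grid, PR curves as
    precision over a recall grid; the averaged areas are the means of the
    member areas.
    """
    if not curves:
        raise ValueError("no curves to average")
    grid = np.linspace(0.0, 1.0, n_grid)
    tprs, precisions = [], []
    for c in curves:
        fpr, tpr = np.asarray(c.roc_points).T
        tprs.append(np.interp(grid, fpr, tpr))
        rec, prec = np.asarray(c.pr_points).T
        order = np.argsort(rec, kind="stable")
        precisions.append(np.interp(grid, rec[order], prec[order]))
    mean_tpr = np.mean(tprs, axis=0)
    mean_prec = np.mean(precisions, axis=0)
    return EvalCurves(
        roc_points=tuple(zip(grid.tolist(), mean_tpr.tolist())),
        pr_points=tuple(zip(grid.tolist(), mean_prec.tolist())),
        auroc=float(np.mean([c.auroc for c in curves])),
        aupr=float(np.mean([c.aupr for c in curves])),
    )


def precision_at_cutoff(scores, labels, cutoff: float):
    """Precision over predictions scoring strictly above ``cutoff``.

    Returns ``(precision, fraction_above)``; when nothing scores above the
    cutoff the result is flagged empty as ``(nan, 0.0)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    above = s > cutoff
    if not above.any():
        return (math.nan, 0.0)
    precision = float(y[above].mean())
    return (precision, float(above.mean()))


# ---------------------------------------------------------------------------
# Score-bin enrichment
# ---------------------------------------------------------------------------


def _correlation_p(x: np.ndarray, y: np.ndarray, kind: str, observed: float,
                   seed: int = 0, exact_limit: int = 8,
                   n_mc: int = 20000) -> float:
    """Two-sided permutation p-value for a correlation statistic.

    Exact enumeration of all pairings up to ``exact_limit`` points; a
    seeded Monte-Carlo permutation approximation above that.  The rank
    correlation is computed as the Pearson correlation of rank-transformed
    values (rank-transforming commutes with permuting), which lets all
    permutations be evaluated in one matrix product.
    """
    if kind == "spearman":
        x, y = stats.rankdata(x), stats.rankdata(y)
    xs = x - x.mean()
    ys = y - y.mean()
    n = len(x)
    exact = n <= exact_limit
    if exact:
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_mc)])
    Y = ys[perms]
    r = (Y @ xs) / (np.sqrt((xs ** 2).sum()) * np.sqrt((Y ** 2).sum(axis=1)))
    count = int(np.sum(np.abs(r) >= abs(observed) - 1e-12))
    return count / len(perms) if exact else (count + 1) / (len(perms) + 1)


def _pearson_r(x, y) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _spearman_r(x, y) -> float:
    return float(stats.spearmanr(x, y).statistic)


def enrichment_by_bins(scores_a, scores_b, n_bins: int = 10,
                       permutation: bool = True, seed: int = 0) -> EnrichmentTable:
    """Count two score sets in equal-width bins and correlate the per-bin
    count ratio with the bin midpoint.

    Used to ask whether high-confidence deleterious predictions are
    enriched for one group (e.g. proband versus unaffected-sibling de novo
    mutations).  Bins with zero denominator yield NaN ratios and are
    excluded from (not zero-filled into) the correlations; the background
    line is the overall ``|A|/|B|`` ratio.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score sets must be non-empty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts_a, _ = np.histogram(np.clip(a, 0.0, 1.0), bins=edges)
    counts_b, _ = np.histogram(np.clip(b, 0.0, 1.0), bins=edges)
    mids = (edges[:-1] + edges[1:]) / 2.0
    ratios = np.where(counts_b > 0, counts_a / np.maximum(counts_b, 1), np.nan)

    defined = ~np.isnan(ratios)
    if defined.sum() >= 3 and len(np.unique(ratios[defined])) > 1:
        x, y = mids[defined], ratios[defined]
        spearman = _spearman_r(x, y)
        pearson = _pearson_r(x, y)
        if permutation and defined.sum() <= 12:
            sp_p = _correlation_p(x, y, "spearman", spearman, seed=seed)
            pe_p = _correlation_p(x, y, "pearson", pearson, seed=seed)
        else:
            sp_p = float(stats.spearmanr(x, y).pvalue)
            pe_p = float(stats.pearsonr(x, y).pvalue)
    else:
        spearman = pearson = sp_p = pe_p = math.nan

    return EnrichmentTable(
        bin_edges=tuple(edges.tolist()),
        counts_a=tuple(int(c) for c in counts_a),
        counts_b=tuple(int(c) for c in counts_b),
        ratios=tuple(float(r) for r in ratios),
        background=float(a.size / b.size),
        spearman=spearman, spearman_p=sp_p,
        pearson=pearson, pearson_p=pe_p,
    )


def contingency_enrichment(a_pos: int, a_neg: int, b_pos: int, b_neg: int):
    """Enrichment ratios from a 2x2 classification contingency.

    ``pos_ratio = a_pos / b_pos`` (enrichment of group A among positive
    calls) and ``neg_ratio = a_neg / b_neg``, each reported to 2 decimals.
    A zero denominator flags the ratio as NaN rather than raising.
    """
    for c in (a_pos, a_neg, b_pos, b_neg):
        if c < 0:
            raise ValueError("counts must be non-negative")
    pos = round(a_pos / b_pos, 2) if b_pos > 0 else math.nan
    neg = round(a_neg / b_neg, 2) if b_neg > 0 else math.nan
    return (pos, neg)
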
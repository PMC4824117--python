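"""Sparse logistic regression with stability-based feature selection.

A deleterious-probability classifier over the 106-feature representation.
Feature selection runs an L1-penalized logistic regression over repeated
protein-level subsamples and a penalty grid, keeps the features selected
most frequently (at most 20), and the final model is a lightly
ridge-regularized logistic fit on the selected, standardized features.
Three modes are supported: combined (selected features), sequence_only
(the 5 profile features — used when a variant cannot be placed on a
structural model) and structure_only (the 101 structural features).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from . import config
from .config import SEQUENCE_FEATURES, all_feature_names, structure_feature_names
from .formats_io import VariantSpec
from .structure_features import FeatureVector

logger = logging.getLogger(__name__)

MODES = ("combined", "sequence_only", "structure_only")


class DegenerateLabelError(ValueError):
    """Training data carries a single class."""


class MissingFeatureError(KeyError):
    """A selected feature is absent (NaN) from the input vector."""


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Labeled variants with aligned feature vectors, grouped by protein."""

    variants: list[VariantSpec]
    features: np.ndarray                 # (n_records, n_features)
    feature_names: tuple[str, ...]
    labels: np.ndarray = field(init=False)     # 1 = deleterious, 0 = neutral
    groups: np.ndarray = field(init=False)     # protein_id per record

    def __post_init__(self) -> None:
        if len(self.variants) != len(self.features):
            raise ValueError("variants and feature rows must align")
        labels = []
        for v in self.variants:
            if v.label not in ("deleterious", "neutral"):
                raise ValueError(f"unlabeled record {v.protein_id} {v.name}")
            labels.append(1 if v.label == "deleterious" else 0)
        self.labels = np.asarray(labels, dtype=int)
        self.groups = np.asarray([v.protein_id for v in self.variants], dtype=object)
        self.features = np.asarray(self.features, dtype=float)

    @property
    def proteins(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def column_indices(self, names) -> np.ndarray:
        return np.asarray([self.feature_names.index(n) for n in names], dtype=int)

    def subset(self, record_indices) -> "LabeledDataset":
        idx = np.asarray(record_indices, dtype=int)
        return LabeledDataset(
            variants=[self.variants[i] for i in idx],
            features=self.features[idx],
            feature_names=self.feature_names,
        )


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClassifierModel:
    mode: str
    selected_features: tuple[str, ...]
    weights: tuple[float, ...]
    intercept: float
    centers: tuple[float, ...]
    scales: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "combined" and len(self.selected_features) > config.MAX_SELECTED:
            raise ValueError("combined mode allows at most "
                             f"{config.MAX_SELECTED} features")
        if not all(math.isfinite(w) for w in self.weights):
            raise ValueError("weights must be finite")


@dataclass(frozen=True)
class Prediction:
    variant: VariantSpec | None
    score: float
    label: str
    contributions: dict[str, float]
    mode: str

    @property
    def logit(self) -> float:
        return math.log(self.score / (1.0 - self.score))


# ---------------------------------------------------------------------------
# Stability selection
# ---------------------------------------------------------------------------


def stability_select(data: LabeledDataset,
                     n_resamples: int = config.N_RESAMPLES,
                     subsample_frac: float = config.SUBSAMPLE_FRAC,
                     lambda_grid=config.LAMBDA_GRID,
                     freq_threshold: float = config.FREQ_THRESHOLD,
                     seed: int = 0,
                     max_selected: int = config.MAX_SELECTED,
                     redundancy_r: float = config.REDUNDANCY_R) -> list[str]:
    """Frequency-based feature selection over protein-level subsamples.

    For each of ``n_resamples`` random subsamples of ``subsample_frac`` of
    the proteins, an L1-penalized logistic regression is fitted at every
    penalty in ``lambda_grid``; a feature's score is the maximum, over the
    grid, of the fraction of subsamples in which its coefficient is
    nonzero.  Features scoring above ``freq_threshold`` are returned in
    decreasing-frequency order, truncated to ``max_selected``.

    The L1 path does not itself resolve near-duplicate columns (the
    optimum is indifferent to how weight splits across them), so the
    ranked list is filtered greedily: a candidate whose absolute Pearson
    correlation with an already-kept feature exceeds ``redundancy_r`` is
    dropped, keeping the selection non-redundant.
    """
    _check_two_classes(data.labels)
    proteins = data.proteins
    if len(proteins) < 2:
        raise ValueError("stability selection needs >= 2 proteins")
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(subsample_frac * len(proteins))))
    lambdas = np.asarray(list(lambda_grid), dtype=float)

    X = np.nan_to_num(data.features, nan=0.0)
    counts = np.zeros((len(lambdas), X.shape[1]), dtype=int)
    effective = 0
    for _ in range(n_resamples):
        chosen = set(rng.permutation(proteins)[:n_keep])
        mask = np.asarray([g in chosen for g in data.groups])
        y = data.labels[mask]
        if y.min() == y.max():
            continue                       # degenerate subsample: skip, keep going
        Xs, centers, scales = _standardize_fit(X[mask])
        effective += 1
        for li, lam in enumerate(lambdas):
            clf = LogisticRegression(l1_ratio=1.0, C=1.0 / lam,
                                     solver="liblinear", max_iter=2000,
                                     random_state=0)
            clf.fit(Xs, y)
            counts[li] += (np.abs(clf.coef_[0]) > 1e-8)
    if effective == 0:
        raise DegenerateLabelError("every subsample was single-class")

    freq = counts / effective
    best = freq.max(axis=0)
    order = np.argsort(-best, kind="stable")
    selected: list[str] = []
    kept_cols: list[int] = []
    for j in order:
        if best[j] <= freq_threshold or len(selected) >= max_selected:
            continue
        if any(abs(_safe_corr(X[:, j], X[:, k])) > redundancy_r for k in kept_cols):
            continue
        selected.append(data.feature_names[j])
        kept_cols.append(j)
    logger.info("stability selection kept %d/%d features (threshold %.2f)",
                len(selected), X.shape[1], freq_threshold)
    return selected


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise DegenerateLabelError("training data must contain both classes")


def _standardize_fit(X: np.ndarray):
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    scales = np.where(scales == 0.0, 1.0, scales)
    return (X - centers) / scales, centers, scales


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------


def features_for_mode(mode: str, selected=None) -> tuple[str, ...]:
    if mode == "sequence_only":
        return SEQUENCE_FEATURES
    if mode == "structure_only":
        return structure_feature_names()
    if mode == "combined":
        if selected is None:
            raise ValueError("combined mode requires a selected feature list")
        return tuple(selected)
    raise ValueError(f"unknown mode {mode!r}")


def train(data: LabeledDataset, selected=None, mode: str = "combined",
          C: float = config.FINAL_FIT_C) -> ClassifierModel:
    """Fit the final logistic model on standardized selected features.

    The fit minimizes the logistic loss with a light ridge penalty
    (inverse strength ``C``); standardization parameters are learned on
    the training data only and stored with the model.  Deterministic for
    fixed data and configuration, and invariant to record order.
    """
    _check_two_classes(data.labels)
    names = features_for_mode(mode, selected)
    unknown = [n for n in names if n not in data.feature_names]
    if unknown:
        raise KeyError(f"features not in dataset: {unknown}")
    cols = data.column_indices(names)
    X = np.nan_to_num(data.features[:, cols], nan=0.0)
    Xs, centers, scales = _standardize_fit(X)
    clf = LogisticRegression(l1_ratio=0.0, C=C, solver="lbfgs", max_iter=5000)
    clf.fit(Xs, data.labels)
    if clf.n_iter_[0] >= 5000:
        logger.warning("final fit hit the iteration cap (%d iterations)", clf.n_iter_[0])
    return ClassifierModel(
        mode=mode,
        selected_features=tuple(names),
        weights=tuple(float(w) for w in clf.coef_[0]),
        intercept=float(clf.intercept_[0]),
        centers=tuple(float(c) for c in centers),
        scales=tuple(float(s) for s in scales),
    )


def predict(model: ClassifierModel, fv: FeatureVector,
            variant: VariantSpec | None = None) -> Prediction:
    """Deleterious probability for one feature vector.

    score = logistic(intercept + Σ w_i · x_i_standardized); the label is
    deleterious only for scores strictly above 0.5.  Per-feature
    contribution terms (weight × standardized value) are recorded for
    interpretation.  A NaN selected feature raises MissingFeatureError
    (callers route such variants to the sequence-only model).
    """
    fmap = fv.as_dict() if hasattr(fv, "as_dict") else dict(fv)
    contributions = {}
    logit = model.intercept
    for name, w, c, s in zip(model.selected_features, model.weights,
                             model.centers, model.scales):
        if name not in fmap:
            raise MissingFeatureError(f"feature {name!r} absent from input")
        x = fmap[name]
        if math.isnan(x):
            raise MissingFeatureError(f"feature {name!r} is missing (NaN)")
        term = w * (x - c) / s
        contributions[name] = term
        logit += term
    score = 1.0 / (1.0 + math.exp(-max(-500.0, min(500.0, logit))))
    label = "deleterious" if score > config.DECISION_THRESHOLD else "neutral"
    return Prediction(variant=variant, score=score, label=label,
                      contributions=contributions, mode=model.mode)


def aggregate_isoforms(predictions: list[Prediction]) -> Prediction:
    """Collapse per-isoform predictions for one gene to the highest score.

    Any deleterious isoform prediction is treated as evidence of
    deleteriousness; ties break to the lexicographically first isoform ID.
    """
    if not predictions:
        raise ValueError("no predictions to aggregate")

    def key(p: Prediction):
        iso = p.variant.protein_id if p.variant is not None else ""
        return (-p.score, iso)

    return sorted(predictions, key=key)[0]


# ---------------------------------------------------------------------------
# Serialization (versioned flat text)
# ---------------------------------------------------------------------------

MODEL_FORMAT_VERSION = 1


def save_model(model: ClassifierModel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# strudel-model v{MODEL_FORMAT_VERSION}\n")
        fh.write(f"mode\t{model.mode}\n")
        fh.write(f"intercept\t{model.intercept!r}\n")
        fh.write("feature\tcenter\tscale\tweight\n")
        for n, c, s, w in zip(model.selected_features, model.centers,
                              model.scales, model.weights):
            fh.write(f"{n}\t{c!r}\t{s!r}\t{w!r}\n")


def load_model(path) -> ClassifierModel:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("# strudel-model v"):
        raise ValueError(f"{path}: not a model file")
    version = int(lines[0].rsplit("v", 1)[1])
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model version {version}")
    mode = lines[1].split("\t")[1]
    intercept = float(lines[2].split("\t")[1])
    names, centers, scales, weights = [], [], [], []
    for line in lines[4:]:
        if not line:
            continue
        n, c, s, w = line.split("\t")
        names.append(n)
        centers.append(float(c))
        scales.append(float(s))
        weights.append(float(w))
    return ClassifierModel(mode=mode, selected_features=tuple(names),
                           weights=tuple(weights), intercept=intercept,
                           centers=tuple(centers), scales=tuple(scales))
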
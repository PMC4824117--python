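"""Automated physical interpretation of a deleterious prediction.

Each structure feature's weighted contribution to the decision logit is
attributed to exactly one physical category (hydrogen bonding, packing,
disulfide, backbone, solvation, electrostatics, surface, global).
Categories whose summed deleterious-direction contribution exceeds a
configurable fraction of the total absolute structure contribution are
reported, yielding a one-sentence physical hypothesis for why the variant
disrupts the protein.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import config
from .classifier import Prediction


class CategoryTableError(KeyError):
    """A structure feature name has no category assignment."""


def category_of_feature(name: str) -> str | None:
    """Physical category of one feature name; None for sequence features."""
    if name in config.SEQUENCE_FEATURES:
        return None
    if name == config.SURFACE_FEATURE:
        return "surface"
    for prefix in ("ddg_", "relax_"):
        if name.startswith(prefix):
            rest = name[len(prefix):]
            # strip a trailing statistic suffix for the relax block;
            # longest suffix first ("min_quantile" before "quantile")
            for stat in sorted(config.RELAX_STATS + config.RELAX_TOTAL_STATS,
                               key=len, reverse=True):
                if rest.endswith("_" + stat):
                    rest = rest[: -len(stat) - 1]
                    break
            if rest in config.CATEGORY_OF_TERM:
                return config.CATEGORY_OF_TERM[rest]
    raise CategoryTableError(f"no category for feature {name!r}")


def check_category_table() -> None:
    """The category table must be total over the shipped feature manifest."""
    for name in config.all_feature_names():
        category_of_feature(name)


@dataclass(frozen=True)
class InterpretationReport:
    variant: object
    category_scores: dict[str, float]
    top_categories: tuple[str, ...]
    narrative: str


def categorize_contributions(
        prediction: Prediction,
        threshold: float = config.INTERPRETATION_THRESHOLD) -> InterpretationReport:
    """Fold per-feature contributions into physical-category evidence.

    Every structure-feature contribution is assigned to exactly one
    category; a category is reported when its summed positive
    (deleterious-direction) contribution exceeds ``threshold`` times the
    total absolute structure contribution.  Sequence-only predictions get
    a reduced, conservation-based report since no physical evidence exists.
    """
    if prediction.mode == "sequence_only":
        narrative = _render(prediction, ())
        return InterpretationReport(variant=prediction.variant,
                                    category_scores={}, top_categories=(),
                                    narrative=narrative + " [sequence conservation only]")

    scores: dict[str, float] = {}
    total_abs = 0.0
    for name, contrib in prediction.contributions.items():
        cat = category_of_feature(name)
        if cat is None:
            continue
        scores[cat] = scores.get(cat, 0.0) + contrib
        total_abs += abs(contrib)
    cutoff = threshold * total_abs
    top = tuple(sorted(
        (c for c, s in scores.items() if s > cutoff and s > 0.0),
        key=lambda c: -scores[c],
    ))
    return InterpretationReport(variant=prediction.variant,
                                category_scores=scores, top_categories=top,
                                narrative=_render(prediction, top))


def _render(prediction: Prediction, top_categories) -> str:
    base = f"predicted {prediction.label} ({prediction.score:.3f})"
    if prediction.label == "deleterious" and top_categories:
        return f"{base}; evidence: {', '.join(top_categories)}"
    return base


def render_narrative(report: InterpretationReport) -> str:
    """Deterministic one-sentence rendering of a report."""
    return report.narrative


def top_structural_terms(prediction: Prediction, k: int = 3) -> str:
    """Comma-joined names of the k largest deleterious-direction structure
    contributions (for the predictions TSV)."""
    structural = [
        (name, c) for name, c in prediction.contributions.items()
        if category_of_feature(name) is not None and c > 0
    ]
    structural.sort(key=lambda t: (-t[1], t[0]))
    return ",".join(name for name, _ in structural[:k])
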
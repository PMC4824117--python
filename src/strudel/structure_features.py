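"""Structure-based features from matched native/variant score ensembles.

All structural signal is expressed relative to the refined ensemble of the
native protein: a variant statistic is reported as its displacement from
the native-ensemble mean in units of the native-ensemble standard
deviation.  The fast stability-estimate protocol contributes 17 per-term
features, the broader refinement protocol 83 ensemble statistics, and the
accessible-surface table 1 feature — 101 structure features in total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import config
from .formats_io import FormatError, ScoreTable, parse_probe_output


class ManifestError(KeyError):
    """A manifest score term is missing from a score table."""


class EnsembleSizeError(ValueError):
    """Too few decoys for ensemble statistics."""


@dataclass(frozen=True)
class EnsemblePair:
    """Matched native and variant score tables from one protocol."""

    native: ScoreTable
    variant: ScoreTable
    protocol: str

    def __post_init__(self) -> None:
        if set(self.native.terms) != set(self.variant.terms):
            raise FormatError("native and variant tables must share a score-term set")
        if self.native.n_decoys < 2:
            raise EnsembleSizeError("native ensemble needs >= 2 decoys for a spread")


@dataclass(frozen=True)
class FeatureVector:
    """The named 106-feature representation of one variant.

    When ``structure_available`` is false the 101 structure entries are
    NaN (missing-marked, never imputed) and only the 5 sequence features
    carry values.
    """

    names: tuple[str, ...]
    values: tuple[float, ...]
    structure_available: bool

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values must align")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))

    def __getitem__(self, name: str) -> float:
        return self.values[self.names.index(name)]


# ---------------------------------------------------------------------------
# Core normalization
# ---------------------------------------------------------------------------


def ensemble_normalize(variant_values, native_values,
                       cap: float = config.ZERO_SPREAD_SENTINEL) -> float:
    """Mean shift of the variant ensemble in native-sd units.

    Returns ``(mean(variant) - mean(native)) / sd(native)`` with the sample
    (ddof=1) standard deviation.  A native ensemble with zero spread yields
    a signed sentinel capped at ±``cap`` (0 when the means also agree), so
    degenerate fixtures produce bounded features.
    """
    v = np.asarray(variant_values, dtype=float)
    nat = np.asarray(native_values, dtype=float)
    if v.size == 0 or nat.size == 0:
        raise ValueError("empty ensemble")
    if nat.size < 2:
        raise EnsembleSizeError("native ensemble needs >= 2 values")
    shift = v.mean() - nat.mean()
    sd = nat.std(ddof=1)
    if sd == 0.0:
        return 0.0 if shift == 0.0 else math.copysign(cap, shift)
    return float(np.clip(shift / sd, -cap, cap))


def _require_terms(table: ScoreTable, terms) -> None:
    missing = [t for t in terms if t not in table.terms]
    if missing:
        raise ManifestError(f"manifest terms missing from scorefile: {missing}")


# ---------------------------------------------------------------------------
# Fast stability-estimate block (17 features)
# ---------------------------------------------------------------------------


def compute_ddg_features(pair: EnsemblePair,
                         best_k: int = config.DDG_BEST_K) -> dict[str, float]:
    """One normalized per-term delta for the fixed 17-term manifest.

    Each side is reduced to its ``best_k`` lowest-total_score decoys (the
    usual averaging practice for this protocol) before normalizing the
    variant column against the full native column spread.
    """
    if pair.protocol != "ddg_monomer":
        raise ValueError(f"expected ddg_monomer pair, got {pair.protocol}")
    _require_terms(pair.native, config.DDG_TERMS)
    _require_terms(pair.variant, config.DDG_TERMS)

    nat_order = np.argsort(pair.native.column("total_score"), kind="stable")[:best_k]
    var_order = np.argsort(pair.variant.column("total_score"), kind="stable")[:best_k]
    features = {}
    for term in config.DDG_TERMS:
        nat_col = np.asarray(pair.native.column(term))
        var_col = np.asarray(pair.variant.column(term))
        # native spread from the full column; means from best-k decoys
        nat_best = nat_col[nat_order]
        sd = nat_col.std(ddof=1)
        shift = var_col[var_order].mean() - nat_best.mean()
        if sd == 0.0:
            value = 0.0 if shift == 0.0 else math.copysign(config.ZERO_SPREAD_SENTINEL, shift)
        else:
            value = float(np.clip(shift / sd, -config.ZERO_SPREAD_SENTINEL,
                                  config.ZERO_SPREAD_SENTINEL))
        features[f"ddg_{term}"] = value
    return features


# ---------------------------------------------------------------------------
# Refinement-ensemble block (83 features)
# ---------------------------------------------------------------------------


def compute_relax_features(pair: EnsemblePair) -> dict[str, float]:
    """Ensemble statistics per score term for the fixed 20-term manifest.

    Per term: normalized mean shift, normalized minimum shift, the
    native-ensemble quantile of the variant mean (fraction of native
    decoys at or below it), and the overlap fraction (variant decoys
    inside the native [min, max] range).  Three whole-ensemble statistics
    on the total score complete the 83: sd ratio, native quantile of the
    variant minimum, and the fraction of native decoys inside the variant
    range.
    """
    if pair.protocol != "fast_relax":
        raise ValueError(f"expected fast_relax pair, got {pair.protocol}")
    _require_terms(pair.native, config.RELAX_TERMS)
    _require_terms(pair.variant, config.RELAX_TERMS)
    if pair.native.n_decoys < 2 or pair.variant.n_decoys < 2:
        raise EnsembleSizeError("need >= 2 decoys per side for ensemble statistics")

    features: dict[str, float] = {}
    cap = config.ZERO_SPREAD_SENTINEL
    for term in config.RELAX_TERMS:
        nat = np.asarray(pair.native.column(term), dtype=float)
        var = np.asarray(pair.variant.column(term), dtype=float)
        sd = nat.std(ddof=1)

        def norm(shift: float) -> float:
            if sd == 0.0:
                return 0.0 if shift == 0.0 else math.copysign(cap, shift)
            return float(np.clip(shift / sd, -cap, cap))

        features[f"relax_{term}_mean_shift"] = norm(var.mean() - nat.mean())
        features[f"relax_{term}_min_shift"] = norm(var.min() - nat.min())
        features[f"relax_{term}_quantile"] = float(np.mean(nat <= var.mean()))
        features[f"relax_{term}_overlap"] = float(
            np.mean((var >= nat.min()) & (var <= nat.max()))
        )

    nat_tot = np.asarray(pair.native.column("total_score"), dtype=float)
    var_tot = np.asarray(pair.variant.column("total_score"), dtype=float)
    nat_sd = nat_tot.std(ddof=1)
    var_sd = var_tot.std(ddof=1)
    features["relax_total_score_sd_ratio"] = (
        float(min(var_sd / nat_sd, cap)) if nat_sd > 0 else (0.0 if var_sd == 0 else cap)
    )
    features["relax_total_score_min_quantile"] = float(np.mean(nat_tot <= var_tot.min()))
    features["relax_total_score_native_overlap"] = float(
        np.mean((nat_tot >= var_tot.min()) & (nat_tot <= var_tot.max()))
    )
    return features


# ---------------------------------------------------------------------------
# Accessible-surface feature
# ---------------------------------------------------------------------------


def surface_area_feature(probe_output: str, model_residue: int) -> float:
    """Accessible surface area of ``model_residue`` as reported in the
    per-residue surface table (no re-computation)."""
    areas = parse_probe_output(probe_output)
    if model_residue not in areas:
        raise KeyError(f"residue {model_residue} absent from surface output")
    return areas[model_residue]


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_feature_vector(seq, ddg=None, relax=None, surface=None,
                            available: bool = True) -> FeatureVector:
    """Assemble the fixed-order 106-feature vector.

    ``seq`` is a SeqFeatureSet (or name->value mapping of the 5 sequence
    features).  With ``available=True`` all three structure blocks must be
    present; with ``available=False`` structure entries are NaN-marked.
    """
    names = config.all_feature_names()
    seq_map = seq.as_dict() if hasattr(seq, "as_dict") else dict(seq)
    if available:
        if ddg is None or relax is None or surface is None:
            raise ValueError("available=True requires ddg, relax and surface blocks")
        full = dict(seq_map)
        full.update(ddg)
        full.update(relax)
        full[config.SURFACE_FEATURE] = float(surface)
        missing = [n for n in names if n not in full]
        if missing:
            raise ValueError(f"assembly missing features: {missing[:5]}...")
        values = tuple(float(full[n]) for n in names)
    else:
        values = tuple(
            float(seq_map[n]) if n in seq_map else math.nan for n in names
        )
    return FeatureVector(names=names, values=values, structure_available=available)
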
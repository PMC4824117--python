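"""Synthetic generators for every input the pipeline consumes.

These generators produce sequence profiles, matched native/variant score
ensembles, per-residue surface tables, stub structural models and fully
labeled feature datasets with controllable planted signal, so the whole
system — parsers included — is testable without any external tool run or
download.  Emission uses the exact external dialects (ASCII PSSM, score
file, surface table, variant TSV), exercising the real parsing path.

All generators are pure functions of their seed.  Default dataset scale
(200 proteins x ~5 variants, deleterious fraction 0.606 echoing the
5,740/9,477 composition of curated training collections) keeps a full
train/evaluate cycle at desk scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import config
from .classifier import LabeledDataset
from .formats_io import ScoreTable, SequenceProfile, VariantSpec
from .structure_features import EnsemblePair

#: Typical magnitudes (mean, sd) of per-decoy score-term values, in score
#: units; loosely shaped like an all-atom decomposition of a small domain.
TERM_SCALES = {
    "fa_atr": (-900.0, 6.0), "fa_rep": (110.0, 5.0), "fa_sol": (500.0, 5.0),
    "fa_intra_rep": (2.0, 0.2), "fa_elec": (-250.0, 4.0), "pro_close": (2.0, 0.5),
    "hbond_sr_bb": (-60.0, 2.0), "hbond_lr_bb": (-30.0, 2.0),
    "hbond_bb_sc": (-15.0, 1.5), "hbond_sc": (-20.0, 1.5),
    "dslf_fa13": (-4.0, 0.5), "rama": (-20.0, 2.0), "omega": (15.0, 1.5),
    "fa_dun": (300.0, 5.0), "p_aa_pp": (-35.0, 2.0), "ref": (25.0, 0.01),
    "yhh_planarity": (0.5, 0.1), "chainbreak": (0.0, 0.05),
    "atom_pair_constraint": (0.0, 0.1), "total_score": (-350.0, 8.0),
}


# ---------------------------------------------------------------------------
# Sequence profiles
# ---------------------------------------------------------------------------


def generate_profile(sequence: str, conserved_positions=(), seed: int = 0,
                     protein_id: str = "synthetic") -> SequenceProfile:
    """Synthetic PSSM: conserved positions get a strongly favoured native
    amino acid and high information content; the rest are near-neutral.

    Serializable to the ASCII PSSM dialect with bit-exact round-trip.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for p in conserved_positions:
        if not 1 <= p <= len(sequence):
            raise IndexError(f"conserved position {p} outside 1..{len(sequence)}")
    rng = np.random.default_rng(seed)
    conserved = set(conserved_positions)
    log_odds, percentages, info, weights = [], [], [], []
    for i, aa in enumerate(sequence, start=1):
        native_idx = config.PSSM_ALPHABET.index(aa)
        if i in conserved:
            row = rng.integers(-4, 0, size=20)
            row[native_idx] = rng.integers(7, 10)
            info.append(round(float(rng.uniform(2.5, 4.0)), 2))
            pct = np.zeros(20, dtype=int)
            pct[native_idx] = 100
        else:
            row = rng.integers(-2, 3, size=20)
            info.append(round(float(rng.uniform(0.1, 1.2)), 2))
            pct = rng.integers(0, 12, size=20)
        log_odds.append(tuple(int(v) for v in row))
        percentages.append(tuple(int(v) for v in pct))
        weights.append(round(float(rng.uniform(0.1, 1.5)), 2))
    return SequenceProfile(protein_id=protein_id, sequence=sequence,
                           log_odds=tuple(log_odds), info_content=tuple(info),
                           percentages=tuple(percentages), weights=tuple(weights))


# ---------------------------------------------------------------------------
# Score ensembles
# ---------------------------------------------------------------------------


def generate_score_ensembles(effect: dict[str, float] | None = None,
                             n_decoys: int = config.DEFAULT_RELAX_DECOYS,
                             seed: int = 0, protocol: str = "fast_relax",
                             terms=None, sigma_scale: float = 1.0) -> EnsemblePair:
    """Matched native/variant ensembles with per-term planted shifts.

    Native decoys draw from Normal(mu_t, sigma_t) per term; variant decoys
    are shifted by ``effect[t]`` native standard deviations.  ``effect``
    defaults to no shift anywhere.
    """
    if n_decoys < 2:
        raise ValueError("n_decoys must be >= 2")
    if sigma_scale <= 0:
        raise ValueError("sigma_scale must be positive")
    effect = effect or {}
    if terms is None:
        terms = config.RELAX_TERMS if protocol == "fast_relax" else config.DDG_TERMS
    terms = tuple(terms)
    unknown = [t for t in effect if t not in terms]
    if unknown:
        raise KeyError(f"effect names unknown terms: {unknown}")
    rng = np.random.default_rng(seed)
    nat_rows, var_rows = [], []
    for side, rows in (("native", nat_rows), ("variant", var_rows)):
        cols = []
        for t in terms:
            mu, sigma = TERM_SCALES.get(t, (0.0, 1.0))
            sigma *= sigma_scale
            shift = effect.get(t, 0.0) * sigma if side == "variant" else 0.0
            cols.append(rng.normal(mu + shift, sigma, size=n_decoys))
        rows.extend(tuple(float(x) for x in row)
                    for row in np.column_stack(cols))
    native = ScoreTable(protocol=protocol, terms=terms, decoys=tuple(nat_rows))
    variant = ScoreTable(protocol=protocol, terms=terms, decoys=tuple(var_rows))
    return EnsemblePair(native=native, variant=variant, protocol=protocol)


# ---------------------------------------------------------------------------
# Stub structural models
# ---------------------------------------------------------------------------


def make_stub_pdb(sequence: str, chain: str = "A", start_resnum: int = 1,
                  het_records: int = 0) -> str:
    """Minimal CA-trace PDB text for structure-standardization tests."""
    lines = []
    serial = 1
    for i, aa in enumerate(sequence):
        resname = config.ONE_TO_THREE[aa]
        x = 3.8 * i
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname} {chain}{start_resnum + i:4d}    "
            f"{x:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C"
        )
        serial += 1
    for j in range(het_records):
        lines.append(
            f"HETATM{serial:5d} ZN    ZN {chain}{900 + j:4d}    "
            f"{0.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00          ZN"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def generate_probe_table(residue_numbers, seed: int = 0) -> dict[int, float]:
    """Synthetic per-residue accessible-surface areas (square angstroms)."""
    rng = np.random.default_rng(seed)
    return {int(n): round(float(rng.uniform(0.0, 150.0)), 1)
            for n in residue_numbers}


# ---------------------------------------------------------------------------
# Labeled datasets with planted signal
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignalSpec:
    """Shape and planted signal of a synthetic labeled dataset."""

    n_proteins: int = 200
    variants_per_protein: tuple[int, int] = (3, 7)    # inclusive range
    deleterious_fraction: float = 0.606               # ~5740/9477
    informative_features: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.deleterious_fraction < 1.0:
            raise ValueError("deleterious_fraction must lie in (0, 1)")
        names = set(config.all_feature_names())
        unknown = [f for f in self.informative_features if f not in names]
        if unknown:
            raise KeyError(f"informative features not in manifest: {unknown}")
        for f, e in self.informative_features.items():
            if not math.isfinite(e):
                raise ValueError(f"effect size for {f} must be finite")


def generate_labeled_dataset(spec: SignalSpec) -> LabeledDataset:
    """Labeled variants grouped into proteins with class-separated signal.

    Every feature is i.i.d. Gaussian noise except the informative ones,
    whose mean is shifted by the named effect size in deleterious records.
    Proteins carry several variants each so protein-level splitting is
    meaningful.
    """
    rng = np.random.default_rng(spec.seed)
    names = config.all_feature_names()
    name_idx = {n: i for i, n in enumerate(names)}
    lo, hi = spec.variants_per_protein
    aas = config.PSSM_ALPHABET

    variants: list[VariantSpec] = []
    rows: list[np.ndarray] = []
    for p in range(spec.n_proteins):
        protein_id = f"SYN{p:04d}"
        n_var = int(rng.integers(lo, hi + 1))
        for v in range(n_var):
            deleterious = bool(rng.random() < spec.deleterious_fraction)
            nat, mut = rng.choice(20, size=2, replace=False)
            variants.append(VariantSpec(
                protein_id=protein_id, position=v + 1,
                native_aa=aas[nat], variant_aa=aas[mut],
                label="deleterious" if deleterious else "neutral",
            ))
            row = rng.normal(0.0, spec.noise_sd, size=len(names))
            if deleterious:
                for f, e in spec.informative_features.items():
                    row[name_idx[f]] += e
            rows.append(row)
    return LabeledDataset(variants=variants, features=np.vstack(rows),
                          feature_names=names)
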
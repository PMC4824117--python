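"""Central configuration: feature manifests, amino-acid tables, and defaults.

The classifier consumes a fixed 106-feature representation of a missense
variant: 5 sequence-profile features, 17 fast stability-estimate (ddG)
features, 83 refinement-ensemble (relax) features and 1 accessible-surface
feature.  The exact score-term manifests are fixed here and overridable by
callers; counts and term semantics follow standard all-atom score functions.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Amino acids
# ---------------------------------------------------------------------------

#: Column order of the ASCII PSSM dialect (PSIBLAST -out_ascii_pssm).
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

STANDARD_AAS = frozenset(PSSM_ALPHABET)

#: Broad chemical classes used by the amino-change feature.
AA_CLASSES = {
    "nonpolar": frozenset("AVLIMFWPG"),
    "polar": frozenset("STCYNQ"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
}

AA_CLASS_OF = {aa: cls for cls, members in AA_CLASSES.items() for aa in members}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# ---------------------------------------------------------------------------
# Feature manifests
# ---------------------------------------------------------------------------

SEQUENCE_FEATURES = ("pssm_nat", "pssm_mut", "pssm_diff", "info_cont", "aminochange")

#: 16 all-atom score components + total — the fast stability-estimate block.
DDG_TERMS = (
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_rep", "fa_elec", "pro_close",
    "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc", "dslf_fa13",
    "rama", "omega", "fa_dun", "p_aa_pp", "ref", "total_score",
)

#: 20 score terms tracked for the refinement-ensemble block.
RELAX_TERMS = (
    "fa_atr", "fa_rep", "fa_sol", "fa_intra_rep", "fa_elec", "pro_close",
    "hbond_sr_bb", "hbond_lr_bb", "hbond_bb_sc", "hbond_sc", "dslf_fa13",
    "rama", "omega", "fa_dun", "p_aa_pp", "ref", "yhh_planarity",
    "chainbreak", "atom_pair_constraint", "total_score",
)

#: Four per-term ensemble statistics (see structure_features).
RELAX_STATS = ("mean_shift", "min_shift", "quantile", "overlap")

#: Three whole-ensemble statistics on the total score.
RELAX_TOTAL_STATS = ("sd_ratio", "min_quantile", "native_overlap")

SURFACE_FEATURE = "probe_accsurf"


def ddg_feature_names() -> tuple[str, ...]:
    return tuple(f"ddg_{t}" for t in DDG_TERMS)


def relax_feature_names() -> tuple[str, ...]:
    per_term = tuple(f"relax_{t}_{s}" for t in RELAX_TERMS for s in RELAX_STATS)
    totals = tuple(f"relax_total_score_{s}" for s in RELAX_TOTAL_STATS)
    return per_term + totals


def structure_feature_names() -> tuple[str, ...]:
    return ddg_feature_names() + relax_feature_names() + (SURFACE_FEATURE,)


def all_feature_names() -> tuple[str, ...]:
    return SEQUENCE_FEATURES + structure_feature_names()


N_SEQUENCE_FEATURES = len(SEQUENCE_FEATURES)          # 5
N_DDG_FEATURES = len(ddg_feature_names())             # 17
N_RELAX_FEATURES = len(relax_feature_names())         # 83
N_STRUCTURE_FEATURES = N_DDG_FEATURES + N_RELAX_FEATURES + 1  # 101
N_FEATURES = N_SEQUENCE_FEATURES + N_STRUCTURE_FEATURES       # 106

assert N_RELAX_FEATURES == 83 and N_FEATURES == 106

# ---------------------------------------------------------------------------
# Physical-interpretation category table (score term -> category)
# ---------------------------------------------------------------------------

CATEGORY_OF_TERM = {
    "hbond_sr_bb": "hydrogen bonding",
    "hbond_lr_bb": "hydrogen bonding",
    "hbond_bb_sc": "hydrogen bonding",
    "hbond_sc": "hydrogen bonding",
    "fa_rep": "packing",
    "fa_atr": "packing",
    "fa_intra_rep": "packing",
    "fa_dun": "packing",
    "dslf_fa13": "disulfide",
    "rama": "backbone",
    "omega": "backbone",
    "pro_close": "backbone",
    "p_aa_pp": "backbone",
    "yhh_planarity": "backbone",
    "chainbreak": "backbone",
    "fa_sol": "solvation",
    "fa_elec": "electrostatics",
    "ref": "global",
    "atom_pair_constraint": "global",
    "total_score": "global",
}

CATEGORIES = (
    "hydrogen bonding", "packing", "disulfide", "backbone",
    "solvation", "electrostatics", "surface", "global",
)

# ---------------------------------------------------------------------------
# Numerical / protocol defaults
# ---------------------------------------------------------------------------

#: Decoys averaged per side for the ddG block (lowest total_score first).
DDG_BEST_K = 3

#: Cap for the normalized shift when the native ensemble has zero spread.
ZERO_SPREAD_SENTINEL = 10.0

#: Default refinement-ensemble size per side.
DEFAULT_RELAX_DECOYS = 50

# Stability selection
N_RESAMPLES = 100
SUBSAMPLE_FRAC = 0.8
LAMBDA_GRID = tuple(np.logspace(-2.0, 2.0, 25))
FREQ_THRESHOLD = 0.6
MAX_SELECTED = 20

#: Candidates correlating above this with an already-selected feature are
#: dropped from the stability-selection ranking (non-redundancy filter).
REDUNDANCY_R = 0.95

#: Inverse ridge strength of the final (post-selection) fit.
FINAL_FIT_C = 100.0

# Evaluation
N_SPLITS = 100
TRAIN_FRAC = 0.8
AVERAGE_GRID_POINTS = 101
DECISION_THRESHOLD = 0.5

#: A physical category is reported when its summed deleterious-direction
#: contribution exceeds this fraction of the total absolute structure
#: contribution.
INTERPRETATION_THRESHOLD = 0.10

#: Profile-search invocation recorded for provenance (run externally).
PSIBLAST_DEFAULTS = {"iterations": 2, "pseudocount": 2, "database": "nr"}
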
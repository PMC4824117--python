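"""The five sequence-profile features of a variant.

From the position-specific scoring matrix (PSSM) of the protein we take the
log-odds of the native and variant amino acids at the variant position
(``pssm_nat``, ``pssm_mut``), their difference (``pssm_diff``), the
position's information content in bits (``info_cont``), and a coarse
chemical-change ordinal (``aminochange``).  No normalization is applied at
this stage; standardization happens inside the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import AA_CLASS_OF, STANDARD_AAS
from .formats_io import SequenceProfile, ValidationError, VariantSpec

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SeqFeatureSet:
    pssm_nat: float
    pssm_mut: float
    pssm_diff: float
    info_cont: float
    aminochange: int

    def as_dict(self) -> dict[str, float]:
        return {
            "pssm_nat": self.pssm_nat,
            "pssm_mut": self.pssm_mut,
            "pssm_diff": self.pssm_diff,
            "info_cont": self.info_cont,
            "aminochange": float(self.aminochange),
        }


def aminochange(native_aa: str, variant_aa: str) -> int:
    """Broad chemical difference between two amino acids.

    0 — same chemical class (nonpolar / polar-uncharged / positive /
    negative); 1 — different classes without a charge-sign flip; 2 —
    oppositely charged.  Symmetric in its arguments.
    """
    for aa in (native_aa, variant_aa):
        if aa not in STANDARD_AAS:
            raise ValidationError(f"non-standard amino acid {aa!r}")
    a, b = AA_CLASS_OF[native_aa], AA_CLASS_OF[variant_aa]
    if a == b:
        return 0
    if {a, b} == {"positive", "negative"}:
        return 2
    return 1


def compute_sequence_features(profile: SequenceProfile,
                              variant: VariantSpec) -> SeqFeatureSet:
    """Look up the five sequence features for ``variant`` in ``profile``.

    The variant position must lie within the profile; a native amino acid
    that disagrees with the profile sequence is reported as a warning and
    the profile's values are used as-is (wrong-isoform tolerance).
    """
    if not 1 <= variant.position <= len(profile):
        raise IndexError(
            f"position {variant.position} outside profile of length {len(profile)}"
        )
    profile_aa = profile.sequence[variant.position - 1]
    if profile_aa != variant.native_aa:
        logger.warning(
            "%s %s: profile has %s at position %d; proceeding with profile values",
            variant.protein_id, variant.name, profile_aa, variant.position,
        )
    nat = float(profile.log_odds_of(variant.position, variant.native_aa))
    mut = float(profile.log_odds_of(variant.position, variant.variant_aa))
    return SeqFeatureSet(
        pssm_nat=nat,
        pssm_mut=mut,
        pssm_diff=nat - mut,
        info_cont=float(profile.info_content[variant.position - 1]),
        aminochange=aminochange(variant.native_aa, variant.variant_aa),
    )
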
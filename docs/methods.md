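# Methods

## Problem and model

`strudel` classifies missense protein variants as **deleterious** (directly
disrupting protein molecular function — stability, active site, interface or
folding) or **neutral**, and explains *why* a deleterious call was made in
physical terms. The deleterious label is protein-centred: it is not a claim of
disease pathogenicity.

Each variant is represented by a fixed, named vector of 106 features:

| block | count | source |
|---|---|---|
| sequence profile | 5 | PSSM from an iterative profile search |
| fast stability estimate (ddG) | 17 | per-term score deltas, native vs variant |
| refinement ensemble (relax) | 83 | ensemble statistics per score term |
| surface accessibility | 1 | per-residue accessible-surface table |

The classifier is a logistic regression over a stability-selected subset of at
most 20 standardized features:

    P(deleterious | x) = sigmoid( b + sum_i w_i * (x_i - c_i) / s_i )

with centres `c` and scales `s` learned on training data only. Scores strictly
above 0.5 are labelled deleterious; exactly 0.5 is neutral (strict threshold).

## Sequence features

From the variant position's PSSM row we take `pssm_nat` and `pssm_mut` (the
log-odds of the native and variant amino acid), their difference
`pssm_diff = pssm_nat − pssm_mut` (the canonical profile substitution
statistic), and `info_cont`, the position's information content in bits.
`aminochange` is a coarse ordinal of chemical change: 0 within a class
(nonpolar {A,V,L,I,M,F,W,P,G}, polar-uncharged {S,T,C,Y,N,Q}, positive
{K,R,H}, negative {D,E}), 1 across classes without a charge-sign flip, 2 for
oppositely charged classes. It is symmetric in its arguments by construction.
The profile-search invocation recorded in the configuration (2 iterations,
pseudocount 2) is executed externally; the package consumes its ASCII PSSM.

## Structure features and ensemble normalization

All structural signal is expressed relative to the refined ensemble of the
*native* protein:

    z = ( mean(variant values) − mean(native values) ) / sd(native values)

with the sample (ddof=1) standard deviation. This removes protein-specific
score offsets (translation invariance) and scales (scale equivariance). When
the native ensemble has zero spread the statistic is undefined; we return a
signed sentinel capped at ±10 so degenerate fixtures stay bounded.

**ddG block (17).** One normalized delta per term of a fixed 17-term manifest
(16 all-atom components + total). Each side is first reduced to its k=3
lowest-total-score decoys (standard averaging practice for this protocol;
configurable), while the native spread is taken from the full column.

**Relax block (83).** For each of 20 manifest terms, four ensemble
statistics: normalized mean shift, normalized minimum shift, the native
quantile of the variant mean (fraction of native decoys at or below it), and
the overlap fraction (variant decoys inside the native [min, max]). Three
whole-ensemble statistics on the total score complete the block: the sd
ratio, the native quantile of the variant minimum, and the fraction of native
decoys inside the variant range.

The exact term manifests are fixed in `strudel.config` and overridable; the
counts (17 / 83 / 106) are invariants checked at import. Default refinement
ensembles are 50 decoys per side — at that size the sampling error of a mean
shift is ≈ sqrt(2/50) ≈ 0.2 native sd.

**Missing structure.** A variant that cannot be placed on a model is *never*
imputed: its 101 structure entries are NaN-marked and it is routed to the
sequence-only classifier and flagged in the output. A model residue whose
identity contradicts the variant's native amino acid is a distinct *mismatch*
condition (wrong model or isoform): the structure is distrusted, the variant
is scored sequence-only, and the event is logged as an error and summarized,
so the variant still appears exactly once in the output.

## Variant-to-model mapping

Structural models are standardized to a single protein chain (requested, else
alphabetically first), dropping heteroatoms, waters, metals and non-standard
residues (dropped, not translated). Reference-to-model numbering is
reconciled by ungapped sliding-window alignment of the model's residue
sequence against the reference, taking the placement with the most
identities (left-most on ties). Gapped or multi-segment models would need a
gapped aligner; that is a known limitation.

## Stability selection and training

Feature selection fits an L1-penalized logistic regression on 100 random
subsamples of 80% of the *proteins* (never splitting a protein's variants)
across a 25-point logarithmic penalty grid (λ from 0.01 to 100). A feature's
score is the maximum over the grid of its selection frequency; features above
0.6 are ranked by frequency and truncated to 20. Because the L1 optimum is
indifferent to how weight splits across near-duplicate columns, the ranked
list is filtered greedily: a candidate correlating above |r| = 0.95 with an
already-kept feature is dropped ("non-redundant" selection). All selection
hyperparameters are configuration-exposed.

The final fit is a lightly ridge-regularized (C = 100) logistic regression on
the standardized selected features; the light ridge stabilizes collinear
score terms without materially biasing the weights (verified against a direct
numerical minimizer of the same objective). Class imbalance is deliberately
not reweighted — the training composition (≈1.54 deleterious:neutral) is part
of the study conditions. Selection runs once on the full training data;
per-split fits then re-learn weights and standardization on the training fold
only. Training is deterministic given data and seed, and invariant to record
order.

Three modes share the machinery: `combined` (selected features),
`sequence_only` (the 5 profile features) and `structure_only` (the 101
structure features). Per-gene isoform predictions are aggregated by maximum
score (ties to the lexicographically first isoform ID): any deleterious
isoform is treated as evidence of deleteriousness.

## Interpretation

Each structure feature maps to exactly one physical category — hydrogen
bonding (hbond terms), packing (fa_rep, fa_atr, fa_intra_rep, fa_dun),
disulfide (dslf terms), backbone (rama, omega, pro_close, p_aa_pp,
yhh_planarity, chainbreak), solvation (fa_sol), electrostatics (fa_elec),
surface (the accessibility feature) and global (reference energies,
constraints, totals). The table is total over the shipped manifest (checked
at startup). A prediction's per-feature contribution terms (weight ×
standardized value) are summed per category; categories whose
deleterious-direction sum exceeds 10% of the total absolute structure
contribution (configurable) are reported in a deterministic one-sentence
narrative. Attribution is conservative: category sums add up exactly to the
total structure contribution. Sequence-only predictions yield a reduced,
conservation-only statement, since no physical evidence exists to cite.

## Evaluation machinery

Train/test splits are drawn over proteins (default 100 splits, 80/20).
AUROC is integrated by trapezoid over the tie-grouped threshold sweep, which
makes it exactly the Mann–Whitney concordance probability (asserted against a
brute-force pairwise oracle). AUPR integrates the step-wise *precision
envelope* over recall — no linear interpolation between PR points — so AUPR
comparisons within the package are self-consistent; the PR curve starts at
(0, 1) by convention and its precision at recall 1 equals prevalence.
Curves are averaged vertically on a fixed 101-point sweep grid; averaged
areas are the means of member areas by definition.

Score-bin enrichment compares two score sets (e.g. proband vs unaffected
sibling de-novo mutations) in 10 equal-width bins on [0, 1]: per-bin count
ratios against the background |A|/|B|, with Spearman and Pearson correlations
of ratio vs bin midpoint. Empty-denominator bins are NaN-flagged and excluded
from the correlations (they carry no rank information), never zero-filled.
Correlation p-values are two-sided permutation tests: exact enumeration up to
8 defined bins, a seeded 20,000-draw Monte-Carlo approximation for 9–12 bins
(full enumeration beyond 8 points is combinatorially out of reach), and the
asymptotic approximation above that. Rank correlation is computed as the
Pearson correlation of rank-transformed values, which commutes with
permutation and lets all permutations be evaluated in one matrix product.

## Synthetic data: what it does and does not show

The generators produce every input dialect the parsers consume (ASCII PSSM,
score files in both dialects, surface tables, variant tables, stub CA-trace
models), so fixtures exercise the real parsing path. Labeled datasets plant
class-conditional mean shifts in named features over i.i.d. Gaussian noise,
grouped into proteins (default 200 proteins × 3–7 variants, deleterious
fraction 0.606 echoing the 5,740/9,477 composition of curated training
collections). Gaussian noise matches the normalized-feature space, not raw
score distributions.

What passing tests show: the selection/training/evaluation stack recovers
planted signal, ranks held-out synthetic variants (AUROC ≥ 0.9 at effect 2.0
on 3 of 106 features), and the combined mode out-ranks sequence-only when
signal is structural. What they do not show: performance on real variants,
where features are correlated, effects heterogeneous, and labels noisy.
Real-data accuracy requires the external profile search, refinement and
surface tools this package deliberately consumes rather than reimplements.

## Numerical choices and degenerate inputs

- Zero native spread → ±10 sentinel (0 if the means also agree).
- Normalized shifts are clipped to ±10 throughout, keeping features bounded.
- Score exactly 0.5 → neutral (strict "above 0.5" rule).
- Prediction logits are clamped to ±500 before the sigmoid.
- Isoform score ties → lexicographically first isoform.
- Standardization scales of constant columns are set to 1 to avoid division
  by zero.
- Single-class subsamples during stability selection are skipped (the
  frequency denominator counts effective resamples); fully single-class data
  is an error.

## Problem sizes

Default desk-scale conditions: 200 proteins × 5 variants (≈1,000 records) for
recovery runs, 50-decoy ensembles, 100 selection resamples × 25 penalties,
5-fold split evaluation in the acceptance script. These sizes make a full
selection-plus-evaluation cycle take on the order of a minute on one core
while leaving planted-signal recovery far from its detection threshold.

## Known limitations

- Ungapped model-to-reference alignment; no mmCIF input; no multi-chain
  complexes, ligand/nucleic-acid-aware scoring, or membrane proteins.
- The feature manifests fix one defensible choice of score terms; a different
  refinement protocol version would need an overridden manifest.
- The amino-acid class table behind `aminochange` is one standard 4-class
  partition; alternatives (e.g. splitting aromatics) would shift the ordinal
  for a few pairs.
- Multi-residue substitutions are out of scope.
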
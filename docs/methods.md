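# Methods

## The recognition model

The model scores a single amino-acid substitution presented on one MHC
allele. Inputs are the 9-mer binding cores of the wild-type and mutant
peptides (class-II 15-mers are reduced to the 9-mer core reported by the
binding predictor, with the mutant's register imposed on the wild-type so
the pair differs at ≤ 1 core position) and the allele's binding motif — an
L×20 matrix of position-specific amino-acid frequencies over binding cores
of peptides passing the class %rank threshold (2 for MHC-I, 10 for MHC-II).
No pseudocounts are added to motif frequencies; rows may contain exact
zeros.

Forward pass, with all dimensions deliberately tiny (d_a = d_p = 2, K = 8,
L = 9, scale-net hidden width 8):

1. each one-hot residue row (or motif frequency row) is multiplied by
   BLOSUM62 and mapped by a shared affine layer to d_a dimensions;
2. K learnable d_a×d_a kernels are modulated by the motif embedding
   (C_k = E_motif W_k); the position-wise dot product of C_k with the
   peptide embedding gives K responses per position, projected to d_p;
3. learnable per-position weights (separate for MHC-I and MHC-II,
   initialized to 1/L, unnormalized — reported position factors are
   normalized only for display) pool positions into peptide vectors;
4. the pair is summarized geometrically: origin = v^WT, direction =
   (v^MT − v^WT)/(d + ε) with ε = 1e-8, distance d = ‖v^MT − v^WT‖₂;
5. CRD = d · σ(f_scale([origin; direction])) where f_scale is a two-layer
   tanh network, so 0 ≤ CRD ≤ d always, with CRD = 0 for self-pairs;
6. the immunogenicity probability is σ(w₁·CRD + w₂·b + b₀) where
   b = 1 − min(rank, R)/R is a bounded binding-strength covariate
   (R = 2 or 10 by class). The raw %rank encoding is deliberately avoided:
   b lives in [0, 1] with 1 = strongest binding, so the classifier weight
   on binding is directly interpretable.

Component scores expose the incremental structure: SubDist (residue-
embedding distance at the mutated position), SubPosDist (with position
weighting), GeoDist (= d, adding motif enrichment), CRD (adding the sigmoid
scale). For a Hamming-1 pair, SubPosDist = |w_p|·SubDist at the mutated
position p.

### Training

Stage 1 minimizes the triplet loss max(0, CRD(a, p) − CRD(a, n) + margin)
with margin 1 over curated triplets (seed a, cross-reactive p,
non-cross-reactive n on the same allele): cross-reactive pairs mimic
tolerated (non-immunogenic) substitutions and are pulled together;
negatives are pushed apart. Stage 2 minimizes binary cross-entropy on
labeled WT/MT epitopes, updating only the scale net and the output
classifier; every upstream tensor is frozen and the implementation asserts
bit-for-bit equality after training. Both stages run 100 epochs of AdamW at
learning rate 0.005 (the published settings are stated for fine-tuning;
they are applied to both stages). Batches are full-batch up to 4,096
samples, else shuffled mini-batches of 512. Stage 2 keeps the epoch with
the lowest validation loss.

Because no autodiff framework is available in the target environment, the
network is implemented in numpy with hand-derived gradients. The backward
pass is validated against central finite differences (agreement ~1e-10) and
the vectorized forward pass against a loop-based oracle (1e-10 over 1,000
random instances). At d = 0 the distance is non-differentiable; the
subgradient 0 is used for the path through v^MT − v^WT (stage-1 anchors
and positives always differ, so this case does not arise in training).

### Dataset curation

Triplets: TCR–pMHC binding records (CDR3β, peptide, allele) are
deduplicated, filtered to binders at the class rank threshold, grouped by
(allele, CDR3β), and singleton groups dropped. All ordered within-group
pairs at Hamming distance exactly 1 become cross-reactive pairs (ordered,
because the geometric representation is asymmetric in WT/MT). For each
pair, up to 10 negatives are sampled uniformly without replacement from all
single-substitution variants of the seed — at any position — whose
substitution has a strictly negative BLOSUM62 score and which are outside
the seed's cross-reactive set (the union of its groups' peptides). The
BLOSUM62 constraint is a hard filter, not a sampling weight. Every emitted
triplet passes an independent validator.

Labeled epitopes: WT/MT pairs with mismatched lengths or non-canonical
residues are dropped; the MT peptide (the presented neoantigen) must pass
the class rank filter. Splits are 75/10/15, stratified by label, with
rounding carried across strata so global sizes match the fractions.

## Mutation- and tumor-level layers

PHBR is the harmonic mean of per-allele best binding ranks across the HLA
genotype (homozygous alleles counted per genotype copy). Robustness counts
binding alleles at the class threshold. Agretopicity is the MT/WT
binding-score ratio on the best-binding allele (a `rank` basis,
wt_rank/mt_rank, is available because some predictors report scores on
scales where ratios are not meaningful). Expression quartiles use the
right-closed per-patient ECDF (ties share a quartile; the maximum is always
quartile 4), making them invariant under monotone transforms of TPM.

Recognition scores are aggregated across a genotype's alleles by one of
five reducers (mean, harmonic mean, binding-score-weighted average, best
binding, maximum), optionally masked to alleles binding at the class
threshold. The default is the masked maximum. An empty survivor set yields
(0, not presented): a mutation no allele presents cannot be recognized.

The integrated model is a standardized logistic regression over features
selected by recursive elimination: one feature (smallest standardized
|coefficient|) is dropped per step, each visited subset is scored by
4-fold cross-validated AUROC, and exactly five features are retained.
Standardization constants come from the training set and are reused at
prediction time.

Landscape scores (all reported as log10(1 + x); the +1 keeps empty tumors
at 0): the plain sum of per-mutation MHC-dual scores (product of the MHC-I
and MHC-II probabilities by default; sum and max are available); the
CCF-weighted sum; and the clone-aware score, where per-cluster MHC-I and
MHC-II sums are integrated per cluster and averaged across clusters
weighted by prevalence (normalizing by the prevalence total — prevalences
are not assumed to sum to 1). Mutations without a cluster fall into a
singleton pseudo-cluster at their own CCF, with a warning.

Burdens: TMB (all mutations), TNB (PHBR-I ≤ 2), NPB (MHC-I × MHC-II
probability ≥ 0.16, the square of the ~0.4 per-class median score).
Inequality directions follow the published forms exactly: q(i) < c and
L_j/S_j < e strict; PHBR ≤ 2, CCF ≥ 0.85 and dual ≥ 0.16 non-strict.

CSiN averages, over rank cutoffs {0.375, 0.5, 0.625, 0.75, 1.25, 1.75, 2},
the log of the mean normalized VAF × neoantigen-load product over mutations
whose best pMHC rank is below the cutoff; means are taken over the
cutoff-included set. Mutations with VAF < 0.05 are excluded and at most the
500 highest-VAF mutations are kept. The outer log is natural — both
conventions give 0 on a homogeneous landscape, and no absolute CSiN values
are compared externally. Cutoffs with no qualifying mutation are skipped
and the divisor reduced.

ioTNL sums L_j × CCF_j over clusters whose elimination score L_j/S_j is
below e = 1.4, where L_j counts class-I pMHC pairs at rank ≤ 2 within the
cluster and S_j is the cluster's mutation count.

Heterogeneity: the Gini index Σᵢⱼ|xᵢ − xⱼ|/(2n Σxᵢ) of cluster sizes
(sGini) and prevalences (pGini); patients at or below both cohort medians
are heterogeneous, above both homogeneous, otherwise mixed (mixed patients
are excluded from two-group comparisons). A single patient cannot be
classified (medians undefined).

## Interpretation

A substitution matrix (BLOSUM62 from biopython; a PMBEC-style matrix may be
supplied as a TSV — its values are not redistributable here) is reduced to
2-D residue coordinates by PCA with a deterministic sign convention
(largest-magnitude loading positive per component). Motif enrichment at a
core position is summarized by the least-squares affine map E_m ≈ A E_r + t
from the model's 20-residue embedding to its motif-enriched counterpart;
the SVD A = UΣVᵀ gives per-axis scaling factors S_x = |V₁ₓσ₁| + |V₂ₓσ₂|
(and analogously S_y), reading V's columns as the right singular vectors —
validated by the diag(3, 2) → (3, 2) oracle. The allele benefit score is
the mean over the nine positions of √(S_x S_y); patient scores are
geometric means over the genotype per class, their geometric mean (dual),
and the product with log10(TMB + 1). σ₁ = σ₂ ties make V non-unique; the
solver's deterministic decomposition is used and interpretation relies on
matrices with distinct singular values. Rank-deficient point clouds are a
declared degenerate fit (factors reported as 0 in the per-allele sweep).

## Synthetic world

The generators state a small but structured world; their defaults are fixed
design choices, not tuning dials:

- **Alleles**: 3 MHC-I + 2 MHC-II PWMs; anchor positions (2, 9 for class I;
  1, 4, 6, 9 for class II) are sharpened Dirichlet rows (exponent 8),
  non-anchors mildly concentrated (1.5). The mock predictor scores the best
  9-mer window by PWM likelihood and calibrates %rank on a fixed seeded
  background of 5,000 random peptides.
- **TCR binding tables**: 60 groups (20% class II), each a binder seed plus
  1 + Poisson(1.2) conservative variants (BLOSUM62-positive substitutions at
  non-anchor positions that keep the peptide binding in the same register).
  The ordered Hamming-1 pairs within groups are the planted cross-reactive
  truth.
- **Labeled epitopes**: binder WT, random single substitution, MT
  re-filtered for binding. P(immunogenic) = σ(β·(D − med D) + γ·(b − med b))
  with β = γ = 1, where D is the BLOSUM62-PCA distance between the
  exchanged residues — deliberately *not* the model's own embedding, so
  recovery tests are not circular — and b the MT binding strength. The
  median-centering keeps prevalence near 0.5 at any effect size while the
  β = γ = 0 null still gives exactly 0.5.
- **Cohorts**: 60 patients; 1–6 clusters each with a clonal cluster at
  prevalence 1 and Beta(2, 4) subclones; cluster sizes 1 + negative
  binomial (mean ≈ 8, dispersion 3); CCF = cluster prevalence;
  VAF = 0.5 × prevalence × purity (0.7) with multiplicative 2·Beta(20, 20)
  noise. The fraction of presented (binder) mutations is drawn per patient
  from Beta(2, 2) around the cohort mean 0.5 — patients genuinely differ in
  presentation capacity, which is what decouples the immunogenicity
  landscape from raw mutation count; with a constant fraction the landscape
  sum is a monotone function of TMB and a planted landscape-driven response
  would be unidentifiable. Response labels are logistic in the standardized
  landscape sum (effect 2.0).

What a green synthetic test does not establish: the generators have no
mutational signatures, no immunoediting dynamics, no linkage between the
class-I and class-II peptides of a mutation, no allele frequency spectrum
resembling human populations, and PWM-likelihood binding rather than a real
predictor. Green tests certify the mathematics and the pipeline contracts,
not biological accuracy on real cohorts.

## Numerical choices and limitations

- ε = 1e-8 in the direction normalization; direction is the zero vector for
  self-pairs.
- Motif frequencies carry no pseudocounts; an allele with zero binders in
  the peptidome sample is a declared failure (callers may relax the
  threshold).
- The PWM mock floors weights at 1e-6 before taking logs, bounding window
  scores away from −∞ and keeping likelihood ratios finite.
- Best-binding aggregation breaks rank ties by lexicographic allele name.
- Agretopicity floors the WT score at 1e-9; a doubly-zero score pair
  reports 1 with a warning.
- Indels and frameshifts are out of scope (a defined WT peptide is
  required), as are class-II flanking-region effects and foreignness
  computation (an optional pass-through column).
- Training is CPU-only and deterministic for a fixed seed on one machine;
  exact bit-reproducibility across BLAS builds is not guaranteed.
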
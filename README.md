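# neoprecis

Neoantigen immunogenicity scoring and clonality-aware tumor landscape
analysis for cancer immunogenomics.

Somatic missense mutations create mutant peptides (neoantigens) that T
cells can recognize when an MHC molecule presents them. Whether a given
substitution is immunogenic depends on more than MHC binding: T-cell
receptors (TCRs) are cross-reactive, and a mutant peptide too similar to
its wild-type counterpart is usually invisible to the repertoire because
self-reactive T cells are deleted during thymic selection. This package
implements, for bioinformaticians working on neoantigen prioritization and
immunotherapy-response biomarkers:

- **A T-cell recognition model** scoring wild-type/mutant 9-mer binding-core
  pairs. One-hot residues are mapped through BLOSUM62 into a learned 2-D
  embedding, enriched position-wise by the allele's binding motif
  (an L×20 position-specific frequency matrix) through K = 8 motif-modulated
  kernels, and pooled with learnable position weights into peptide vectors
  v^WT, v^MT. The geometric representation (origin v^WT, normalized
  direction, distance d = ‖v^MT − v^WT‖₂) yields the cross-reactivity
  distance CRD = d·σ(f_scale([origin; direction])), and the immunogenicity
  probability is σ(W·[CRD; binding] + b). Training is two-stage:
  contrastive triplet loss max(0, CRD(a,p) − CRD(a,n) + 1) on cross-reactive
  peptide triplets, then binary cross-entropy fine-tuning on T-cell assay
  labels with all upstream layers frozen.
- **Dataset curation**: cross-reactive triplets from TCR–pMHC binding tables
  (grouping by MHC allele and CDR3β, Hamming-distance-1 pairs, negatives
  with negative BLOSUM62 substitution scores), and labeled WT/MT epitope
  tables with binding-rank filtering and stratified splits.
- **Mutation-centric metrics**: PHBR (harmonic mean of per-allele best
  binding ranks across the HLA genotype), binding robustness, agretopicity,
  expression quartiles, masked-maximum aggregation of recognition scores
  across alleles, and an RFE-selected standardized logistic model
  integrating abundance, presentation and recognition.
- **Tumor-centric landscapes**: TMB/TNB/NPB burdens; log-scaled landscape
  scores (plain sum, CCF-weighted, and clone-aware with per-cluster
  MHC-I × MHC-II integration weighted by clone prevalence); the CSiN and
  ioTNL clonality-aware benchmarks; Gini-index tumor heterogeneity
  classification; and model-interpretation tools (PCA residue embeddings,
  affine/SVD scaling factors, allele and patient benefit scores).
- **Synthetic data generators** for every input (PWM alleles, TCR binding
  tables with planted cross-reactive structure, labeled epitopes with
  logistic ground truth, cohorts with clonal architecture), so the whole
  pipeline is testable without external data or predictors.

A pluggable predictor interface stands in for MHC binding tools (e.g.
NetMHCpan): bring your own predictions as a TSV, or use the built-in
deterministic PWM mock.

## Worked example

```python
from neoprecis.synthetic_data import SyntheticConfig, gen_alleles_and_motifs, gen_tcr_binding_table
from neoprecis.triplet_curation import make_triplets
from neoprecis.immuno_model import (ImmunoModelParams, TrainConfig, train_stage1,
                                    component_scores, predict, binding_covariate)
from neoprecis.core_motifs import make_core_pair

config = SyntheticConfig(seed=0)
world = gen_alleles_and_motifs(config)
records, _ = gen_tcr_binding_table(config, world)
triplets = make_triplets(records, world.predictor, seed=0)
params, history = train_stage1(
    triplets, world.motifs, ImmunoModelParams.initialize(seed=0),
    TrainConfig(epochs=40, seed=0), predictor=world.predictor,
)
print(f"trained on {len(triplets)} triplets; loss {history[0]:.3f} -> {history[-1]:.3f}")

allele = world.alleles("I")[0]
wt, mt = "KLVALGINA", "KLVALGWNA"
pair, pred = make_core_pair(wt, mt, allele, world.predictor)
scores = component_scores(pair, world.motifs[allele], params)
trace = predict(pair, world.motifs[allele], binding_covariate(pred, "I"), params)
print(f"{wt} -> {mt} on {allele}:")
for k, v in scores.items():
    print(f"  {k:10s} {v:.4f}")
print(f"  {'probability':10s} {trace.probability:.4f}")
```

prints

```
trained on 2860 triplets; loss 0.999 -> 0.289
KLVALGINA -> KLVALGWNA on HLA-A*01:01:
  SubDist    3.4767
  SubPosDist 0.4189
  GeoDist    1.2636
  CRD        1.1201
  probability 0.4708
```

`SubDist` is the raw residue-embedding distance of the I→W substitution;
`SubPosDist` weights it by the learned importance of core position 7;
`GeoDist` is the full motif-enriched geometric distance; `CRD` scales it by
the sequence-context factor (always ≤ GeoDist). The probability combines
CRD with the mutant peptide's binding strength — here an intermediate
value, reflecting a chemically drastic substitution at a position of
moderate learned weight.

## Command line

```sh
neoprecis synth binding --out binding.tsv --seed 1
neoprecis make-triplets --binding binding.tsv --out triplets.tsv --seed 1
neoprecis train --stage 1 --triplets triplets.tsv --checkpoint-out model.npz
neoprecis score-peptides --peptides pairs.tsv --model model.npz --out scores.tsv
neoprecis landscape --mutations scored_mutations.tsv --out landscape.tsv
neoprecis run --out-dir results/   # full synthetic end-to-end pipeline
```

All tables are TSV with a one-line `#schema=` header; thresholds live in a
single `RunConfig` (YAML-overridable via `--config`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computation from scratch — synthetic world,
triplet curation, both training stages, cohort scoring and the per-patient
landscape table — and writes the JSON report to `--out`.
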
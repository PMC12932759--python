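"""Synthetic generators for every input the framework consumes.

The generated world is deliberately simple but structured: alleles are
sharp position-weight matrices with designated anchor positions; TCR
binding tables contain groups of binder peptides related by conservative
(BLOSUM62-positive) single substitutions, which constitute the planted
cross-reactive pairs; labeled WT/MT epitopes carry labels drawn from a
logistic model over a model-independent ground-truth distance (the
BLOSUM62-PCA residue distance at the substituted position, so recovery
tests cannot be circular); and cohorts have a clonal cluster at prevalence
1 plus Beta-distributed subclones, negative-binomial cluster sizes, and
VAF = 0.5 x prevalence x purity with Beta noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._aa import AA_ORDER, N_AA, blosum62_score, hamming
from .core_motifs import (
    CORE_LENGTH,
    PEPTIDE_LENGTHS,
    RANK_THRESHOLDS,
    BindingMotif,
    PWMPredictor,
)
from .immuno_model import ImmunoModelParams, binding_covariate
from .interpretation import pca_embedding, substitution_pca_distance
from ._aa import blosum62_matrix
from .landscape import CloneCluster, TumorProfile
from .mutation_metrics import (
    AggregationConfig,
    MutationRecord,
    expression_quartile,
    score_mutation_class,
)

ANCHOR_POSITIONS = {"I": (2, 9), "II": (1, 4, 6, 9)}


@dataclass
class SyntheticConfig:
    """Stated world for all generators. Defaults are chosen once to mimic a
    small but realistic setting (see the methods note) and are not tuned."""

    n_alleles_i: int = 3
    n_alleles_ii: int = 2
    anchor_sharpness: float = 8.0
    background_sharpness: float = 1.5
    n_tcr_groups: int = 60
    frac_class_ii: float = 0.2
    group_size_mean: float = 1.2  # extra members beyond the seed (Poisson)
    n_epitopes: int = 300
    label_beta: float = 1.0      # effect of true substitution distance
    label_gamma: float = 1.0     # effect of binding strength
    n_patients: int = 60
    max_clusters: int = 6
    mutations_per_cluster: float = 8.0  # negative binomial mean
    nb_dispersion: float = 3.0
    purity: float = 0.7
    binder_fraction: float = 0.5       # cohort mean fraction of presented mutations
    binder_concentration: float = 4.0  # Beta concentration of per-patient fractions
    response_effect: float = 2.0  # logistic effect of NP-Sum on response
    seed: int = 0


@dataclass
class SyntheticWorld:
    pwms: dict[str, np.ndarray]
    classes: dict[str, str]
    predictor: PWMPredictor
    motifs: dict[str, BindingMotif]

    def alleles(self, mhc_class: str) -> list[str]:
        return sorted(a for a, c in self.classes.items() if c == mhc_class)


def _pwm_row(rng: np.random.Generator, sharpness: float) -> np.ndarray:
    if np.isinf(sharpness):
        row = np.zeros(N_AA)
        row[rng.integers(N_AA)] = 1.0
        return row
    base = rng.dirichlet(np.ones(N_AA))
    row = base**sharpness
    return row / row.sum()


def gen_alleles_and_motifs(config: SyntheticConfig, seed: int | None = None) -> SyntheticWorld:
    """Per-allele sharp PWMs with designated anchor positions, a calibrated
    mock predictor over them, and the matching binding motifs."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pwms: dict[str, np.ndarray] = {}
    classes: dict[str, str] = {}
    for cls, n in (("I", config.n_alleles_i), ("II", config.n_alleles_ii)):
        for k in range(n):
            allele = f"HLA-{'A' if cls == 'I' else 'DRB1'}*{k + 1:02d}:01"
            pwm = np.stack([
                _pwm_row(
                    rng,
                    config.anchor_sharpness
                    if (i + 1) in ANCHOR_POSITIONS[cls]
                    else config.background_sharpness,
                )
                for i in range(CORE_LENGTH)
            ])
            pwms[allele] = pwm
            classes[allele] = cls
    predictor = PWMPredictor(pwms, classes)
    motifs = {
        allele: BindingMotif(allele=allele, mhc_class=classes[allele],
                             matrix=pwm, n_source_peptides=0)
        for allele, pwm in pwms.items()
    }
    return SyntheticWorld(pwms=pwms, classes=classes, predictor=predictor, motifs=motifs)


def sample_binder(
    world: SyntheticWorld,
    allele: str,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> str:
    """Draw a peptide from the allele's PWM until it passes the class rank
    threshold (class-II binders get random flanks around the 9-mer core)."""
    cls = world.classes[allele]
    threshold = RANK_THRESHOLDS[cls]
    length = PEPTIDE_LENGTHS[cls]
    pwm = world.pwms[allele]
    for _ in range(max_tries):
        core = "".join(
            AA_ORDER[rng.choice(N_AA, p=pwm[i] / pwm[i].sum())]
            for i in range(CORE_LENGTH)
        )
        if length == CORE_LENGTH:
            pep = core
        else:
            n_flank = length - CORE_LENGTH
            left = rng.integers(0, n_flank + 1)
            flanks = "".join(AA_ORDER[j] for j in rng.integers(0, N_AA, n_flank))
            pep = flanks[:left] + core + flanks[left:]
        if world.predictor.predict(pep, allele).rank_percentile <= threshold:
            return pep
    raise RuntimeError(f"could not sample a binder for {allele}")


def _conservative_variant(
    peptide: str,
    world: SyntheticWorld,
    allele: str,
    rng: np.random.Generator,
    core_start: int,
    max_tries: int = 100,
) -> str | None:
    """Single BLOSUM62-positive substitution that keeps the peptide binding."""
    cls = world.classes[allele]
    threshold = RANK_THRESHOLDS[cls]
    anchors = {core_start + p - 1 for p in ANCHOR_POSITIONS[cls]}
    positions = [i for i in range(core_start, core_start + CORE_LENGTH) if i not in anchors]
    for _ in range(max_tries):
        pos = positions[rng.integers(len(positions))]
        res = peptide[pos]
        options = [a for a in AA_ORDER if a != res and blosum62_score(res, a) > 0]
        if not options:
            continue
        sub = options[rng.integers(len(options))]
        cand = peptide[:pos] + sub + peptide[pos + 1 :]
        pred = world.predictor.predict(cand, allele)
        if pred.rank_percentile <= threshold and pred.core_start == core_start:
            return cand
    return None


def gen_tcr_binding_table(
    config: SyntheticConfig,
    world: SyntheticWorld,
    seed: int | None = None,
):
    """TCR-pMHC binding records with known cross-reactive structure.

    Returns (records, planted_pairs) where planted_pairs is the set of
    ordered Hamming-1 (seed, variant, allele) tuples constructed within
    groups — the ground truth that pair extraction should recover.
    """
    from .triplet_curation import TCRBindingRecord

    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    records: list[TCRBindingRecord] = []
    planted: set[tuple[str, str, str]] = set()
    for g in range(config.n_tcr_groups):
        cls = "II" if rng.random() < config.frac_class_ii else "I"
        alleles = world.alleles(cls)
        if not alleles:
            continue
        allele = alleles[rng.integers(len(alleles))]
        cdr3 = "CASS" + "".join(AA_ORDER[j] for j in rng.integers(0, N_AA, 8)) + "F"
        seed_pep = sample_binder(world, allele, rng)
        core_start = world.predictor.predict(seed_pep, allele).core_start
        members = {seed_pep}
        n_extra = 1 + rng.poisson(config.group_size_mean)
        for _ in range(n_extra):
            var = _conservative_variant(seed_pep, world, allele, rng, core_start)
            if var is not None:
                members.add(var)
        for pep in sorted(members):
            records.append(TCRBindingRecord(cdr3, pep, allele, cls))
        for a in members:
            for b in members:
                if a != b and hamming(a, b) == 1:
                    planted.add((a, b, allele))
    return records, planted


def gen_labeled_epitopes(
    config: SyntheticConfig,
    world: SyntheticWorld,
    seed: int | None = None,
):
    """Labeled WT/MT epitopes with logistic ground truth.

    P(immunogenic) = sigmoid(beta (D - median D) + gamma (b - median b))
    where D is the BLOSUM62-PCA distance between the substituted residues
    and b the bounded binding strength of the MT peptide; centering on the
    batch medians keeps prevalence near 0.5 at any effect size. Returns
    (epitopes, truth) with per-sample D, b and P recorded.
    """
    from .triplet_curation import LabeledEpitope

    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    emb = pca_embedding(blosum62_matrix())
    rows = []
    for _ in range(config.n_epitopes):
        cls = "II" if rng.random() < config.frac_class_ii else "I"
        alleles = world.alleles(cls)
        allele = alleles[rng.integers(len(alleles))]
        threshold = RANK_THRESHOLDS[cls]
        for _ in range(100):
            wt = sample_binder(world, allele, rng)
            pos = int(rng.integers(len(wt)))
            sub = AA_ORDER[rng.integers(N_AA)]
            if sub == wt[pos]:
                continue
            mt = wt[:pos] + sub + wt[pos + 1 :]
            pred = world.predictor.predict(mt, allele)
            if pred.rank_percentile <= threshold:
                break
        else:
            continue
        dist = substitution_pca_distance(wt[pos], sub, emb)
        strength = binding_covariate(pred, cls)
        rows.append((wt, mt, allele, cls, dist, strength))
    dists = np.array([r[4] for r in rows])
    strengths = np.array([r[5] for r in rows])
    logits = config.label_beta * (dists - np.median(dists)) + config.label_gamma * (
        strengths - np.median(strengths)
    )
    probs = 1.0 / (1.0 + np.exp(-logits))
    labels = (rng.random(len(rows)) < probs).astype(int)
    epitopes = [
        LabeledEpitope(wt, mt, allele, cls, label=int(lab))
        for (wt, mt, allele, cls, _, _), lab in zip(rows, labels)
    ]
    truth = {
        "true_distance": dists,
        "binding_strength": strengths,
        "probability": probs,
    }
    return epitopes, truth


def _random_nonbinder_pair(world, alleles, cls, rng):
    """WT/MT peptides not constrained to bind (background mutations)."""
    length = PEPTIDE_LENGTHS[cls]
    wt = "".join(AA_ORDER[j] for j in rng.integers(0, N_AA, length))
    pos = int(rng.integers(length))
    choices = [a for a in AA_ORDER if a != wt[pos]]
    mt = wt[:pos] + choices[rng.integers(len(choices))] + wt[pos + 1 :]
    return wt, mt


def gen_cohort(
    config: SyntheticConfig,
    world: SyntheticWorld,
    params: ImmunoModelParams | None = None,
    seed: int | None = None,
):
    """Tumor cohort with known clonal architecture and planted response.

    Each patient receives a clonal cluster at prevalence 1.0 plus Beta(2,4)
    subclones, negative-binomial cluster sizes, per-mutation CCF equal to
    cluster prevalence, and VAF = 0.5 x prevalence x purity with Beta
    multiplicative noise. The fraction of presented (binder) mutations
    varies between patients (Beta around the configured mean), emulating
    genotype-dependent presentation capacity; this decouples the
    immunogenicity landscape from raw mutation count. Response labels are
    drawn from a logistic model on the standardized NP-Sum landscape score.

    Returns (profiles, responses, truth).
    """
    from .landscape import landscape_sum

    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    params = params or ImmunoModelParams.initialize(seed=config.seed)
    agg = AggregationConfig()
    profiles: list[TumorProfile] = []
    for p in range(config.n_patients):
        hla_i = list(rng.choice(world.alleles("I"), size=min(3, config.n_alleles_i), replace=False))
        hla_ii = list(rng.choice(world.alleles("II"), size=min(2, config.n_alleles_ii), replace=False))
        binder_frac = float(rng.beta(
            config.binder_fraction * config.binder_concentration,
            (1.0 - config.binder_fraction) * config.binder_concentration,
        ))
        n_clusters = int(rng.integers(1, config.max_clusters + 1))
        prevalences = [1.0] + [float(rng.beta(2, 4)) for _ in range(n_clusters - 1)]
        clusters, mutations = [], []
        tpms: dict[str, float] = {}
        mut_idx = 0
        for j, prev in enumerate(prevalences):
            cid = f"c{j}"
            n_mut = 1 + rng.negative_binomial(
                config.nb_dispersion,
                config.nb_dispersion / (config.nb_dispersion + config.mutations_per_cluster - 1),
            )
            member_ids = set()
            for _ in range(n_mut):
                mid = f"P{p}_m{mut_idx}"
                mut_idx += 1
                member_ids.add(mid)
                gene = f"GENE{mut_idx}"
                tpm = float(rng.lognormal(2.0, 1.5))
                tpms[gene] = tpm
                is_binder = rng.random() < binder_frac
                if is_binder:
                    allele_i = hla_i[rng.integers(len(hla_i))]
                    mt_i = sample_binder(world, allele_i, rng)
                    pos = int(rng.integers(CORE_LENGTH))
                    choices = [a for a in AA_ORDER if a != mt_i[pos]]
                    wt_i = mt_i[:pos] + choices[rng.integers(len(choices))] + mt_i[pos + 1 :]
                    allele_ii = hla_ii[rng.integers(len(hla_ii))]
                    mt_ii = sample_binder(world, allele_ii, rng)
                    pos = int(rng.integers(len(mt_ii)))
                    choices = [a for a in AA_ORDER if a != mt_ii[pos]]
                    wt_ii = mt_ii[:pos] + choices[rng.integers(len(choices))] + mt_ii[pos + 1 :]
                else:
                    wt_i, mt_i = _random_nonbinder_pair(world, hla_i, "I", rng)
                    wt_ii, mt_ii = _random_nonbinder_pair(world, hla_ii, "II", rng)
                m_i = score_mutation_class(wt_i, mt_i, hla_i, world.predictor,
                                           world.motifs, params, "I", agg)
                m_ii = score_mutation_class(wt_ii, mt_ii, hla_ii, world.predictor,
                                            world.motifs, params, "II", agg)
                noise = rng.beta(20, 20) * 2.0  # mean 1 multiplicative noise
                vaf = float(np.clip(0.5 * prev * config.purity * noise, 0.0, 1.0))
                mutations.append(MutationRecord(
                    mutation_id=mid, gene=gene,
                    wt_peptide_i=wt_i, mt_peptide_i=mt_i,
                    wt_peptide_ii=wt_ii, mt_peptide_ii=mt_ii,
                    dna_af=vaf,
                    rna_af=float(np.clip(vaf * rng.beta(20, 20) * 2.0, 0.0, 1.0)),
                    tpm=tpm,
                    rank_per_allele_i=m_i["rank_per_allele"],
                    rank_per_allele_ii=m_ii["rank_per_allele"],
                    score_per_allele_i=m_i["score_per_allele"],
                    score_per_allele_ii=m_ii["score_per_allele"],
                    phbr_i=m_i["phbr"], phbr_ii=m_ii["phbr"],
                    robustness_i=m_i["robustness"], robustness_ii=m_ii["robustness"],
                    agretopicity=m_i["agretopicity"],
                    np_immuno_i=0.0 if np.isnan(m_i["np_immuno"]) else m_i["np_immuno"],
                    np_immuno_ii=0.0 if np.isnan(m_ii["np_immuno"]) else m_ii["np_immuno"],
                    pmhc_ranks=(list(m_i["rank_per_allele"].values())
                                + list(m_ii["rank_per_allele"].values())),
                    ccf=prev, cluster_id=cid,
                ))
            clusters.append(CloneCluster(cluster_id=cid, prevalence=prev,
                                         mutation_ids=member_ids))
        quartiles = expression_quartile(tpms)
        for m in mutations:
            m.expr_quartile = quartiles[m.gene]
        profiles.append(TumorProfile(
            patient_id=f"P{p}", hla_i=hla_i, hla_ii=hla_ii,
            mutations=mutations, clusters=clusters, purity=config.purity,
        ))
    np_sums = np.array([landscape_sum(pr) for pr in profiles])
    z = (np_sums - np_sums.mean()) / (np_sums.std() or 1.0)
    probs = 1.0 / (1.0 + np.exp(-config.response_effect * z))
    responses = (rng.random(len(profiles)) < probs).astype(int)
    truth = {"np_sum": np_sums, "response_probability": probs}
    return profiles, responses, truth
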
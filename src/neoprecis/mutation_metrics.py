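"""Mutation-centric immunogenicity metrics and the integrated model.

Each somatic missense mutation is characterized along three dimensions:
abundance (DNA/RNA allele fractions and per-patient expression quartile),
MHC presentation (PHBR — the harmonic mean of per-allele best binding ranks
across the HLA genotype — and robustness, the number of binding alleles),
and T-cell recognition (the immunogenicity model's probability, the
agretopicity ratio, and an optional externally computed foreignness
pass-through). Recognition scores are aggregated across a genotype's
alleles; the default is the masked maximum (best score among alleles that
bind at the class rank threshold). The integrated model is a standardized
logistic regression over features chosen by recursive feature elimination
scored with cross-validated AUROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .core_motifs import RANK_THRESHOLDS

logger = logging.getLogger(__name__)

AGGREGATION_METHODS = ("mean", "harmonic_mean", "weighted_average", "best_binding", "maximum")

DEFAULT_FEATURES = {
    "I": ["dna_af", "rna_af", "expr_quartile", "phbr_i", "np_immuno_i"],
    "II": ["dna_af", "rna_af", "expr_quartile", "phbr_ii", "np_immuno_ii"],
}


@dataclass
class MutationRecord:
    """One somatic missense mutation with its metric annotations."""

    mutation_id: str
    gene: str = ""
    wt_peptide_i: str = ""
    mt_peptide_i: str = ""
    wt_peptide_ii: str = ""
    mt_peptide_ii: str = ""
    dna_af: float = np.nan
    rna_af: float = np.nan
    tpm: float = np.nan
    expr_quartile: int = 0
    rank_per_allele_i: dict = field(default_factory=dict)
    rank_per_allele_ii: dict = field(default_factory=dict)
    score_per_allele_i: dict = field(default_factory=dict)
    score_per_allele_ii: dict = field(default_factory=dict)
    phbr_i: float = np.nan
    phbr_ii: float = np.nan
    robustness_i: int = 0
    robustness_ii: int = 0
    agretopicity: float = np.nan
    foreignness: float | None = None
    np_immuno_i: float = np.nan
    np_immuno_ii: float = np.nan
    pmhc_ranks: list = field(default_factory=list)
    ccf: float = np.nan
    cluster_id: str | None = None

    @property
    def np_dual(self) -> float:
        return self.np_immuno_i * self.np_immuno_ii


@dataclass
class AggregationConfig:
    method: str = "maximum"
    masked: bool = True
    rank_thresholds: dict = field(default_factory=lambda: dict(RANK_THRESHOLDS))

    def __post_init__(self):
        if self.method not in AGGREGATION_METHODS:
            raise ValueError(f"method must be one of {AGGREGATION_METHODS}")


def phbr(best_rank_per_allele: dict[str, float] | list[float]) -> float:
    """Patient harmonic-mean best rank: n / sum(1/rank). Homozygous alleles
    are counted once per genotype copy (pass a list with repeats)."""
    ranks = (list(best_rank_per_allele.values())
             if isinstance(best_rank_per_allele, dict) else list(best_rank_per_allele))
    if not ranks:
        raise ValueError("PHBR requires at least one allele rank")
    ranks = np.asarray(ranks, dtype=float)
    if np.any(ranks <= 0):
        raise ValueError("all ranks must be > 0")
    return float(len(ranks) / np.sum(1.0 / ranks))


def robustness(best_rank_per_allele: dict[str, float] | list[float], threshold: float) -> int:
    """Number of binding alleles (rank <= threshold)."""
    ranks = (list(best_rank_per_allele.values())
             if isinstance(best_rank_per_allele, dict) else list(best_rank_per_allele))
    return int(sum(r <= threshold for r in ranks))


def agretopicity(mt_score: float, wt_score: float, eps: float = 1e-9) -> float:
    """Ratio of MT to WT binding scores (higher = stronger differential
    presentation of the mutant). A zero WT score is floored at ``eps``;
    if both scores are zero the ratio is reported as 1 with a warning."""
    if mt_score < 0 or wt_score < 0:
        raise ValueError("binding scores must be >= 0")
    if mt_score == 0 and wt_score == 0:
        logger.warning("both binding scores are zero; agretopicity reported as 1")
        return 1.0
    return float(mt_score / max(wt_score, eps))


def expression_quartile(tpm_by_gene: dict[str, float]) -> dict[str, int]:
    """Per-patient quartile transformation of TPM values.

    Quartile = ceil(4 * F(x)) with F the right-closed empirical CDF, so ties
    share the quartile of their common ECDF value and the maximum always
    lands in quartile 4. Invariant under monotone transforms of TPM.
    """
    genes = list(tpm_by_gene)
    values = np.array([tpm_by_gene[g] for g in genes], dtype=float)
    if len(genes) < 4:
        logger.warning("fewer than 4 genes; quartiles assigned from available ranks")
    n = len(values)
    ecdf = np.array([np.sum(values <= v) / n for v in values])
    quart = np.minimum(4, np.ceil(4 * ecdf)).astype(int)
    quart = np.maximum(quart, 1)
    return dict(zip(genes, quart.tolist()))


def aggregate_alleles(
    score_per_allele: dict[str, float],
    rank_per_allele: dict[str, float],
    config: AggregationConfig,
    mhc_class: str = "I",
) -> tuple[float, bool]:
    """Aggregate per-allele recognition scores into one mutation-level score.

    With masking, only alleles binding at the class rank threshold survive;
    an empty survivor set yields (0.0, False) — an unpresented mutation
    cannot be recognized. ``best_binding`` takes the score of the
    minimum-rank allele (ties broken by allele name); ``weighted_average``
    weights scores by binding score.
    """
    if set(score_per_allele) != set(rank_per_allele):
        raise ValueError("score and rank maps must share allele keys")
    if not score_per_allele:
        raise ValueError("empty allele map")
    threshold = config.rank_thresholds[mhc_class]
    alleles = sorted(score_per_allele)
    if config.masked:
        survivors = [a for a in alleles if rank_per_allele[a] <= threshold]
    else:
        survivors = alleles
    presented = any(rank_per_allele[a] <= threshold for a in alleles)
    if not survivors:
        return 0.0, False
    scores = np.array([score_per_allele[a] for a in survivors], dtype=float)
    if config.method == "mean":
        value = scores.mean()
    elif config.method == "harmonic_mean":
        value = len(scores) / np.sum(1.0 / (scores + 1e-9))
    elif config.method == "weighted_average":
        weights = scores.copy()
        total = weights.sum()
        value = scores.mean() if total == 0 else float(np.sum(weights * scores) / total)
    elif config.method == "best_binding":
        best = min(survivors, key=lambda a: (rank_per_allele[a], a))
        value = score_per_allele[best]
    else:  # maximum
        value = scores.max()
    return float(value), presented


@dataclass
class IntegratedModel:
    """Standardized logistic regression over RFE-selected features."""

    selected_features: list[str]
    means: np.ndarray
    sds: np.ndarray
    coefficients: np.ndarray
    intercept: float
    elimination_path: list[tuple[int, float]] = field(default_factory=list)


def _cv_auroc(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LogisticRegression(max_iter=1000)
    return float(np.mean(cross_val_score(model, X, y, cv=cv, scoring="roc_auc")))


def fit_integrated(
    features: pd.DataFrame,
    labels: np.ndarray,
    retain: int = 5,
    folds: int = 4,
    seed: int = 0,
) -> IntegratedModel:
    """Recursive feature elimination scored by cross-validated AUROC, then a
    standardized logistic regression on the retained features.

    One feature (the smallest standardized |coefficient|) is dropped per
    step until ``retain`` remain; the CV AUROC of every visited subset is
    recorded in ``elimination_path``. Constant features are dropped up
    front with a warning. Standardization constants come from the training
    data and are reused at predict time.
    """
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain two classes")
    if features.isna().any().any():
        raise ValueError("feature table contains missing values; impute first")
    work = features.copy()
    for col in list(work.columns):
        if work[col].std(ddof=0) == 0:
            logger.warning("constant feature %s dropped before fitting", col)
            work = work.drop(columns=col)
    current = list(work.columns)
    if retain > len(current):
        raise ValueError(f"cannot retain {retain} of {len(current)} features")

    def standardized(cols):
        X = work[cols].to_numpy(dtype=float)
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        return (X - mu) / sd, mu, sd

    path = []
    while True:
        X, _, _ = standardized(current)
        path.append((len(current), _cv_auroc(X, labels, folds, seed)))
        if len(current) <= retain:
            break
        model = LogisticRegression(max_iter=1000).fit(X, labels)
        weakest = current[int(np.argmin(np.abs(model.coef_[0])))]
        current = [c for c in current if c != weakest]

    X, mu, sd = standardized(current)
    final = LogisticRegression(max_iter=1000).fit(X, labels)
    return IntegratedModel(
        selected_features=current,
        means=mu,
        sds=sd,
        coefficients=final.coef_[0],
        intercept=float(final.intercept_[0]),
        elimination_path=path,
    )


def predict_integrated(model: IntegratedModel, features: pd.DataFrame) -> np.ndarray:
    """Per-mutation probability sigmoid(beta . z + beta0) with z standardized
    by the stored training constants."""
    missing = [c for c in model.selected_features if c not in features.columns]
    if missing:
        raise KeyError(f"missing selected features: {missing}")
    X = features[model.selected_features].to_numpy(dtype=float)
    z = (X - model.means) / model.sds
    logit = z @ model.coefficients + model.intercept
    return 1.0 / (1.0 + np.exp(-logit))


# --- end-to-end scoring of one mutation -----------------------------------

def score_mutation_class(
    wt_peptide: str,
    mt_peptide: str,
    alleles: list[str],
    predictor,
    motifs: dict,
    params,
    mhc_class: str,
    aggregation: AggregationConfig | None = None,
    agretopicity_basis: str = "score",
) -> dict:
    """Per-class presentation and recognition metrics for one mutation:
    per-allele best ranks/scores, PHBR, robustness, aggregated
    immunogenicity probability, and the MT/WT agretopicity on the
    best-binding allele (binding-score ratio by default; ``rank`` uses
    wt_rank / mt_rank instead)."""
    from .core_motifs import UnsupportedAlleleError, make_core_pair
    from .immuno_model import binding_covariate
    from .immuno_model import predict as model_predict

    aggregation = aggregation or AggregationConfig()
    ranks: dict[str, float] = {}
    scores: dict[str, float] = {}
    probs: dict[str, float] = {}
    wt_scores: dict[str, float] = {}
    wt_ranks: dict[str, float] = {}
    for allele in alleles:
        try:
            pair, pred = make_core_pair(wt_peptide, mt_peptide, allele, predictor)
            wt_pred = predictor.predict(wt_peptide, allele)
        except UnsupportedAlleleError:
            logger.warning("allele %s unsupported; skipped", allele)
            continue
        ranks[allele] = pred.rank_percentile
        scores[allele] = pred.binding_score
        wt_scores[allele] = wt_pred.binding_score
        wt_ranks[allele] = wt_pred.rank_percentile
        motif = motifs.get(allele)
        if motif is not None and params is not None:
            trace = model_predict(pair, motif, binding_covariate(pred, mhc_class), params)
            probs[allele] = trace.probability
    if not ranks:
        raise ValueError("no supported allele for this mutation")
    threshold = RANK_THRESHOLDS[mhc_class]
    np_score, presented = (
        aggregate_alleles(probs, {a: ranks[a] for a in probs}, aggregation, mhc_class)
        if probs else (np.nan, False)
    )
    best = min(ranks, key=lambda a: (ranks[a], a))
    if agretopicity_basis == "rank":
        agre = wt_ranks[best] / ranks[best]
    else:
        agre = agretopicity(scores[best], wt_scores[best])
    return {
        "rank_per_allele": ranks,
        "score_per_allele": scores,
        "phbr": phbr(ranks),
        "robustness": robustness(ranks, threshold),
        "np_immuno": np_score,
        "presented": presented,
        "agretopicity": agre,
    }
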
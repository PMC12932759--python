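"""Patient-level neoantigen burdens, tumor-centric landscape scores,
clonality-aware benchmark scores (CSiN, ioTNL) and Gini-based tumor
heterogeneity classification.

Landscape scores aggregate per-mutation immunogenicity into one number per
tumor: a plain sum, a cancer-cell-fraction weighted sum, or a clone-wise
aggregate where per-cluster MHC-I and MHC-II sums are integrated
(multiplication by default) and averaged across clusters weighted by
cluster prevalence. All three are reported as log10(1 + x).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .interpretation import BenefitScores
from .mutation_metrics import MutationRecord

logger = logging.getLogger(__name__)

DUAL_METHODS = ("product", "sum", "max")
CSIN_CUTOFFS = (0.375, 0.5, 0.625, 0.75, 1.25, 1.75, 2.0)


@dataclass
class CloneCluster:
    cluster_id: str
    prevalence: float
    mutation_ids: set = field(default_factory=set)

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("cluster prevalence must be within [0, 1]")

    @property
    def size(self) -> int:
        return len(self.mutation_ids)


@dataclass
class TumorProfile:
    patient_id: str
    hla_i: list[str]
    hla_ii: list[str]
    mutations: list[MutationRecord]
    clusters: list[CloneCluster] = field(default_factory=list)
    purity: float = 1.0

    def __post_init__(self):
        if not self.hla_i or not self.hla_ii:
            raise ValueError("HLA allele lists must be non-empty")
        known = {c.cluster_id for c in self.clusters}
        for m in self.mutations:
            if m.cluster_id is not None and m.cluster_id not in known:
                raise ValueError(f"mutation {m.mutation_id} references unknown cluster {m.cluster_id}")


@dataclass
class LandscapeResult:
    patient_id: str
    tmb: int
    tnb: int
    npb: int
    np_sum: float
    np_ccf: float
    np_clone: float
    csin: float
    iotnl: float
    s_gini: float
    p_gini: float
    pct_clonal: float
    pct_binding_i: float
    heterogeneity_class: str = ""
    benefit: BenefitScores | None = None


def dual_score(np_i: float, np_ii: float, method: str = "product") -> float:
    """Integrate MHC-I and MHC-II immunogenicity scores for one mutation."""
    if method not in DUAL_METHODS:
        raise ValueError(f"method must be one of {DUAL_METHODS}")
    if method == "product":
        return float(np_i * np_ii)
    if method == "sum":
        return float(np_i + np_ii)
    return float(max(np_i, np_ii))


def mutation_burdens(
    profile: TumorProfile,
    phbr_threshold: float = 2.0,
    npb_threshold: float = 0.16,
) -> tuple[int, int, int]:
    """(TMB, TNB, NPB): total mutations; mutations binding MHC-I
    (PHBR <= 2); mutations whose MHC-I x MHC-II immunogenicity product
    passes the dual threshold (0.16 = 0.4^2, the squared per-class median
    immunogenicity)."""
    tmb = len(profile.mutations)
    tnb = sum(1 for m in profile.mutations if m.phbr_i <= phbr_threshold)
    npb = sum(1 for m in profile.mutations if m.np_dual >= npb_threshold)
    return tmb, tnb, npb


def _scored(mutations: list[MutationRecord], method: str) -> list[tuple[MutationRecord, float]]:
    out = []
    for m in mutations:
        if np.isnan(m.np_immuno_i) or np.isnan(m.np_immuno_ii):
            logger.warning("mutation %s lacks immunogenicity scores; skipped", m.mutation_id)
            continue
        out.append((m, dual_score(m.np_immuno_i, m.np_immuno_ii, method)))
    return out


def landscape_sum(profile: TumorProfile, integration: str = "product") -> float:
    """log10(1 + sum of per-mutation dual scores)."""
    total = sum(s for _, s in _scored(profile.mutations, integration))
    return float(np.log10(1.0 + total))


def landscape_ccf(profile: TumorProfile, integration: str = "product") -> float:
    """log10(1 + sum of CCF-weighted dual scores); mutations lacking a CCF
    are skipped with a warning."""
    total = 0.0
    for m, s in _scored(profile.mutations, integration):
        if np.isnan(m.ccf):
            logger.warning("mutation %s lacks CCF; skipped", m.mutation_id)
            continue
        total += m.ccf * s
    return float(np.log10(1.0 + total))


def landscape_clone(profile: TumorProfile, integration: str = "product") -> float:
    """Clone-aware landscape score.

    Within each cluster the MHC-I and MHC-II scores are summed separately,
    integrated (product by default), and the cluster scores are averaged
    weighted by cluster prevalence: log10(1 + sum_j prev_j C_j / sum_j prev_j).
    Mutations without a cluster assignment fall into a singleton
    pseudo-cluster whose prevalence is their own CCF.
    """
    sums: dict[str, tuple[float, float, float]] = {}
    for c in profile.clusters:
        sums[c.cluster_id] = (0.0, 0.0, c.prevalence)
    for m in profile.mutations:
        if np.isnan(m.np_immuno_i) or np.isnan(m.np_immuno_ii):
            continue
        cid = m.cluster_id
        if cid is None:
            cid = f"_singleton_{m.mutation_id}"
            prev = 0.0 if np.isnan(m.ccf) else m.ccf
            logger.warning(
                "mutation %s has no cluster; singleton pseudo-cluster (prevalence %.3f)",
                m.mutation_id, prev,
            )
            sums.setdefault(cid, (0.0, 0.0, prev))
        a, b, prev = sums[cid]
        sums[cid] = (a + m.np_immuno_i, b + m.np_immuno_ii, prev)
    total_prev = sum(prev for _, _, prev in sums.values())
    if total_prev == 0:
        logger.warning("total cluster prevalence is zero; clone landscape degenerate")
        return 0.0
    weighted = sum(prev * dual_score(a, b, integration) for a, b, prev in sums.values())
    return float(np.log10(1.0 + weighted / total_prev))


def csin(
    mutations: list[MutationRecord],
    cutoffs: tuple[float, ...] = CSIN_CUTOFFS,
    vaf_min: float = 0.05,
    max_mutations: int = 500,
) -> float:
    """Cauchy-Schwarz index of neoantigens.

    Per rank-percentile cutoff c, mutations whose best pMHC rank q(i) is
    strictly below c contribute (V_i / mean V)(L_i / mean L), where V_i is
    the VAF (DNA allele fraction) and L_i the number of pMHC pairs with
    rank < c; the cutoff term is the natural log of the mean contribution,
    and CSiN is the mean over cutoffs. Mutations with VAF < 0.05 are
    excluded and at most the 500 highest-VAF mutations are retained.
    Cutoffs with no qualifying mutation are skipped (divisor reduced).
    """
    kept = [m for m in mutations if not np.isnan(m.dna_af) and m.dna_af >= vaf_min and m.pmhc_ranks]
    kept.sort(key=lambda m: -m.dna_af)
    kept = kept[:max_mutations]
    if not kept:
        logger.warning("no mutations qualify for CSiN")
        return 0.0
    vafs = np.array([m.dna_af for m in kept])
    ranks = [np.asarray(m.pmhc_ranks, dtype=float) for m in kept]
    best = np.array([r.min() for r in ranks])
    terms = []
    for c in cutoffs:
        included = best < c
        if not included.any():
            logger.warning("CSiN cutoff %s has no qualifying mutation; skipped", c)
            continue
        V = vafs[included]
        Lc = np.array([np.sum(r < c) for r, inc in zip(ranks, included) if inc], dtype=float)
        contrib = (V / V.mean()) * (Lc / Lc.mean())
        terms.append(np.log(contrib.mean()))
    if not terms:
        return 0.0
    return float(np.mean(terms))


def iotnl(
    loads: list[float],
    sizes: list[int],
    ccfs: list[float],
    e: float = 1.4,
) -> float:
    """Immunoediting-optimized tumor neoantigen load.

    Sums L_j * CCF_j over clusters whose elimination score L_j / S_j is
    strictly below the cutoff e (L_j = cluster neoantigen load, S_j =
    cluster nonsynonymous mutation count). Clusters with S_j = 0 are
    skipped with a warning.
    """
    total = 0.0
    for L, S, ccf in zip(loads, sizes, ccfs, strict=True):
        if S <= 0:
            logger.warning("cluster with zero mutations skipped in ioTNL")
            continue
        if L / S < e:
            total += L * ccf
    return float(total)


def cluster_neoantigen_loads(
    profile: TumorProfile, rank_threshold: float = 2.0
) -> tuple[list[float], list[int], list[float]]:
    """(L_j, S_j, CCF_j) per cluster: L_j counts class-I pMHC pairs with
    rank <= 2 over member mutations, S_j is the cluster mutation count."""
    by_cluster = {c.cluster_id: c for c in profile.clusters}
    loads = {cid: 0.0 for cid in by_cluster}
    sizes = {cid: 0 for cid in by_cluster}
    for m in profile.mutations:
        if m.cluster_id is None or m.cluster_id not in by_cluster:
            continue
        sizes[m.cluster_id] += 1
        loads[m.cluster_id] += sum(
            1 for r in m.rank_per_allele_i.values() if r <= rank_threshold
        )
    ids = sorted(by_cluster)
    return (
        [loads[c] for c in ids],
        [sizes[c] for c in ids],
        [by_cluster[c].prevalence for c in ids],
    )


def gini(values) -> float:
    """Gini index of inequality: sum_ij |x_i - x_j| / (2 n sum_i x_i).

    0 means perfect equality; a single value gives 0. All-zero input is
    degenerate and returns 0 with a warning.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size == 0:
        raise ValueError("gini requires at least one value")
    if np.any(x < 0):
        raise ValueError("gini requires nonnegative values")
    total = x.sum()
    if total == 0:
        logger.warning("all-zero values; Gini index degenerate (0)")
        return 0.0
    diff = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff / (2 * x.size * total))


def tumor_gini(profile: TumorProfile) -> tuple[float, float]:
    """(sGini, pGini): Gini indices of cluster mutation counts and cluster
    prevalences."""
    if not profile.clusters:
        raise ValueError("profile has no clusters")
    sizes = [c.size if c.size else sum(1 for m in profile.mutations if m.cluster_id == c.cluster_id)
             for c in profile.clusters]
    prevalences = [c.prevalence for c in profile.clusters]
    return gini(sizes), gini(prevalences)


def heterogeneity_class(
    s_ginis: list[float], p_ginis: list[float]
) -> list[str]:
    """Quadrant classification against cohort medians: both indices <=
    median -> heterogeneous, both > median -> homogeneous, otherwise mixed.
    Requires >= 2 patients (cohort medians are undefined otherwise)."""
    if len(s_ginis) != len(p_ginis):
        raise ValueError("sGini and pGini lists must be matched")
    if len(s_ginis) < 2:
        raise ValueError("heterogeneity classification requires >= 2 patients")
    s_med, p_med = np.median(s_ginis), np.median(p_ginis)
    out = []
    for s, p in zip(s_ginis, p_ginis):
        if s <= s_med and p <= p_med:
            out.append("heterogeneous")
        elif s > s_med and p > p_med:
            out.append("homogeneous")
        else:
            out.append("mixed")
    return out


def clonality_summaries(
    profile: TumorProfile,
    ccf_clonal: float = 0.85,
    phbr_threshold: float = 2.0,
) -> tuple[float, float]:
    """(%ClonalMuts, %Binding-I): fraction of mutations with CCF >= 0.85 and
    fraction with PHBR-I <= 2, both clipped to [0, 1]."""
    if not profile.mutations:
        logger.warning("empty mutation list; clonality summaries are (0, 0)")
        return 0.0, 0.0
    n = len(profile.mutations)
    clonal = sum(1 for m in profile.mutations if not np.isnan(m.ccf) and m.ccf >= ccf_clonal)
    binding = sum(1 for m in profile.mutations if m.phbr_i <= phbr_threshold)
    return float(np.clip(clonal / n, 0, 1)), float(np.clip(binding / n, 0, 1))


def compute_landscape(
    profile: TumorProfile,
    integration: str = "product",
    csin_cutoffs: tuple[float, ...] = CSIN_CUTOFFS,
    iotnl_e: float = 1.4,
    benefit: BenefitScores | None = None,
) -> LandscapeResult:
    """All patient-level scores for one tumor profile."""
    tmb, tnb, npb = mutation_burdens(profile)
    s_g, p_g = tumor_gini(profile) if profile.clusters else (0.0, 0.0)
    loads, sizes, ccfs = cluster_neoantigen_loads(profile)
    pct_clonal, pct_binding = clonality_summaries(profile)
    return LandscapeResult(
        patient_id=profile.patient_id,
        tmb=tmb, tnb=tnb, npb=npb,
        np_sum=landscape_sum(profile, integration),
        np_ccf=landscape_ccf(profile, integration),
        np_clone=landscape_clone(profile, integration),
        csin=csin(profile.mutations, cutoffs=csin_cutoffs),
        iotnl=iotnl(loads, sizes, ccfs, e=iotnl_e),
        s_gini=s_g, p_gini=p_g,
        pct_clonal=pct_clonal, pct_binding_i=pct_binding,
        benefit=benefit,
    )
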
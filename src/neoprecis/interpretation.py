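"""Model interpretation: residue-embedding baselines, affine analysis of
motif enrichment, and allele/patient benefit scores.

A substitution matrix (BLOSUM62, or a user-supplied PMBEC-style matrix)
is reduced to a 2-D residue embedding by PCA. The trained model's own
residue embedding can be compared against its motif-enriched counterpart at
each core position through a least-squares affine fit E_m = A E_r + t;
singular-value decomposition of A yields per-axis scaling factors, whose
geometric mean averaged over the 9 core positions defines the allele
benefit score. Patient-level benefit scores are geometric means over the
HLA genotype, combined across MHC classes and with log-scaled tumor
mutation burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._aa import AA_ORDER, N_AA, blosum62_matrix, one_hot
from .core_motifs import CORE_LENGTH, BindingMotif
from .immuno_model import ImmunoModelParams, embed_residues, motif_enrich


class DegenerateFitError(ValueError):
    """The affine fit is underdetermined (rank-deficient point cloud)."""


@dataclass
class AffineFit:
    """Least-squares affine map E_m ~ A E_r + t (column-vector convention)."""

    A: np.ndarray
    t: np.ndarray
    residual: float


@dataclass(frozen=True)
class ScalingFactors:
    allele: str
    position: int
    s_x: float
    s_y: float

    def __post_init__(self):
        if self.s_x < 0 or self.s_y < 0:
            raise ValueError("scaling factors must be nonnegative")


@dataclass
class BenefitScores:
    per_allele_i: dict[str, float]
    per_allele_ii: dict[str, float]
    mhc_i: float
    mhc_ii: float
    dual: float
    combined: float


def pca_embedding(substitution_matrix: np.ndarray) -> np.ndarray:
    """Top-2 principal-component coordinates of a symmetric 20x20
    substitution matrix (each amino acid's substitution profile is one
    observation).

    Sign convention: within each component, the largest-magnitude loading is
    made positive, so the output is deterministic across eigensolvers.
    """
    mat = np.asarray(substitution_matrix, dtype=float)
    if mat.shape != (N_AA, N_AA):
        raise ValueError("substitution matrix must be 20x20")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("substitution matrix must be symmetric")
    centered = mat - mat.mean(axis=0)
    cov = centered.T @ centered / (N_AA - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:2]
    comps = eigvecs[:, order]
    for j in range(comps.shape[1]):
        if comps[np.argmax(np.abs(comps[:, j])), j] < 0:
            comps[:, j] = -comps[:, j]
    return centered @ comps


def substitution_pca_distance(a: str, b: str, embedding: np.ndarray) -> float:
    """Euclidean distance between two residues in a PCA embedding."""
    ia, ib = AA_ORDER.index(a), AA_ORDER.index(b)
    return float(np.linalg.norm(embedding[ia] - embedding[ib]))


def residue_embedding(params: ImmunoModelParams) -> np.ndarray:
    """The model's 20x2 residue embedding (one embedding per amino acid)."""
    return embed_residues(np.eye(N_AA), params)


def motif_enriched_residue_embedding(
    motif: BindingMotif, position: int, params: ImmunoModelParams
) -> np.ndarray:
    """20x2 motif-enriched coordinates of each residue at one core position
    (1-based). The enrichment is position-wise, so only the motif row at
    ``position`` matters."""
    if not 1 <= position <= CORE_LENGTH:
        raise ValueError("position must be in 1..9")
    E_motif = embed_residues(motif.matrix, params)
    E_res = residue_embedding(params)
    out = np.empty((N_AA, params.d_p))
    i = position - 1
    for r in range(N_AA):
        E_pep = np.zeros((CORE_LENGTH, params.d_a))
        E_pep[i] = E_res[r]
        out[r] = motif_enrich(E_pep, E_motif, params)[i]
    return out


def fit_affine(E_r: np.ndarray, E_m: np.ndarray) -> AffineFit:
    """Least-squares A, t minimizing ||E_m - (E_r A_row + t)||_F^2 over
    matched 20x2 point clouds; returned A uses the column-vector convention
    (E_m^T = A E_r^T + t)."""
    E_r, E_m = np.asarray(E_r, float), np.asarray(E_m, float)
    if E_r.shape != E_m.shape or E_r.ndim != 2:
        raise ValueError("point clouds must be matched 2-D matrices")
    centered = E_r - E_r.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < E_r.shape[1]:
        raise DegenerateFitError("source point cloud is rank-deficient")
    design = np.hstack([E_r, np.ones((len(E_r), 1))])
    coef, _, _, _ = np.linalg.lstsq(design, E_m, rcond=None)
    A_row, t = coef[:-1], coef[-1]
    residual = float(np.mean((E_m - design @ coef) ** 2))
    return AffineFit(A=A_row.T, t=t, residual=residual)


def scaling_factors(A: np.ndarray) -> tuple[float, float]:
    """Per-axis scaling of an affine map from the SVD A = U S V^T:
    S_x = |V[0,0] s1| + |V[0,1] s2|, S_y = |V[1,0] s1| + |V[1,1] s2|,
    where V's columns are the right singular vectors (s1 >= s2)."""
    A = np.asarray(A, dtype=float)
    if A.shape != (2, 2) or not np.all(np.isfinite(A)):
        raise ValueError("A must be a finite 2x2 matrix")
    _, sigma, Vt = np.linalg.svd(A)
    V = Vt.T
    s_x = abs(V[0, 0] * sigma[0]) + abs(V[0, 1] * sigma[1])
    s_y = abs(V[1, 0] * sigma[0]) + abs(V[1, 1] * sigma[1])
    return float(s_x), float(s_y)


def allele_scaling_factors(
    motif: BindingMotif, params: ImmunoModelParams
) -> list[ScalingFactors]:
    """Affine-fit scaling factors of motif enrichment at each core position,
    fit on the full 20-residue point cloud."""
    E_r = residue_embedding(params)
    out = []
    for position in range(1, CORE_LENGTH + 1):
        E_m = motif_enriched_residue_embedding(motif, position, params)
        try:
            fit = fit_affine(E_r, E_m)
            s_x, s_y = scaling_factors(fit.A)
        except DegenerateFitError:
            s_x = s_y = 0.0
        out.append(ScalingFactors(motif.allele, position, s_x, s_y))
    return out


def allele_benefit_score(factors: list[ScalingFactors]) -> float:
    """Mean over the 9 core positions of sqrt(S_x * S_y)."""
    if sorted(f.position for f in factors) != list(range(1, CORE_LENGTH + 1)):
        raise ValueError("exactly one ScalingFactors per position 1..9 required")
    return float(np.mean([np.sqrt(f.s_x * f.s_y) for f in factors]))


def _geometric_mean(values) -> float:
    values = np.asarray(list(values), dtype=float)
    if np.any(values <= 0):
        raise ValueError("benefit scores must be > 0 for the geometric mean")
    return float(np.exp(np.mean(np.log(values))))


def patient_benefit_scores(
    allele_scores_i: dict[str, float],
    allele_scores_ii: dict[str, float],
    tmb: float,
) -> BenefitScores:
    """Patient-level benefit scores: per-class geometric means over the HLA
    genotype, their geometric mean (dual), and the combination with
    log-scaled TMB (log10(TMB + 1); the +1 guards zero-mutation tumors)."""
    if not allele_scores_i or not allele_scores_ii:
        raise ValueError("at least one allele score per MHC class is required")
    if tmb < 0:
        raise ValueError("tmb must be >= 0")
    mhc_i = _geometric_mean(allele_scores_i.values())
    mhc_ii = _geometric_mean(allele_scores_ii.values())
    dual = float(np.sqrt(mhc_i * mhc_ii))
    return BenefitScores(
        per_allele_i=dict(allele_scores_i),
        per_allele_ii=dict(allele_scores_ii),
        mhc_i=mhc_i,
        mhc_ii=mhc_ii,
        dual=dual,
        combined=float(np.log10(tmb + 1.0) * dual),
    )
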
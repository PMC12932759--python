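"""The T-cell recognition network and its two-stage training.

Architecture (all tensors tiny; implemented in numpy with hand-derived
gradients, verified against finite differences in the test suite):

1. *Residue embedding*: one-hot peptide rows (and motif frequency rows) are
   multiplied by BLOSUM62 and mapped by a shared affine layer into a
   ``d_a = 2`` dimensional residue space.
2. *Motif enrichment*: ``K = 8`` learnable d_a x d_a kernels are modulated
   by the allele's motif embedding (C_k = E_motif W_k); each kernel response
   is the position-wise dot product of C_k with the peptide embedding, and
   the K responses are projected to ``d_p = 2`` per position.
3. *Position-weighted pooling*: a learnable weight per core position
   (separate for MHC-I and MHC-II) pools the L x d_p matrix to a peptide
   vector v.
4. *Geometric representation*: origin = v_WT, direction = normalized
   (v_MT - v_WT), distance d = ||v_MT - v_WT||.
5. *Cross-reactivity distance*: CRD = d * sigmoid(f_scale([origin; dir]))
   with a two-layer tanh scale net, so 0 <= CRD <= d.
6. *Immunogenicity*: probability = sigmoid(w . [CRD; binding] + b), where
   the binding covariate is 1 - min(rank, R)/R (R = 2 for MHC-I, 10 for
   MHC-II), a bounded binding-strength encoding.

Training stage 1 minimizes the triplet loss
max(0, CRD(anchor, cross-reactive) - CRD(anchor, negative) + margin) on the
cross-reactive triplet dataset; stage 2 fine-tunes only the scale net and
output classifier with binary cross-entropy on labeled WT/MT epitopes,
keeping every upstream tensor frozen bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._aa import blosum62_matrix, one_hot
from .core_motifs import (
    RANK_THRESHOLDS,
    BindingMotif,
    BindingPrediction,
    CorePeptidePair,
    CORE_LENGTH,
)

logger = logging.getLogger(__name__)

TENSOR_NAMES = (
    "embed_w", "embed_b", "conv", "proj", "pos_w_i", "pos_w_ii",
    "scale_w1", "scale_b1", "scale_w2", "scale_b2", "out_w", "out_b",
)
STAGE1_TRAINABLE = (
    "embed_w", "embed_b", "conv", "proj", "pos_w_i", "pos_w_ii",
    "scale_w1", "scale_b1", "scale_w2", "scale_b2",
)
STAGE2_TRAINABLE = ("scale_w1", "scale_b1", "scale_w2", "scale_b2", "out_w", "out_b")


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


@dataclass
class ImmunoModelParams:
    """All trainable tensors plus hyperparameters.

    Shapes: embed_w (20, d_a), embed_b (d_a,), conv (K, d_a, d_a),
    proj (d_p, K), pos_w_i / pos_w_ii (L,), scale_w1 (hidden, 2*d_p),
    scale_b1 (hidden,), scale_w2 (hidden,), scale_b2 scalar,
    out_w (2,), out_b scalar.
    """

    embed_w: np.ndarray
    embed_b: np.ndarray
    conv: np.ndarray
    proj: np.ndarray
    pos_w_i: np.ndarray
    pos_w_ii: np.ndarray
    scale_w1: np.ndarray
    scale_b1: np.ndarray
    scale_w2: np.ndarray
    scale_b2: float
    out_w: np.ndarray
    out_b: float
    d_a: int = 2
    d_p: int = 2
    K: int = 8
    L: int = CORE_LENGTH
    hidden: int = 8
    epsilon: float = 1e-8
    margin: float = 1.0

    @classmethod
    def initialize(cls, seed: int = 0, d_a: int = 2, d_p: int = 2, K: int = 8,
                   hidden: int = 8, init_scale: float = 0.1) -> "ImmunoModelParams":
        rng = np.random.default_rng(seed)
        L = CORE_LENGTH
        return cls(
            embed_w=rng.normal(0, init_scale, (20, d_a)),
            embed_b=rng.normal(0, init_scale, d_a),
            conv=rng.normal(0, init_scale, (K, d_a, d_a)),
            proj=rng.normal(0, init_scale, (d_p, K)),
            pos_w_i=np.full(L, 1.0 / L),
            pos_w_ii=np.full(L, 1.0 / L),
            scale_w1=rng.normal(0, init_scale, (hidden, 2 * d_p)),
            scale_b1=np.zeros(hidden),
            scale_w2=rng.normal(0, init_scale, hidden),
            scale_b2=0.0,
            out_w=rng.normal(0, init_scale, 2),
            out_b=0.0,
            d_a=d_a, d_p=d_p, K=K, hidden=hidden,
        )

    def pos_w(self, mhc_class: str) -> np.ndarray:
        return self.pos_w_i if mhc_class == "I" else self.pos_w_ii

    def tensors(self) -> dict[str, np.ndarray]:
        return {name: np.asarray(getattr(self, name), dtype=float) for name in TENSOR_NAMES}

    def set_tensor(self, name: str, value: np.ndarray) -> None:
        current = getattr(self, name)
        if np.isscalar(current) or np.ndim(current) == 0:
            setattr(self, name, float(value))
        else:
            setattr(self, name, np.asarray(value, dtype=float).reshape(np.shape(current)))

    def copy(self) -> "ImmunoModelParams":
        kw = {n: np.array(getattr(self, n), dtype=float, copy=True) for n in TENSOR_NAMES}
        kw["scale_b2"] = float(self.scale_b2)
        kw["out_b"] = float(self.out_b)
        return ImmunoModelParams(
            **kw, d_a=self.d_a, d_p=self.d_p, K=self.K, L=self.L,
            hidden=self.hidden, epsilon=self.epsilon, margin=self.margin,
        )

    def validate(self) -> None:
        for name, t in self.tensors().items():
            if not np.all(np.isfinite(t)):
                raise ValueError(f"non-finite values in parameter {name}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be > 0")

    # --- checkpoint I/O ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = {
            "schema": "neoprecis-immuno.v1",
            "d_a": self.d_a, "d_p": self.d_p, "K": self.K, "L": self.L,
            "hidden": self.hidden, "epsilon": self.epsilon, "margin": self.margin,
        }
        np.savez(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.tensors())

    @classmethod
    def load(cls, path: str | Path) -> "ImmunoModelParams":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            if meta.get("schema") != "neoprecis-immuno.v1":
                raise ValueError("unrecognized checkpoint schema")
            kw = {name: data[name] for name in TENSOR_NAMES}
        kw["scale_b2"] = float(kw["scale_b2"])
        kw["out_b"] = float(kw["out_b"])
        return cls(**kw, d_a=meta["d_a"], d_p=meta["d_p"], K=meta["K"], L=meta["L"],
                   hidden=meta["hidden"], epsilon=meta["epsilon"], margin=meta["margin"])


@dataclass
class ForwardTrace:
    """Intermediate quantities of one WT/MT forward pass."""

    E_wt: np.ndarray
    E_mt: np.ndarray
    E_motif: np.ndarray
    enriched_wt: np.ndarray
    enriched_mt: np.ndarray
    v_wt: np.ndarray
    v_mt: np.ndarray
    origin: np.ndarray
    direction: np.ndarray
    distance: float
    crd: float
    probability: float


def binding_covariate(prediction: BindingPrediction | float, mhc_class: str) -> float:
    """Bounded binding-strength encoding b = 1 - min(rank, R)/R in [0, 1]."""
    rank = prediction.rank_percentile if isinstance(prediction, BindingPrediction) else float(prediction)
    R = RANK_THRESHOLDS[mhc_class]
    return 1.0 - min(rank, R) / R


# --- elementary operations (exposed for unit testing) ---------------------

def embed_residues(rows: np.ndarray, params: ImmunoModelParams) -> np.ndarray:
    """Affine residue embedding of L x 20 rows (one-hot peptides or motif
    frequency rows): row_i -> (row_i . BLOSUM62) W + b."""
    rows = np.asarray(rows, dtype=float)
    if not np.all(np.isfinite(rows)):
        raise ValueError("non-finite embedding input")
    return rows @ blosum62_matrix() @ params.embed_w + params.embed_b


def motif_enrich(E_pep: np.ndarray, E_motif: np.ndarray, params: ImmunoModelParams) -> np.ndarray:
    """Motif-dependent convolution: H_k[i] = sum_d (E_motif W_k)[i,d] E_pep[i,d],
    projected from K kernel responses to d_p per position."""
    if E_pep.shape != E_motif.shape:
        raise ValueError("peptide and motif embeddings must share shape")
    C = np.einsum("ld,kde->lke", E_motif, params.conv)
    H = np.einsum("lke,le->lk", C, E_pep)
    return H @ params.proj.T


def pool_peptide(E_enriched: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Position-weighted pooling v = sum_i w_i E_enriched[i]."""
    return np.einsum("l,lp->p", np.asarray(weights, dtype=float), E_enriched)


def geometric_representation(
    v_wt: np.ndarray, v_mt: np.ndarray, epsilon: float = 1e-8
) -> tuple[np.ndarray, np.ndarray, float]:
    u = np.asarray(v_mt, dtype=float) - np.asarray(v_wt, dtype=float)
    d = float(np.linalg.norm(u))
    direction = u / (d + epsilon)
    return np.asarray(v_wt, dtype=float), direction, d


def scale_factor(origin: np.ndarray, direction: np.ndarray, params: ImmunoModelParams) -> float:
    x = np.concatenate([origin, direction])
    h = np.tanh(params.scale_w1 @ x + params.scale_b1)
    return float(params.scale_w2 @ h + params.scale_b2)


def crd(origin: np.ndarray, direction: np.ndarray, distance: float,
        params: ImmunoModelParams) -> float:
    """CRD = d * sigmoid(f_scale([origin; direction])); 0 <= CRD <= d."""
    s = scale_factor(origin, direction, params)
    return float(distance * sigmoid(s))


def predict(
    pair: CorePeptidePair,
    motif: BindingMotif,
    binding_cov: float,
    params: ImmunoModelParams,
) -> ForwardTrace:
    """Full forward pass for one WT/MT core pair on one allele."""
    if pair.allele != motif.allele or pair.mhc_class != motif.mhc_class:
        raise ValueError(
            f"pair allele {pair.allele}/{pair.mhc_class} does not match motif "
            f"{motif.allele}/{motif.mhc_class}"
        )
    E_wt = embed_residues(one_hot(pair.wt_core), params)
    E_mt = embed_residues(one_hot(pair.mt_core), params)
    E_motif = embed_residues(motif.matrix, params)
    enr_wt = motif_enrich(E_wt, E_motif, params)
    enr_mt = motif_enrich(E_mt, E_motif, params)
    w = params.pos_w(pair.mhc_class)
    v_wt, v_mt = pool_peptide(enr_wt, w), pool_peptide(enr_mt, w)
    origin, direction, d = geometric_representation(v_wt, v_mt, params.epsilon)
    c = crd(origin, direction, d, params)
    logit = params.out_w[0] * c + params.out_w[1] * binding_cov + params.out_b
    return ForwardTrace(
        E_wt=E_wt, E_mt=E_mt, E_motif=E_motif,
        enriched_wt=enr_wt, enriched_mt=enr_mt,
        v_wt=v_wt, v_mt=v_mt, origin=origin, direction=direction,
        distance=d, crd=c, probability=float(sigmoid(logit)),
    )


def component_scores(
    pair: CorePeptidePair, motif: BindingMotif, params: ImmunoModelParams
) -> dict[str, float]:
    """Incremental component scores: SubDist (residue-embedding distance at
    the mutated position), SubPosDist (position-weighted), GeoDist (full
    motif-enriched geometric distance) and CRD (sigmoid-scaled GeoDist)."""
    if pair.is_self_pair:
        return {"SubDist": 0.0, "SubPosDist": 0.0, "GeoDist": 0.0, "CRD": 0.0}
    E_wt = embed_residues(one_hot(pair.wt_core), params)
    E_mt = embed_residues(one_hot(pair.mt_core), params)
    p = pair.mutated_position - 1
    sub_dist = float(np.linalg.norm(E_wt[p] - E_mt[p]))
    w = params.pos_w(pair.mhc_class)
    sub_pos_dist = float(np.linalg.norm(pool_peptide(E_wt, w) - pool_peptide(E_mt, w)))
    trace = predict(pair, motif, 0.0, params)
    return {
        "SubDist": sub_dist,
        "SubPosDist": sub_pos_dist,
        "GeoDist": trace.distance,
        "CRD": trace.crd,
    }


# --- batched forward/backward --------------------------------------------

@dataclass
class _BatchCache:
    Z_wt: np.ndarray
    Z_mt: np.ndarray
    Z_motif: np.ndarray
    E_wt: np.ndarray
    E_mt: np.ndarray
    E_motif: np.ndarray
    C: np.ndarray
    H_wt: np.ndarray
    H_mt: np.ndarray
    enr_wt: np.ndarray
    enr_mt: np.ndarray
    v_wt: np.ndarray
    v_mt: np.ndarray
    u: np.ndarray
    d: np.ndarray
    direction: np.ndarray
    x: np.ndarray
    h: np.ndarray
    s: np.ndarray
    sig_s: np.ndarray
    crd: np.ndarray
    pos_key: str


def forward_batch(
    params: ImmunoModelParams,
    X_wt: np.ndarray,
    X_mt: np.ndarray,
    M: np.ndarray,
    mhc_class: str = "I",
) -> _BatchCache:
    """Vectorized CRD forward pass over N (WT, MT, motif) instances.

    X_wt, X_mt, M have shape (N, L, 20); rows of X are one-hot, rows of M
    are motif frequencies.
    """
    B = blosum62_matrix()
    Z_wt, Z_mt, Z_motif = X_wt @ B, X_mt @ B, M @ B
    E_wt = Z_wt @ params.embed_w + params.embed_b
    E_mt = Z_mt @ params.embed_w + params.embed_b
    E_motif = Z_motif @ params.embed_w + params.embed_b
    C = np.einsum("nld,kde->nlke", E_motif, params.conv)
    H_wt = np.einsum("nlke,nle->nlk", C, E_wt)
    H_mt = np.einsum("nlke,nle->nlk", C, E_mt)
    enr_wt = np.einsum("nlk,pk->nlp", H_wt, params.proj)
    enr_mt = np.einsum("nlk,pk->nlp", H_mt, params.proj)
    pos_key = "pos_w_i" if mhc_class == "I" else "pos_w_ii"
    w = getattr(params, pos_key)
    v_wt = np.einsum("l,nlp->np", w, enr_wt)
    v_mt = np.einsum("l,nlp->np", w, enr_mt)
    u = v_mt - v_wt
    d = np.linalg.norm(u, axis=1)
    direction = u / (d + params.epsilon)[:, None]
    x = np.concatenate([v_wt, direction], axis=1)
    pre = x @ params.scale_w1.T + params.scale_b1
    h = np.tanh(pre)
    s = h @ params.scale_w2 + params.scale_b2
    sig_s = sigmoid(s)
    return _BatchCache(
        Z_wt=Z_wt, Z_mt=Z_mt, Z_motif=Z_motif,
        E_wt=E_wt, E_mt=E_mt, E_motif=E_motif, C=C,
        H_wt=H_wt, H_mt=H_mt, enr_wt=enr_wt, enr_mt=enr_mt,
        v_wt=v_wt, v_mt=v_mt, u=u, d=d, direction=direction,
        x=x, h=h, s=s, sig_s=sig_s, crd=d * sig_s, pos_key=pos_key,
    )


def backward_batch(
    params: ImmunoModelParams,
    cache: _BatchCache,
    d_crd: np.ndarray,
) -> dict[str, np.ndarray]:
    """Gradients of sum_n d_crd[n] * CRD[n] with respect to all parameters.

    At d = 0 the distance is non-differentiable; the subgradient 0 is used
    for the path through u (the scale-net path through origin remains).
    """
    grads = {name: np.zeros_like(np.asarray(getattr(params, name), dtype=float))
             for name in TENSOR_NAMES}
    d, sig_s, u = cache.d, cache.sig_s, cache.u
    eps = params.epsilon

    dd_direct = d_crd * sig_s
    ds = d_crd * d * sig_s * (1.0 - sig_s)
    # scale net
    grads["scale_w2"] = ds @ cache.h
    grads["scale_b2"] = np.array(ds.sum())
    dh = ds[:, None] * params.scale_w2[None, :]
    dpre = dh * (1.0 - cache.h**2)
    grads["scale_w1"] = dpre.T @ cache.x
    grads["scale_b1"] = dpre.sum(axis=0)
    dx = dpre @ params.scale_w1
    dv_wt = dx[:, : params.d_p].copy()
    ddir = dx[:, params.d_p :]
    # direction and distance paths into u (zeroed where d == 0)
    safe = d > 0
    inv = np.where(safe, 1.0 / (d + eps), 0.0)
    du = ddir * inv[:, None]
    proj_coef = np.where(safe, np.einsum("np,np->n", ddir, u) / (d + eps) ** 2, 0.0)
    du -= (proj_coef * np.where(safe, 1.0 / np.where(safe, d, 1.0), 0.0))[:, None] * u
    du += np.where(safe, dd_direct / np.where(safe, d, 1.0), 0.0)[:, None] * u
    dv_mt = du
    dv_wt -= du
    # pooling
    w = getattr(params, cache.pos_key)
    grads[cache.pos_key] = (
        np.einsum("nlp,np->l", cache.enr_wt, dv_wt)
        + np.einsum("nlp,np->l", cache.enr_mt, dv_mt)
    )
    denr_wt = np.einsum("l,np->nlp", w, dv_wt)
    denr_mt = np.einsum("l,np->nlp", w, dv_mt)
    # projection
    grads["proj"] = (
        np.einsum("nlp,nlk->pk", denr_wt, cache.H_wt)
        + np.einsum("nlp,nlk->pk", denr_mt, cache.H_mt)
    )
    dH_wt = np.einsum("nlp,pk->nlk", denr_wt, params.proj)
    dH_mt = np.einsum("nlp,pk->nlk", denr_mt, params.proj)
    # kernel responses
    dC = (
        np.einsum("nlk,nle->nlke", dH_wt, cache.E_wt)
        + np.einsum("nlk,nle->nlke", dH_mt, cache.E_mt)
    )
    dE_wt = np.einsum("nlk,nlke->nle", dH_wt, cache.C)
    dE_mt = np.einsum("nlk,nlke->nle", dH_mt, cache.C)
    grads["conv"] = np.einsum("nld,nlke->kde", cache.E_motif, dC)
    dE_motif = np.einsum("nlke,kde->nld", dC, params.conv)
    # residue embedding (shared across peptide and motif legs)
    grads["embed_w"] = (
        np.einsum("nld,nle->de", cache.Z_wt, dE_wt)
        + np.einsum("nld,nle->de", cache.Z_mt, dE_mt)
        + np.einsum("nld,nle->de", cache.Z_motif, dE_motif)
    )
    grads["embed_b"] = (
        dE_wt.sum(axis=(0, 1)) + dE_mt.sum(axis=(0, 1)) + dE_motif.sum(axis=(0, 1))
    )
    return grads


def accumulate(into: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
    for k, v in grads.items():
        into[k] = into.get(k, 0.0) + v


class AdamW:
    """Decoupled-weight-decay Adam over a named-tensor dictionary."""

    def __init__(self, names, lr=0.005, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.names = tuple(names)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = {n: 0.0 for n in self.names}
        self.v = {n: 0.0 for n in self.names}
        self.t = 0

    def step(self, params: ImmunoModelParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.betas
        for name in self.names:
            g = np.asarray(grads[name], dtype=float)
            p = np.asarray(getattr(params, name), dtype=float)
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            p = p - self.lr * (m_hat / (np.sqrt(v_hat) + self.eps) + self.weight_decay * p)
            params.set_tensor(name, p)


# --- triplet encoding and training ---------------------------------------

@dataclass
class TrainConfig:
    epochs: int = 100
    lr: float = 0.005
    weight_decay: float = 0.01
    batch_size: int = 512
    full_batch_limit: int = 4096
    seed: int = 0


def encode_triplets(
    triplets,
    motifs: dict[str, BindingMotif],
    predictor=None,
) -> dict[str, dict[str, np.ndarray]]:
    """One-hot encode triplets per MHC class; triplets on alleles with no
    motif are skipped with a warning. Class-II 15-mers are reduced to their
    9-mer binding cores (anchor register from the predictor, applied to all
    three peptides of the triplet)."""
    batches: dict[str, dict[str, list]] = {}
    for t in triplets:
        motif = motifs.get(t.allele)
        if motif is None:
            logger.warning("no motif for allele %s; triplet skipped", t.allele)
            continue
        seed_pep, cross, neg = t.seed, t.cross_reactive, t.non_cross_reactive
        if len(seed_pep) > CORE_LENGTH:
            if predictor is None:
                logger.warning("no predictor to core-reduce %d-mer triplet; skipped", len(seed_pep))
                continue
            start = predictor.predict(seed_pep, t.allele).core_start
            seed_pep = seed_pep[start : start + CORE_LENGTH]
            cross = cross[start : start + CORE_LENGTH]
            neg = neg[start : start + CORE_LENGTH]
        b = batches.setdefault(t.mhc_class, {"a": [], "p": [], "n": [], "m": []})
        b["a"].append(one_hot(seed_pep))
        b["p"].append(one_hot(cross))
        b["n"].append(one_hot(neg))
        b["m"].append(motif.matrix)
    return {
        cls: {k: np.stack(v) for k, v in parts.items()}
        for cls, parts in batches.items()
    }


def triplet_losses(params: ImmunoModelParams, enc: dict[str, dict[str, np.ndarray]]) -> np.ndarray:
    """Per-triplet losses max(0, CRD(a,p) - CRD(a,n) + margin) across classes."""
    losses = []
    for cls, b in enc.items():
        crd_p = forward_batch(params, b["a"], b["p"], b["m"], cls).crd
        crd_n = forward_batch(params, b["a"], b["n"], b["m"], cls).crd
        losses.append(np.maximum(0.0, crd_p - crd_n + params.margin))
    return np.concatenate(losses) if losses else np.array([])


def _stage1_epoch(params, enc, opt, rng, config):
    total_loss, total_n = 0.0, 0
    for cls, b in enc.items():
        n = len(b["a"])
        if n <= config.full_batch_limit:
            slices = [np.arange(n)]
        else:
            order = rng.permutation(n)
            slices = np.array_split(order, int(np.ceil(n / config.batch_size)))
        for idx in slices:
            cp = forward_batch(params, b["a"][idx], b["p"][idx], b["m"][idx], cls)
            cn = forward_batch(params, b["a"][idx], b["n"][idx], b["m"][idx], cls)
            viol = cp.crd - cn.crd + params.margin
            active = (viol > 0).astype(float)
            total_loss += float(np.maximum(0.0, viol).sum())
            total_n += len(idx)
            scale = 1.0 / len(idx)
            grads = backward_batch(params, cp, active * scale)
            accumulate(grads, backward_batch(params, cn, -active * scale))
            opt.step(params, grads)
    return total_loss / max(total_n, 1)


def train_stage1(
    triplets,
    motifs: dict[str, BindingMotif],
    params: ImmunoModelParams,
    config: TrainConfig | None = None,
    predictor=None,
) -> tuple[ImmunoModelParams, list[float]]:
    """Contrastive stage: minimize triplet loss over CRD. Returns updated
    parameters (a copy) and the per-epoch mean training loss."""
    config = config or TrainConfig()
    params = params.copy()
    enc = encode_triplets(triplets, motifs, predictor)
    if not enc:
        raise ValueError("no encodable triplets (missing motifs?)")
    opt = AdamW(STAGE1_TRAINABLE, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history = [_stage1_epoch(params, enc, opt, rng, config) for _ in range(config.epochs)]
    return params, history


# --- stage 2: fine-tuning on labeled epitopes -----------------------------

def encode_epitopes(
    epitopes,
    motifs: dict[str, BindingMotif],
    predictor,
) -> dict[str, np.ndarray]:
    """Precompute one-hot WT/MT cores, motif rows, binding covariates and
    labels for labeled epitopes (MT register imposed on WT)."""
    from .core_motifs import make_core_pair

    X_wt, X_mt, M, bcov, y = [], [], [], [], []
    for e in epitopes:
        motif = motifs.get(e.allele)
        if motif is None:
            logger.warning("no motif for allele %s; epitope skipped", e.allele)
            continue
        pair, pred = make_core_pair(e.wt_peptide, e.mt_peptide, e.allele, predictor)
        X_wt.append(one_hot(pair.wt_core))
        X_mt.append(one_hot(pair.mt_core))
        M.append(motif.matrix)
        bcov.append(binding_covariate(pred, e.mhc_class))
        y.append(float(e.label))
    if not y:
        raise ValueError("no encodable epitopes")
    return {
        "X_wt": np.stack(X_wt), "X_mt": np.stack(X_mt), "M": np.stack(M),
        "bcov": np.array(bcov), "y": np.array(y),
    }


def _bce(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _stage2_forward(params, geo, bcov):
    """CRD and probability from frozen geometric quantities."""
    x = np.concatenate([geo["origin"], geo["direction"]], axis=1)
    h = np.tanh(x @ params.scale_w1.T + params.scale_b1)
    s = h @ params.scale_w2 + params.scale_b2
    sig_s = sigmoid(s)
    c = geo["d"] * sig_s
    logit = params.out_w[0] * c + params.out_w[1] * bcov + params.out_b
    return x, h, sig_s, c, sigmoid(logit)


def train_stage2(
    epitopes,
    motifs: dict[str, BindingMotif],
    predictor,
    params: ImmunoModelParams,
    config: TrainConfig | None = None,
    mhc_classes: tuple[str, ...] = ("I", "II"),
) -> tuple[ImmunoModelParams, dict]:
    """Fine-tune the scale net and output classifier with BCE, keeping all
    upstream tensors frozen bit-for-bit. The epoch with the lowest
    validation loss is kept (training split is used for validation when the
    input carries no 'val' split)."""
    config = config or TrainConfig()
    params = params.copy()
    train = [e for e in epitopes if e.split == "train" and e.mhc_class in mhc_classes]
    val = [e for e in epitopes if e.split == "val" and e.mhc_class in mhc_classes]
    if not train:
        raise ValueError("no training epitopes")
    if len(set(e.label for e in train)) < 2:
        raise ValueError("stage-2 training labels contain a single class")
    if not val:
        logger.warning("no validation split; model selection uses the training loss")

    def _geo(batch_eps):
        # frozen upstream: compute geometric quantities once per class batch
        parts = {"origin": [], "direction": [], "d": [], "bcov": [], "y": []}
        for cls in ("I", "II"):
            sub = [e for e in batch_eps if e.mhc_class == cls]
            if not sub:
                continue
            enc = encode_epitopes(sub, motifs, predictor)
            cache = forward_batch(params, enc["X_wt"], enc["X_mt"], enc["M"], cls)
            parts["origin"].append(cache.v_wt)
            parts["direction"].append(cache.direction)
            parts["d"].append(cache.d)
            parts["bcov"].append(enc["bcov"])
            parts["y"].append(enc["y"])
        return {k: np.concatenate(v) for k, v in parts.items()}

    tr = _geo(train)
    va = _geo(val) if val else tr
    frozen_before = {n: np.array(getattr(params, n), copy=True)
                     for n in STAGE1_TRAINABLE if n not in STAGE2_TRAINABLE}
    opt = AdamW(STAGE2_TRAINABLE, lr=config.lr, weight_decay=config.weight_decay)
    best = (np.inf, None)
    history = {"train_loss": [], "val_loss": []}
    n = len(tr["y"])
    for _ in range(config.epochs):
        x, h, sig_s, c, p = _stage2_forward(params, tr, tr["bcov"])
        dlogit = (p - tr["y"]) / n
        grads = {
            "out_w": np.array([dlogit @ c, dlogit @ tr["bcov"]]),
            "out_b": np.array(dlogit.sum()),
        }
        dcrd = dlogit * params.out_w[0]
        ds = dcrd * tr["d"] * sig_s * (1 - sig_s)
        grads["scale_w2"] = ds @ h
        grads["scale_b2"] = np.array(ds.sum())
        dh = ds[:, None] * params.scale_w2[None, :]
        dpre = dh * (1 - h**2)
        grads["scale_w1"] = dpre.T @ x
        grads["scale_b1"] = dpre.sum(axis=0)
        opt.step(params, grads)
        history["train_loss"].append(_bce(tr["y"], _stage2_forward(params, tr, tr["bcov"])[4]))
        val_loss = _bce(va["y"], _stage2_forward(params, va, va["bcov"])[4])
        history["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, {name: np.array(getattr(params, name), copy=True)
                               for name in STAGE2_TRAINABLE})
    if best[1] is not None:
        for name, value in best[1].items():
            params.set_tensor(name, value)
    for name, before in frozen_before.items():
        after = np.asarray(getattr(params, name))
        if not np.array_equal(before, after):  # freeze contract
            raise AssertionError(f"frozen tensor {name} changed during stage 2")
    return params, history
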
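"""Curation of cross-reactive peptide triplets and labeled epitope datasets.

TCR-pMHC binding tables (CDR3 beta chain, peptide, MHC allele) are grouped
by (allele, CDR3); peptides sharing a group bind the same TCR and MHC and
are therefore treated as cross-reactive. Within-group peptide pairs at
Hamming distance 1 mimic single amino-acid substitutions that preserve TCR
recognition. For each such pair, non-cross-reactive negatives are sampled as
single-substitution variants of the seed whose substitution has a negative
BLOSUM62 score (substantial biochemical dissimilarity) and which do not
belong to the seed's cross-reactive set.

Labeled epitope tables (WT peptide, MT peptide, allele, T-cell assay label)
are filtered for matched lengths and MHC binding, then split into stratified
train/validation/test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._aa import AA_ORDER, blosum62_score, hamming, is_canonical
from .core_motifs import RANK_THRESHOLDS, PredictorInterface, UnsupportedAlleleError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TCRBindingRecord:
    cdr3_beta: str
    peptide: str
    allele: str
    mhc_class: str

    def __post_init__(self):
        if not (self.cdr3_beta and self.peptide and self.allele):
            raise ValueError("cdr3_beta, peptide and allele must all be non-empty")


@dataclass(frozen=True)
class Triplet:
    """Seed / cross-reactive / non-cross-reactive peptide triplet."""

    seed: str
    cross_reactive: str
    non_cross_reactive: str
    allele: str
    mhc_class: str
    group_id: str = ""


@dataclass(frozen=True)
class LabeledEpitope:
    wt_peptide: str
    mt_peptide: str
    allele: str
    mhc_class: str
    label: int
    split: str = "train"


def validate_triplet(t: Triplet, cross_reactive_set: set[str] | None = None) -> None:
    """Independent validator: rechecks Hamming distances, BLOSUM62 sign and
    set exclusion for one triplet. Raises ValueError on violation."""
    if hamming(t.seed, t.cross_reactive) != 1:
        raise ValueError("seed/cross_reactive must be at Hamming distance 1")
    if hamming(t.seed, t.non_cross_reactive) != 1:
        raise ValueError("seed/non_cross_reactive must be at Hamming distance 1")
    pos = next(
        i for i, (a, b) in enumerate(zip(t.seed, t.non_cross_reactive)) if a != b
    )
    if blosum62_score(t.seed[pos], t.non_cross_reactive[pos]) >= 0:
        raise ValueError("negative substitution must have BLOSUM62 score < 0")
    if cross_reactive_set is not None and t.non_cross_reactive in cross_reactive_set:
        raise ValueError("negative peptide belongs to the cross-reactive set")


def filter_and_group_complexes(
    records: list[TCRBindingRecord],
    predictor: PredictorInterface,
    rank_thresholds: dict[str, float] | None = None,
) -> dict[tuple[str, str], set[str]]:
    """Group binding peptides by (allele, CDR3), dropping weak binders and
    singleton groups.

    Records are deduplicated on (cdr3, peptide, allele). Peptides failing
    the class rank threshold, containing non-canonical residues, or on
    unsupported alleles are removed; surviving groups must hold >= 2
    distinct peptides.
    """
    thresholds = dict(RANK_THRESHOLDS)
    if rank_thresholds:
        thresholds.update(rank_thresholds)
    groups: dict[tuple[str, str], set[str]] = {}
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        key = (rec.cdr3_beta, rec.peptide, rec.allele)
        if key in seen:
            continue
        seen.add(key)
        if not is_canonical(rec.peptide):
            continue
        try:
            pred = predictor.predict(rec.peptide, rec.allele)
        except UnsupportedAlleleError:
            logger.warning("allele %s unsupported by predictor; record dropped", rec.allele)
            continue
        if pred.rank_percentile > thresholds[rec.mhc_class]:
            continue
        groups.setdefault((rec.allele, rec.cdr3_beta), set()).add(rec.peptide)
    return {k: v for k, v in groups.items() if len(v) >= 2}


def extract_cross_reactive_pairs(
    groups: dict[tuple[str, str], set[str]],
    classes: dict[str, str] | PredictorInterface | None = None,
) -> list[tuple[str, str, str, str]]:
    """All ordered within-group peptide pairs at Hamming distance exactly 1.

    Pairs are deduplicated across groups on (seed, cross_reactive, allele)
    and returned as (seed, cross_reactive, allele, mhc_class) tuples in
    deterministic order.
    """

    def mhc_class(allele: str) -> str:
        if classes is None:
            return "I"
        if isinstance(classes, PredictorInterface):
            return classes.mhc_class(allele)
        return classes[allele]

    out: dict[tuple[str, str, str], str] = {}
    for (allele, _cdr3), peptides in sorted(groups.items()):
        for a in sorted(peptides):
            for b in sorted(peptides):
                if a == b or len(a) != len(b) or hamming(a, b) != 1:
                    continue
                out.setdefault((a, b, allele), mhc_class(allele))
    return [(s, c, al, cls) for (s, c, al), cls in sorted(out.items())]


def negative_candidates(seed: str, cross_reactive_set: set[str]) -> list[str]:
    """All single-substitution variants of the seed, at any position, whose
    substitution has a negative BLOSUM62 score and which are outside the
    seed's cross-reactive set."""
    out = []
    for pos, res in enumerate(seed):
        for sub in AA_ORDER:
            if sub == res or blosum62_score(res, sub) >= 0:
                continue
            cand = seed[:pos] + sub + seed[pos + 1 :]
            if cand not in cross_reactive_set:
                out.append(cand)
    return out


def sample_non_cross_reactive(
    pair: tuple[str, str, str, str],
    cross_reactive_set: set[str],
    n_per_pair: int = 10,
    rng: np.random.Generator | int | None = None,
) -> list[Triplet]:
    """Sample up to ``n_per_pair`` negatives (without replacement) for one
    cross-reactive pair, emitting validated triplets."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    seed, cross, allele, mhc_class = pair
    candidates = negative_candidates(seed, cross_reactive_set | {seed})
    if not candidates:
        logger.warning("no valid negative candidates for seed %s; pair skipped", seed)
        return []
    if len(candidates) < n_per_pair:
        logger.warning(
            "only %d negative candidates for seed %s (requested %d)",
            len(candidates), seed, n_per_pair,
        )
        chosen = candidates
    else:
        chosen = [candidates[i] for i in rng.choice(len(candidates), n_per_pair, replace=False)]
    triplets = [
        Triplet(seed, cross, neg, allele, mhc_class, group_id=f"{allele}|{seed}")
        for neg in chosen
    ]
    for t in triplets:
        validate_triplet(t, cross_reactive_set)
    return triplets


def make_triplets(
    records: list[TCRBindingRecord],
    predictor: PredictorInterface,
    n_per_pair: int = 10,
    seed: int = 0,
    rank_thresholds: dict[str, float] | None = None,
) -> list[Triplet]:
    """Full triplet curation: group, pair, and sample negatives.

    The cross-reactive set for each seed is the union of peptides sharing
    any (allele, CDR3) group with it.
    """
    groups = filter_and_group_complexes(records, predictor, rank_thresholds)
    pairs = extract_cross_reactive_pairs(groups, predictor)
    cr_sets: dict[tuple[str, str], set[str]] = {}
    for (allele, _cdr3), peptides in groups.items():
        for p in peptides:
            cr_sets.setdefault((allele, p), set()).update(peptides)
    rng = np.random.default_rng(seed)
    triplets: list[Triplet] = []
    for pair in pairs:
        s, _, allele, _ = pair
        triplets.extend(
            sample_non_cross_reactive(pair, cr_sets[(allele, s)], n_per_pair, rng)
        )
    return triplets


def assign_splits(
    labels: np.ndarray,
    split_fracs: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Stratified train/val/test assignment honoring the fractions within
    each label stratum (largest-remainder apportionment, +-1 sample per
    stratum). Rounding errors are carried across strata so the global
    split sizes match the fractions exactly whenever possible."""
    if not np.isclose(sum(split_fracs), 1.0):
        raise ValueError("split fractions must sum to 1")
    names = np.array(["train", "val", "test"])
    out = np.empty(len(labels), dtype=object)
    carry = np.zeros(3)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        rng.shuffle(idx)
        n = len(idx)
        exact = np.array(split_fracs) * n + carry
        sizes = np.maximum(np.floor(exact), 0).astype(int)
        remainders = exact - sizes
        for _ in range(n - sizes.sum()):
            j = int(np.argmax(remainders))
            sizes[j] += 1
            remainders[j] = -1.0
        carry = exact - sizes
        bounds = np.cumsum(sizes)
        out[idx[: bounds[0]]] = names[0]
        out[idx[bounds[0] : bounds[1]]] = names[1]
        out[idx[bounds[1] :]] = names[2]
    return out


def curate_labeled_dataset(
    records: list[dict] | pd.DataFrame,
    predictor: PredictorInterface,
    split_fracs: tuple[float, float, float] = (0.75, 0.10, 0.15),
    seed: int = 0,
    rank_thresholds: dict[str, float] | None = None,
) -> list[LabeledEpitope]:
    """Filter a labeled WT/MT epitope table and assign stratified splits.

    Removes pairs with mismatched lengths, non-canonical residues, and MT
    peptides failing the class rank filter. Splits are stratified by label
    with a fixed seed.
    """
    thresholds = dict(RANK_THRESHOLDS)
    if rank_thresholds:
        thresholds.update(rank_thresholds)
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    kept: list[dict] = []
    for rec in records:
        wt, mt = rec["wt_peptide"], rec["mt_peptide"]
        if len(wt) != len(mt):
            continue
        if not (is_canonical(wt) and is_canonical(mt)):
            continue
        try:
            pred = predictor.predict(mt, rec["allele"])
        except UnsupportedAlleleError:
            continue
        if pred.rank_percentile > thresholds[rec["mhc_class"]]:
            continue
        kept.append(rec)
    if not kept:
        return []
    labels = np.array([int(r["label"]) for r in kept])
    splits = assign_splits(labels, split_fracs, np.random.default_rng(seed))
    return [
        LabeledEpitope(
            wt_peptide=r["wt_peptide"],
            mt_peptide=r["mt_peptide"],
            allele=r["allele"],
            mhc_class=r["mhc_class"],
            label=int(r["label"]),
            split=s,
        )
        for r, s in zip(kept, splits)
    ]


# --- TSV interfaces -------------------------------------------------------

def read_tcr_binding_tsv(path: str | Path) -> list[TCRBindingRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TCRBindingRecord(r.cdr3_beta, r.peptide, r.allele, r.mhc_class)
        for r in df.itertuples(index=False)
    ]


def write_triplets_tsv(triplets: list[Triplet], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (t.seed, t.cross_reactive, t.non_cross_reactive, t.allele, t.mhc_class)
            for t in triplets
        ],
        columns=["seed", "cross_reactive", "non_cross_reactive", "allele", "mhc_class"],
    )
    with open(path, "w") as fh:
        fh.write("#schema=triplets.v1\n")
        df.to_csv(fh, sep="\t", index=False)


def read_triplets_tsv(path: str | Path) -> list[Triplet]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        Triplet(r.seed, r.cross_reactive, r.non_cross_reactive, r.allele, r.mhc_class)
        for r in df.itertuples(index=False)
    ]


def write_epitopes_tsv(epitopes: list[LabeledEpitope], path: str | Path) -> None:
    df = pd.DataFrame([e.__dict__ for e in epitopes])
    with open(path, "w") as fh:
        fh.write("#schema=epitopes.v1\n")
        df.to_csv(fh, sep="\t", index=False)


def read_epitopes_tsv(path: str | Path) -> list[LabeledEpitope]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [LabeledEpitope(**row) for row in df.to_dict("records")]
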
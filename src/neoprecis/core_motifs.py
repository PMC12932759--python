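"""Peptide/allele primitives, MHC binding-motif construction, and the
pluggable binding-predictor contract.

The binding predictor is an abstraction over tools like NetMHCpan: anything
that maps (peptide, allele) to a %rank percentile (lower = stronger
binding), a binding score (higher = stronger), and the 0-based offset of the
9-mer binding core within the query peptide. Two implementations ship here:

* :class:`PWMPredictor` — a deterministic position-weight-matrix mock whose
  %rank is calibrated on a fixed random background; used for tests and
  synthetic data.
* :class:`TablePredictor` — an adapter over precomputed tabular predictions
  (columns: peptide, allele, core, rank, score) supplied by the user.

An allele's binding motif is the L x 20 matrix of position-specific amino
acid frequencies over the 9-mer binding cores of peptides that pass the
class rank threshold (2 for MHC-I, 10 for MHC-II). No pseudocounts are
added, so frequencies may be exactly zero.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._aa import (
    AA_INDEX,
    AA_ORDER,
    CORE_LENGTH,
    N_AA,
    hamming,
    one_hot,
    random_peptides,
    validate_peptide,
)

RANK_THRESHOLDS = {"I": 2.0, "II": 10.0}
PEPTIDE_LENGTHS = {"I": 9, "II": 15}


class UnsupportedAlleleError(KeyError):
    """The predictor does not cover the requested allele."""


class ZeroBindersError(ValueError):
    """No peptide in the sample passed the binding rank threshold."""


@dataclass(frozen=True)
class BindingPrediction:
    """One predictor call: %rank percentile, raw binding score, core offset."""

    rank_percentile: float
    binding_score: float
    core_start: int

    def __post_init__(self):
        if not self.rank_percentile > 0:
            raise ValueError("rank_percentile must be > 0")
        if self.core_start < 0:
            raise ValueError("core_start must be >= 0")


@dataclass(frozen=True)
class CorePeptidePair:
    """9-mer WT/MT binding cores for one substitution on one allele.

    ``mutated_position`` is 1-based within the core. It is ``None`` for a
    WT self-pair (identical cores), which arises when the substitution in
    the full peptide falls outside the predicted binding core.
    """

    wt_core: str
    mt_core: str
    allele: str
    mhc_class: str
    mutated_position: int | None = None

    def __post_init__(self):
        validate_peptide(self.wt_core, "wt_core")
        validate_peptide(self.mt_core, "mt_core")
        if len(self.wt_core) != CORE_LENGTH or len(self.mt_core) != CORE_LENGTH:
            raise ValueError("binding cores must be 9-mers")
        if self.mhc_class not in ("I", "II"):
            raise ValueError("mhc_class must be 'I' or 'II'")
        d = hamming(self.wt_core, self.mt_core)
        if d > 1:
            raise ValueError(
                f"cores differ at {d} positions; pairs must be Hamming <= 1"
            )
        if d == 1:
            pos = next(
                i for i, (a, b) in enumerate(zip(self.wt_core, self.mt_core)) if a != b
            )
            if self.mutated_position is None:
                object.__setattr__(self, "mutated_position", pos + 1)
            elif self.mutated_position != pos + 1:
                raise ValueError(
                    f"mutated_position {self.mutated_position} does not index the "
                    f"differing position ({pos + 1})"
                )
        elif self.mutated_position is not None:
            raise ValueError("self-pair must not declare a mutated_position")

    @property
    def is_self_pair(self) -> bool:
        return self.wt_core == self.mt_core


@dataclass
class BindingMotif:
    """Per-allele L x 20 position-specific amino-acid frequency matrix."""

    allele: str
    mhc_class: str
    matrix: np.ndarray
    n_source_peptides: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (CORE_LENGTH, N_AA):
            raise ValueError(f"motif matrix must be {CORE_LENGTH}x{N_AA}")
        if np.any(self.matrix < 0):
            raise ValueError("motif frequencies must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every motif row must sum to 1")

    def consensus(self) -> str:
        """Most frequent residue per position."""
        return "".join(AA_ORDER[j] for j in self.matrix.argmax(axis=1))


class PredictorInterface(ABC):
    """Contract for pluggable MHC binding predictors.

    Implementations must be deterministic for fixed inputs and raise
    :class:`UnsupportedAlleleError` for alleles they do not cover.
    """

    @property
    @abstractmethod
    def supported_alleles(self) -> set[str]: ...

    @abstractmethod
    def predict(self, peptide: str, allele: str) -> BindingPrediction: ...

    @abstractmethod
    def mhc_class(self, allele: str) -> str: ...

    def rank_threshold(self, allele: str) -> float:
        return RANK_THRESHOLDS[self.mhc_class(allele)]


class PWMPredictor(PredictorInterface):
    """Deterministic mock predictor scoring peptides against PWMs.

    ``binding_score`` is the PWM likelihood of the best 9-mer window
    (product of per-position weights, floored), so scores are positive and
    their ratios are meaningful fold changes; ``rank_percentile`` is the
    percentage of a fixed, seeded background sample scoring at least as
    well (a monotone-decreasing transform of the score, always > 0).
    """

    def __init__(
        self,
        pwms: dict[str, np.ndarray],
        classes: dict[str, str],
        background_size: int = 5000,
        background_seed: int = 20,
        floor: float = 1e-6,
    ):
        self._log_pwms = {}
        self._classes = dict(classes)
        self._floor = floor
        for allele, pwm in pwms.items():
            pwm = np.asarray(pwm, dtype=float)
            if pwm.shape != (CORE_LENGTH, N_AA):
                raise ValueError("PWM must be 9x20")
            if not np.all(np.isfinite(pwm)) or np.any(pwm < 0):
                raise ValueError("PWM weights must be finite and nonnegative")
            self._log_pwms[allele] = np.log(pwm + floor)
        # calibrate %rank on a fixed background per allele (class-appropriate length)
        self._bg_scores: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(background_seed)
        for allele in sorted(self._log_pwms):
            length = PEPTIDE_LENGTHS[self._classes[allele]]
            bg = random_peptides(background_size, length, rng)
            scores = np.array([self._best_window(p, allele)[0] for p in bg])
            self._bg_scores[allele] = np.sort(scores)

    @property
    def supported_alleles(self) -> set[str]:
        return set(self._log_pwms)

    def mhc_class(self, allele: str) -> str:
        try:
            return self._classes[allele]
        except KeyError:
            raise UnsupportedAlleleError(allele) from None

    def _best_window(self, peptide: str, allele: str) -> tuple[float, int]:
        lp = self._log_pwms[allele]
        best_score, best_start = -np.inf, 0
        for start in range(len(peptide) - CORE_LENGTH + 1):
            idx = [AA_INDEX[c] for c in peptide[start : start + CORE_LENGTH]]
            score = float(lp[np.arange(CORE_LENGTH), idx].sum())
            if score > best_score:  # ties -> smallest offset
                best_score, best_start = score, start
        return best_score, best_start

    def predict(self, peptide: str, allele: str) -> BindingPrediction:
        if allele not in self._log_pwms:
            raise UnsupportedAlleleError(allele)
        validate_peptide(peptide)
        if len(peptide) < CORE_LENGTH:
            raise ValueError("peptide shorter than the 9-mer binding core")
        score, start = self._best_window(peptide, allele)
        bg = self._bg_scores[allele]
        n_ge = len(bg) - np.searchsorted(bg, score, side="left")
        rank = 100.0 * (n_ge + 1) / (len(bg) + 1)
        return BindingPrediction(
            rank_percentile=float(rank),
            binding_score=float(np.exp(score)),
            core_start=start,
        )


class TablePredictor(PredictorInterface):
    """Adapter over precomputed tabular predictions (NetMHCpan-style).

    Expects columns ``peptide, allele, core, rank, score`` (an ``mhc_class``
    column is optional; class is otherwise inferred from peptide length).
    """

    REQUIRED = ("peptide", "allele", "core", "rank", "score")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise ValueError(f"prediction table is missing columns: {missing}")
        self._lookup: dict[tuple[str, str], BindingPrediction] = {}
        self._classes: dict[str, str] = {}
        for row in table.itertuples(index=False):
            start = row.peptide.find(row.core)
            if start < 0:
                raise ValueError(f"core {row.core!r} not found in {row.peptide!r}")
            self._lookup[(row.peptide, row.allele)] = BindingPrediction(
                rank_percentile=float(row.rank),
                binding_score=float(row.score),
                core_start=start,
            )
            cls = getattr(row, "mhc_class", "I" if len(row.peptide) < 12 else "II")
            self._classes[row.allele] = cls

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TablePredictor":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    @property
    def supported_alleles(self) -> set[str]:
        return set(self._classes)

    def mhc_class(self, allele: str) -> str:
        try:
            return self._classes[allele]
        except KeyError:
            raise UnsupportedAlleleError(allele) from None

    def predict(self, peptide: str, allele: str) -> BindingPrediction:
        try:
            return self._lookup[(peptide, allele)]
        except KeyError:
            if allele not in self._classes:
                raise UnsupportedAlleleError(allele) from None
            raise KeyError(f"no prediction for ({peptide}, {allele})") from None


def pwm_mock_predictor(
    motif_spec: dict[str, np.ndarray] | np.ndarray,
    classes: dict[str, str] | None = None,
    allele: str = "MOCK*01:01",
    mhc_class: str = "I",
    **kwargs,
) -> PWMPredictor:
    """Build a deterministic PWM mock predictor (test double).

    Accepts either a single 9x20 weight matrix (one allele) or a dict of
    allele -> matrix plus a class map.
    """
    if isinstance(motif_spec, dict):
        if classes is None:
            raise ValueError("classes map required for multi-allele predictors")
        return PWMPredictor(motif_spec, classes, **kwargs)
    return PWMPredictor({allele: np.asarray(motif_spec)}, {allele: mhc_class}, **kwargs)


def extract_binding_core(
    peptide: str, allele: str, predictor: PredictorInterface
) -> tuple[str, BindingPrediction]:
    """Return the 9-mer binding core reported by the predictor, plus the prediction."""
    validate_peptide(peptide)
    if len(peptide) < CORE_LENGTH:
        raise ValueError(f"peptide {peptide!r} is shorter than the 9-mer core")
    pred = predictor.predict(peptide, allele)
    if pred.core_start > len(peptide) - CORE_LENGTH:
        raise ValueError("predictor reported an out-of-range core_start")
    return peptide[pred.core_start : pred.core_start + CORE_LENGTH], pred


def make_core_pair(
    wt_peptide: str,
    mt_peptide: str,
    allele: str,
    predictor: PredictorInterface,
) -> tuple[CorePeptidePair, BindingPrediction]:
    """Pair WT/MT peptides on the MT peptide's binding register.

    The binding core is predicted on the MT peptide and the WT peptide is
    sliced at the same offset, which guarantees the resulting cores differ
    at no more than one position whenever the full peptides do.
    """
    if len(wt_peptide) != len(mt_peptide):
        raise ValueError("WT and MT peptides must have equal length")
    if hamming(wt_peptide, mt_peptide) > 1:
        raise ValueError("WT/MT peptides must differ at no more than one position")
    mt_core, pred = extract_binding_core(mt_peptide, allele, predictor)
    wt_core = wt_peptide[pred.core_start : pred.core_start + CORE_LENGTH]
    pair = CorePeptidePair(
        wt_core=wt_core,
        mt_core=mt_core,
        allele=allele,
        mhc_class=predictor.mhc_class(allele),
    )
    return pair, pred


def build_binding_motif(
    peptidome_sample: list[str],
    allele: str,
    predictor: PredictorInterface,
    rank_threshold: float | None = None,
) -> BindingMotif:
    """Position-specific amino-acid frequencies over retained binding cores.

    Peptides passing the class rank threshold contribute their 9-mer binding
    core; frequencies are computed per core position with no pseudocounts.
    """
    mhc_class = predictor.mhc_class(allele)
    if rank_threshold is None:
        rank_threshold = RANK_THRESHOLDS[mhc_class]
    counts = np.zeros((CORE_LENGTH, N_AA), dtype=float)
    n_retained = 0
    for peptide in peptidome_sample:
        core, pred = extract_binding_core(peptide, allele, predictor)
        if pred.rank_percentile <= rank_threshold:
            counts += one_hot(core)
            n_retained += 1
    if n_retained == 0:
        raise ZeroBindersError(
            f"no peptide passed rank threshold {rank_threshold} for {allele}"
        )
    return BindingMotif(
        allele=allele,
        mhc_class=mhc_class,
        matrix=counts / n_retained,
        n_source_peptides=n_retained,
    )


def sample_peptidome(
    n: int, mhc_class: str, seed: int = 0, fasta: str | Path | None = None
) -> list[str]:
    """Peptidome sample for motif building.

    Default is uniform random peptides of the class-appropriate length with
    a fixed seed; a FASTA proteome may be supplied instead, in which case
    peptides are drawn as random substrings of its sequences (records with
    non-canonical residues in the window are skipped).
    """
    length = PEPTIDE_LENGTHS[mhc_class]
    rng = np.random.default_rng(seed)
    if fasta is None:
        return random_peptides(n, length, rng)
    from Bio import SeqIO

    seqs = [str(r.seq) for r in SeqIO.parse(str(fasta), "fasta")]
    seqs = [s for s in seqs if len(s) >= length]
    if not seqs:
        raise ValueError("no FASTA sequence long enough for the peptide length")
    out: list[str] = []
    attempts = 0
    while len(out) < n and attempts < 50 * n:
        attempts += 1
        s = seqs[rng.integers(len(seqs))]
        start = rng.integers(len(s) - length + 1)
        pep = s[start : start + length].upper()
        if all(c in AA_INDEX for c in pep):
            out.append(pep)
    if len(out) < n:
        raise ValueError("could not draw enough canonical peptides from the FASTA")
    return out


# --- motif TSV round-trip -------------------------------------------------

def write_motif_tsv(motif: BindingMotif, path: str | Path) -> None:
    df = pd.DataFrame(motif.matrix, columns=list(AA_ORDER))
    df.insert(0, "position", np.arange(1, CORE_LENGTH + 1))
    with open(path, "w") as fh:
        fh.write(
            f"# allele={motif.allele}\tmhc_class={motif.mhc_class}"
            f"\tn_source_peptides={motif.n_source_peptides}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_motif_tsv(path: str | Path) -> BindingMotif:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("motif TSV must start with a '# allele=...' header")
        meta = dict(kv.split("=", 1) for kv in header[1:].strip().split("\t"))
        df = pd.read_csv(fh, sep="\t")
    matrix = df[list(AA_ORDER)].to_numpy(dtype=float)
    return BindingMotif(
        allele=meta["allele"],
        mhc_class=meta.get("mhc_class", "I"),
        matrix=matrix,
        n_source_peptides=int(meta.get("n_source_peptides", 0)),
    )
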
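"""Amino-acid alphabet utilities and the BLOSUM62 substitution matrix.

The 20 canonical residues are kept in the conventional BLOSUM ordering
(ARNDCQEGHILKMFPSTWYV). Peptides containing ambiguous residues (X/B/Z/U/*)
are rejected at ingest because the residue-embedding transform multiplies
one-hot rows by the BLOSUM62 matrix, which is only meaningful for canonical
residues.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
N_AA = 20
CORE_LENGTH = 9


@lru_cache(maxsize=None)
def blosum62_matrix() -> np.ndarray:
    """20x20 BLOSUM62 score matrix over `AA_ORDER`, as floats."""
    full = substitution_matrices.load("BLOSUM62")
    mat = np.empty((N_AA, N_AA), dtype=float)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = full[a, b]
    mat.flags.writeable = False
    return mat


def blosum62_score(a: str, b: str) -> float:
    return blosum62_matrix()[AA_INDEX[a], AA_INDEX[b]]


def is_canonical(peptide: str) -> bool:
    return len(peptide) > 0 and all(c in AA_INDEX for c in peptide)


def validate_peptide(peptide: str, name: str = "peptide") -> str:
    if not is_canonical(peptide):
        raise ValueError(
            f"{name} {peptide!r} contains non-canonical residues; "
            f"only {AA_ORDER} are accepted"
        )
    return peptide


def one_hot(peptide: str) -> np.ndarray:
    """L x 20 one-hot encoding of a canonical peptide."""
    validate_peptide(peptide)
    out = np.zeros((len(peptide), N_AA), dtype=float)
    for i, aa in enumerate(peptide):
        out[i, AA_INDEX[aa]] = 1.0
    return out


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_peptides(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """Uniform random peptides over the canonical alphabet."""
    idx = rng.integers(0, N_AA, size=(n, length))
    return ["".join(AA_ORDER[j] for j in row) for row in idx]
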
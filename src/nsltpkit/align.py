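"""Global pairwise alignment identity.

Identity between two sequences is defined on a Needleman-Wunsch global
alignment with match +1, mismatch 0 and a linear gap penalty of -1, as
the number of identical aligned pairs divided by the number of alignment
columns, in percent.  The alignment itself is delegated to
:class:`Bio.Align.PairwiseAligner`.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

__all__ = ["pairwise_identity", "identity_matrix", "IdentityMatrix"]


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the optimal global alignment of two sequences."""
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


class IdentityMatrix:
    """Symmetric percent-identity matrix over a set of named sequences."""

    def __init__(self, ids: list[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(matrix), 100.0):
            raise ValueError("identity matrix diagonal must be 100")
        if matrix.min() < 0 or matrix.max() > 100 + 1e-9:
            raise ValueError("identities must lie in [0, 100]")
        self.ids = list(ids)
        self.matrix = matrix
        self._index = {name: i for i, name in enumerate(self.ids)}

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.matrix[self._index[a], self._index[b]])

    def __contains__(self, name: str) -> bool:
        return name in self._index


def identity_matrix(sequences: dict[str, str]) -> IdentityMatrix:
    """All-against-all global-alignment identity for a named sequence set."""
    ids = list(sequences)
    n = len(ids)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_identity(sequences[ids[i]], sequences[ids[j]])
    return IdentityMatrix(ids, mat)
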
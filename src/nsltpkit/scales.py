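"""Residue scale tables used across the package.

The numeric content follows the ExPASy/ProtParam conventions: average
(not monoisotopic) residue masses, the Bjellqvist pKa set for charge and
isoelectric-point calculations, the Kyte-Doolittle hydropathy scale and
the Guruprasad dipeptide instability weights (DIWV).  The published
constant tables are taken from Biopython's data modules rather than
duplicated here.

Unknown residues ('X') use a documented neutral fallback: mass = mean of
the 20 standard residue masses, KD = 0, DIWV = 1.0, no ionizable group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.IUPACData import protein_weights as _AVERAGE_WEIGHTS
from Bio.SeqUtils.IsoelectricPoint import (
    negative_pKs as _NEGATIVE_PKS,
    pKcterminal as _PK_CTERMINAL,
    pKnterminal as _PK_NTERMINAL,
    positive_pKs as _POSITIVE_PKS,
)
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV, kd as _KD

WATER_MASS = 18.01528

#: Average mass (Da) of the *free* amino acid; subtract one water per peptide bond.
RESIDUE_MASS: dict[str, float] = dict(_AVERAGE_WEIGHTS)
RESIDUE_MASS["X"] = sum(_AVERAGE_WEIGHTS.values()) / len(_AVERAGE_WEIGHTS)

KYTE_DOOLITTLE: dict[str, float] = dict(_KD)
KYTE_DOOLITTLE["X"] = 0.0


def instability_weight(first: str, second: str) -> float:
    """Guruprasad DIWV weight of the dipeptide ``first``-``second``."""
    try:
        return _DIWV[first][second]
    except KeyError:
        return 1.0


@dataclass(frozen=True)
class PKaSet:
    """Bjellqvist pKa values as used by the ExPASy Compute pI/Mw tool.

    The N- and C-terminal pKa depend on the terminal residue for a small
    set of residues; side-chain pKas cover D, E, C, Y (acidic) and
    H, K, R (basic).
    """

    positive: dict[str, float] = field(default_factory=lambda: dict(_POSITIVE_PKS))
    negative: dict[str, float] = field(default_factory=lambda: dict(_NEGATIVE_PKS))
    nterm_by_residue: dict[str, float] = field(default_factory=lambda: dict(_PK_NTERMINAL))
    cterm_by_residue: dict[str, float] = field(default_factory=lambda: dict(_PK_CTERMINAL))

    def nterm(self, residue: str) -> float:
        return self.nterm_by_residue.get(residue, self.positive["Nterm"])

    def cterm(self, residue: str) -> float:
        return self.cterm_by_residue.get(residue, self.negative["Cterm"])


BJELLQVIST = PKaSet()
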
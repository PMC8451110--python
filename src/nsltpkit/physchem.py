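"""Closed-form physicochemical profiling of protein sequences.

Implements the ProtParam-style descriptor set used to characterize
nsLTP catalogs: molecular weight (average masses), isoelectric point
(Bjellqvist pKa set, bisection), Guruprasad instability index, Ikai
aliphatic index and the grand average of hydropathy (GRAVY, mean
Kyte-Doolittle score).  ``summarize_cohort`` reduces a cohort of
profiles to the per-group mean/min/max summaries reported for gene-family
catalogs, at catalog precision (Mw to 1 Da, pI and indices to 2 dp).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .scales import BJELLQVIST, KYTE_DOOLITTLE, RESIDUE_MASS, WATER_MASS, instability_weight

__all__ = [
    "PhyschemProfile",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "instability_index",
    "aliphatic_index",
    "gravy",
    "profile",
    "summarize_cohort",
]


@dataclass(frozen=True)
class PhyschemProfile:
    id: str
    length: int
    mw: float
    pi: float
    instability: float
    aliphatic: float
    gravy: float

    def __post_init__(self) -> None:
        if self.length < 1 or self.mw <= 0 or not 0 < self.pi < 14:
            raise ValueError(f"{self.id}: implausible physicochemical profile")


def _check(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    return sequence


def molecular_weight(sequence: str) -> float:
    """Average molecular mass in Da: free residue masses minus one water per bond."""
    _check(sequence)
    return sum(RESIDUE_MASS[res] for res in sequence) - (len(sequence) - 1) * WATER_MASS


def net_charge(sequence: str, pH: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH (Bjellqvist pKa set)."""
    _check(sequence)
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    positive_pkas = [BJELLQVIST.nterm(sequence[0])]
    negative_pkas = [BJELLQVIST.cterm(sequence[-1])]
    for res in sequence:
        if res in BJELLQVIST.positive:
            positive_pkas.append(BJELLQVIST.positive[res])
        elif res in BJELLQVIST.negative:
            negative_pkas.append(BJELLQVIST.negative[res])
    charge = sum(1.0 / (1.0 + 10 ** (pH - pka)) for pka in positive_pkas)
    charge -= sum(1.0 / (1.0 + 10 ** (pka - pH)) for pka in negative_pkas)
    return charge


def isoelectric_point(sequence: str, tolerance: float = 1e-4, max_iter: int = 100) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Iterates until ``|net_charge| < tolerance`` (net charge is strictly
    decreasing in pH, so the bracket always contains the unique zero).
    """
    _check(sequence)
    lo, hi = 0.0, 14.0
    pH = 7.0
    for _ in range(max_iter):
        pH = (lo + hi) / 2.0
        charge = net_charge(sequence, pH)
        if abs(charge) < tolerance:
            break
        if charge > 0:
            lo = pH
        else:
            hi = pH
    return pH


def instability_index(sequence: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    _check(sequence)
    if len(sequence) < 2:
        raise ValueError("instability index requires at least 2 residues")
    total = sum(instability_weight(a, b) for a, b in zip(sequence, sequence[1:]))
    return 10.0 / len(sequence) * total


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index: X(A) + 2.9 X(V) + 3.9 (X(I) + X(L)), mole percent."""
    _check(sequence)
    length = len(sequence)
    mole = {res: 100.0 * sequence.count(res) / length for res in "AVIL"}
    return mole["A"] + 2.9 * mole["V"] + 3.9 * (mole["I"] + mole["L"])


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle score."""
    _check(sequence)
    return sum(KYTE_DOOLITTLE[res] for res in sequence) / len(sequence)


def profile(protein_id: str, sequence: str) -> PhyschemProfile:
    """All five descriptors for one sequence."""
    return PhyschemProfile(
        id=protein_id,
        length=len(sequence),
        mw=molecular_weight(sequence),
        pi=isoelectric_point(sequence),
        instability=instability_index(sequence),
        aliphatic=aliphatic_index(sequence),
        gravy=gravy(sequence),
    )


_COLUMN_ROUNDING = {"length": 0, "mw": 0, "pi": 2, "instability": 2, "aliphatic": 2, "gravy": 3}


def summarize_cohort(
    profiles: Sequence[PhyschemProfile] | pd.DataFrame,
    groups: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-group and combined mean/min/max of the five descriptors.

    ``profiles`` may be a list of :class:`PhyschemProfile` or a DataFrame
    with columns length/mw/pi/instability/aliphatic/gravy (e.g. a
    transcribed catalog table).  ``groups`` supplies one source label per
    profile; a "combined" group over everything is always included.
    Means are rounded at catalog precision (Mw to the nearest Da, pI to
    2 decimals, length to the nearest integer).
    """
    if isinstance(profiles, pd.DataFrame):
        frame = profiles.copy()
    else:
        frame = pd.DataFrame(
            {
                "length": [p.length for p in profiles],
                "mw": [p.mw for p in profiles],
                "pi": [p.pi for p in profiles],
                "instability": [p.instability for p in profiles],
                "aliphatic": [p.aliphatic for p in profiles],
                "gravy": [p.gravy for p in profiles],
            }
        )
    if frame.empty:
        raise ValueError("summarize_cohort requires a non-empty cohort")
    frame = frame[list(_COLUMN_ROUNDING)]
    if groups is not None:
        labels = list(groups)
        if len(labels) != len(frame):
            raise ValueError("one group label per profile required")
    else:
        labels = ["all"] * len(frame)

    rows = []
    group_names = list(dict.fromkeys(labels)) + ["combined"]
    for name in group_names:
        sub = frame if name == "combined" else frame[[lab == name for lab in labels]]
        for column, ndigits in _COLUMN_ROUNDING.items():
            mean = round(sub[column].mean(), ndigits) if ndigits else round(sub[column].mean())
            rows.append(
                {
                    "group": name,
                    "metric": column,
                    "mean": mean,
                    "min": sub[column].min(),
                    "max": sub[column].max(),
                }
            )
    result = pd.DataFrame(rows).set_index(["group", "metric"])
    bad = result[(result["min"] > result["mean"]) | (result["mean"] > result["max"])]
    # rounding can nudge a mean marginally past an extreme only in degenerate
    # single-member groups; tolerate half a rounding unit
    for (grp, metric), row in bad.iterrows():
        unit = 10.0 ** -_COLUMN_ROUNDING[metric] if _COLUMN_ROUNDING[metric] else 1.0
        if row["mean"] < row["min"] - unit or row["mean"] > row["max"] + unit:
            raise AssertionError(f"summary out of range for {grp}/{metric}")
    return result
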
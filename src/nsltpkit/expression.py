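"""Expression analysis: FPKM tissue matrices and qRT-PCR 2^-ddCt.

Relative expression follows the standard 2^-ddCt scheme: technical
replicates are averaged per biological sample, dCt = Ct(target) -
Ct(reference gene), ddCt subtracts the gene's mean calibrator dCt, and
the reported fold change is 2^-mean(ddCt) over biological replicates
(so the calibrator condition is exactly 1).  Significance against the
calibrator uses a two-sided Welch t-test on the dCt values — the
customary choice where the underlying publication style shows
significance stars without naming a test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

__all__ = [
    "RelativeExpression",
    "relative_quantity",
    "star_label",
    "heatmap_matrix",
    "tissue_specificity_flags",
]

REQUIRED_QPCR_COLUMNS = ("gene", "condition", "bio_rep", "tech_rep", "ct_target", "ct_reference")


@dataclass(frozen=True)
class RelativeExpression:
    gene: str
    condition: str
    rq: float               # 2^-mean(ddCt) over biological replicates
    se: float                # standard error of per-replicate RQ
    p_value: Optional[float]  # Welch t-test vs calibrator dCt; None if untestable
    stars: str               # ** | * | ns

    def __post_init__(self) -> None:
        if self.rq <= 0:
            raise ValueError("relative quantity must be positive")


def star_label(p_value: Optional[float]) -> str:
    if p_value is None:
        return "ns"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return "ns"


def relative_quantity(table: pd.DataFrame, calibrator: str) -> list[RelativeExpression]:
    """2^-ddCt relative expression per gene and condition.

    ``table`` is long-format with columns gene, condition, bio_rep,
    tech_rep, ct_target, ct_reference.  ``calibrator`` names the
    reference condition.  With a single biological replicate the fold
    change is still reported but the p-value is absent.
    """
    missing = set(REQUIRED_QPCR_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns {sorted(missing)}")
    if not np.isfinite(table[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValueError("Ct values must be finite")

    # average technical replicates within each biological sample
    per_bio = (
        table.groupby(["gene", "condition", "bio_rep"], sort=True)[["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    per_bio["dct"] = per_bio["ct_target"] - per_bio["ct_reference"]

    results: list[RelativeExpression] = []
    for gene, gene_rows in per_bio.groupby("gene", sort=True):
        cal = gene_rows[gene_rows["condition"] == calibrator]["dct"].to_numpy()
        if cal.size == 0:
            raise ValueError(f"{gene}: calibrator condition {calibrator!r} missing")
        cal_mean = cal.mean()
        for condition, rows in gene_rows.groupby("condition", sort=True):
            ddct = rows["dct"].to_numpy() - cal_mean
            # subtract the means (not the mean of differences) so the
            # calibrator condition lands on ddCt = 0, hence RQ = 1, exactly
            rq = float(2.0 ** -(rows["dct"].to_numpy().mean() - cal_mean))
            per_rep_rq = 2.0 ** -ddct
            se = float(per_rep_rq.std(ddof=1) / math.sqrt(len(ddct))) if len(ddct) > 1 else 0.0
            if condition == calibrator or len(ddct) < 2 or cal.size < 2:
                p_value = None
            else:
                p_value = float(
                    stats.ttest_ind(rows["dct"], cal, equal_var=False).pvalue
                )
            results.append(
                RelativeExpression(
                    gene=gene,
                    condition=condition,
                    rq=rq,
                    se=se,
                    p_value=p_value,
                    stars=star_label(p_value),
                )
            )
    return results


def heatmap_matrix(
    expr: pd.DataFrame,
    log2_transform: bool = True,
    zscore_rows: bool = True,
    cluster_rows: bool = True,
) -> pd.DataFrame:
    """Display transform of an FPKM matrix: log2(x+1), row z-score, row order.

    Zero-variance rows map to all-zero after z-scoring, and the returned
    frame never contains non-finite values.  Row order (when clustering)
    comes from average-linkage hierarchical clustering on correlation
    distance and affects display only.
    """
    if (expr < 0).to_numpy().any():
        raise ValueError("expression values must be non-negative")
    mat = expr.astype(float)
    if log2_transform:
        mat = np.log2(mat + 1.0)
    if zscore_rows:
        centered = mat.sub(mat.mean(axis=1), axis=0)
        sd = mat.std(axis=1, ddof=0)
        mat = centered.div(sd.replace(0.0, np.inf), axis=0)
    mat = mat.replace([np.inf, -np.inf], 0.0).fillna(0.0)
    if cluster_rows and len(mat) > 2:
        distances = pdist(mat.to_numpy(), metric="correlation")
        distances = np.nan_to_num(distances, nan=1.0)  # constant rows
        order = leaves_list(average(distances))
        mat = mat.iloc[order]
    return mat


def tissue_specificity_flags(
    expr: pd.DataFrame,
    specificity_fraction: float = 0.5,
    min_expr: float = 1.0,
) -> dict[str, list[str]]:
    """Per-gene tissue specificity calls.

    A gene is "specific" to every tissue contributing at least
    ``specificity_fraction`` of its row total; genes whose values are all
    below ``min_expr`` are flagged ``["not expressed"]``.
    """
    if expr.shape[1] < 2:
        raise ValueError("at least two conditions are required")
    flags: dict[str, list[str]] = {}
    for gene, row in expr.iterrows():
        values = row.astype(float)
        if (values < min_expr).all():
            flags[str(gene)] = ["not expressed"]
            continue
        total = values.sum()
        specific = [str(t) for t, v in values.items() if total > 0 and v / total >= specificity_fraction]
        flags[str(gene)] = specific
    return flags
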
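"""Sex-bias fold-change stratification of top-expressed genes.

At each stage the most highly expressed genes (default 5,000, ranked by the
larger of the male and female normalized FPKM) are classified by the
between-sex fold change into four groups — unbiased (< 1.5), ×1.5–2.0,
×2.0–3.0 and ×3.0 and above — and summarised separately for autosomal and
Z-linked genes.  In a ZZ/ZW system with incomplete dosage compensation the
Z chromosome is expected to show an excess of male-biased genes at every
stage, which these tables make visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import STAGES, ExpressionMatrix

FOLD_CLASSES = ("unbiased", "fc1.5_2", "fc2_3", "fc3plus")
#: left-closed, right-open class boundaries on the fold-change axis
FOLD_BOUNDS = (1.5, 2.0, 3.0)


@dataclass(frozen=True)
class BiasClassification:
    gene_id: str
    stage: str
    direction: str  # male-biased / female-biased / unbiased
    fold_class: str
    fold_change: float
    chromosome_class: str


def classify_bias(
    m: float, f: float, pseudocount: float = 1.0
) -> tuple[str, str, float]:
    """Classify one gene's (male, female) expression pair at one stage.

    fold = (max + pc) / (min + pc); classes are [1, 1.5) unbiased,
    [1.5, 2) fc1.5_2, [2, 3) fc2_3, [3, ∞) fc3plus.  Direction follows the
    larger sex and is "unbiased" exactly when the class is.
    """
    if m < 0 or f < 0:
        raise ValueError("expression values must be non-negative")
    hi, lo = (m, f) if m >= f else (f, m)
    fold = (hi + pseudocount) / (lo + pseudocount)
    if fold < FOLD_BOUNDS[0]:
        return "unbiased", "unbiased", fold
    if fold < FOLD_BOUNDS[1]:
        cls = "fc1.5_2"
    elif fold < FOLD_BOUNDS[2]:
        cls = "fc2_3"
    else:
        cls = "fc3plus"
    direction = "male-biased" if m > f else "female-biased"
    return direction, cls, fold


def select_top_genes(
    matrix: ExpressionMatrix, stage: str, n: int = 5000
) -> list[str]:
    """Top ``n`` gene ids at a stage, ranked by max(male, female) FPKM.

    Ties are broken lexicographically by gene id so the selection is
    deterministic.  Returns min(n, total genes) ids.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    m = matrix.values[matrix.sample_id_for("male", stage)]
    f = matrix.values[matrix.sample_id_for("female", stage)]
    peak = pd.concat([m, f], axis=1).max(axis=1)
    order = sorted(zip(-peak.to_numpy(dtype=float), peak.index))
    return [gid for _, gid in order[:n]]


def classify_stage(
    matrix: ExpressionMatrix,
    stage: str,
    n: int = 5000,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Gene-level bias table for the top-``n`` genes at one stage."""
    top = select_top_genes(matrix, stage, n=n)
    m_col = matrix.values.loc[top, matrix.sample_id_for("male", stage)]
    f_col = matrix.values.loc[top, matrix.sample_id_for("female", stage)]
    chrom = matrix.chromosome_class_series().loc[top]
    rows = []
    for gid in top:
        direction, cls, fold = classify_bias(
            float(m_col[gid]), float(f_col[gid]), pseudocount
        )
        rows.append((gid, stage, direction, cls, fold, chrom[gid]))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "stage", "direction", "fold_class", "fold_change", "chromosome_class"],
    )


def bias_proportion_table(
    matrix: ExpressionMatrix,
    stages: list[str] | None = None,
    n: int = 5000,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Stratum-level summary: counts per fold class and threshold proportions.

    One row per (stage, chromosome_class, direction) with the count in each
    fold class and, for each threshold ×1.5 / ×2.0 / ×3.0, the proportion of
    the stratum's top genes at or above it in that direction.  Genes with
    chromosome class "unknown" or "W" contribute to totals but are not
    reported as strata (only autosome vs Z is summarised).
    """
    stages = list(stages) if stages is not None else [
        s for s in STAGES if matrix.has_sample("male", s) and matrix.has_sample("female", s)
    ]
    out = []
    for stage in stages:
        gene_table = classify_stage(matrix, stage, n=n, pseudocount=pseudocount)
        for chrom in ("autosome", "Z"):
            sub = gene_table[gene_table.chromosome_class == chrom]
            denom = len(sub)
            n_unbiased = int((sub.direction == "unbiased").sum())
            for direction in ("male-biased", "female-biased"):
                d = sub[sub.direction == direction]
                row = {
                    "stage": stage,
                    "chromosome_class": chrom,
                    "direction": direction,
                    "n_top_genes": denom,
                    "n_unbiased": n_unbiased,
                }
                for cls in FOLD_CLASSES[1:]:
                    row[f"n_{cls}"] = int((d.fold_class == cls).sum())
                for thr in FOLD_BOUNDS:
                    count = int((d.fold_change >= thr).sum())
                    row[f"prop_fc{thr:g}"] = count / denom if denom else np.nan
                out.append(row)
    return pd.DataFrame(out)
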
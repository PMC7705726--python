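"""Between-sample normalization and clustering pre-processing.

Two distinct jobs live here:

* **TMM scaling** — trimmed mean of M-values between-sample normalization,
  computed on FPKM columns.  M (log2 expression ratio) and A (average log2
  abundance) are formed from column-sum proportions; genes in the extreme
  tails of M and A are discarded and the factor is the precision-weighted
  mean of the surviving M values.  The per-sample factor stored here is the
  *effective* one — relative column mass times the trimmed-mean ratio —
  rescaled so the factors have geometric mean 1, so that dividing each
  column by its factor both equalises sequencing-depth-like differences and
  corrects compositional bias.

* **Clustering pre-processing** — quantile normalization across columns,
  log2 with a pseudocount, and per-gene z-scoring (per sex, over the three
  embryonic stages, by default), producing the trajectories that the
  up/flat/down pattern clustering consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import EMBRYONIC_STAGES, SEXES, ExpressionMatrix


@dataclass
class NormalizationFactors:
    """Per-sample TMM scaling factors, geometric mean 1."""

    factors: dict[str, float]
    reference_sample: str
    trim_m: float
    trim_a: float

    def __post_init__(self) -> None:
        vals = np.array(list(self.factors.values()), dtype=float)
        if (vals <= 0).any():
            raise ValueError("TMM factors must be positive")
        log_gm = np.mean(np.log(vals))
        if abs(log_gm) > 1e-9:
            raise ValueError("TMM factors must have geometric mean 1")
        for name, frac in (("trim_m", self.trim_m), ("trim_a", self.trim_a)):
            if not 0 < frac < 0.5:
                raise ValueError(f"{name} must lie in (0, 0.5)")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.factors),
                "factor": [self.factors[s] for s in self.factors],
                "is_reference": [s == self.reference_sample for s in self.factors],
            }
        )


@dataclass
class ZScoreMatrix:
    """Per-gene standardized log2 trajectories over the embryonic columns.

    Columns are ``"<sex>:<stage>"``.  ``constant`` flags rows whose values
    were constant within their standardization scope; those rows are set to
    z = 0 ("no change") rather than NaN.
    """

    values: pd.DataFrame
    scope: str
    constant: pd.DataFrame  # genes × scope-groups, boolean

    def column(self, sex: str, stage: str) -> pd.Series:
        return self.values[f"{sex}:{stage}"]


def _double_trimmed_mask(m: np.ndarray, a: np.ndarray, trim_m: float, trim_a: float) -> np.ndarray:
    """Keep genes inside the central (1 − 2·trim) rank band of both M and A."""
    n = len(m)
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    return (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)


def tmm_factors(
    matrix: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Compute TMM scaling factors over the FPKM columns.

    The reference sample is the one whose 75th-percentile expression
    proportion is closest to the across-sample mean of that percentile.
    For each other sample, M and A are computed over genes positive in both
    the sample and the reference, the top and bottom ``trim_m`` of genes by
    M and ``trim_a`` by A are discarded, and the factor is
    2**(weighted mean M) with inverse asymptotic binomial-variance weights.
    The returned factors fold in relative column mass and are rescaled to
    geometric mean 1.
    """
    X = matrix.values.to_numpy(dtype=float)
    sample_ids = matrix.sample_ids
    if X.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    colsum = X.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("every sample must have positive total expression")
    P = X / colsum  # proportions

    q75 = np.quantile(P, 0.75, axis=0)
    ref = int(np.argmin(np.abs(q75 - q75.mean())))

    log_ratio = np.zeros(X.shape[1])
    for k in range(X.shape[1]):
        if k == ref:
            continue
        both = (X[:, k] > 0) & (X[:, ref] > 0)
        if not both.any():
            raise ValueError(
                f"no genes positive in both sample {sample_ids[k]!r} and the reference"
            )
        pk, pr = P[both, k], P[both, ref]
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        keep = _double_trimmed_mask(m, a, trim_m, trim_a)
        if not keep.any():
            raise ValueError(
                "no genes survive the M/A trim; lower trim_m/trim_a for this matrix"
            )
        # asymptotic binomial variance of M on the proportion scale; a common
        # library-size factor is omitted so the weights depend only on the
        # proportions, which keeps the estimator exactly scale-invariant
        # (re-normalizing an already normalized matrix returns factors of 1)
        pk_keep, pr_keep = pk[keep], pr[keep]
        var = (1.0 - pk_keep) / pk_keep + (1.0 - pr_keep) / pr_keep
        w = 1.0 / var
        log_ratio[k] = float(np.sum(w * m[keep]) / np.sum(w))

    # effective factor: relative column mass × trimmed-mean ratio
    eff = np.log2(colsum) + log_ratio
    eff -= eff.mean()  # geometric mean 1
    factors = {sid: float(2.0 ** e) for sid, e in zip(sample_ids, eff)}
    return NormalizationFactors(
        factors=factors,
        reference_sample=sample_ids[ref],
        trim_m=trim_m,
        trim_a=trim_a,
    )


def apply_factors(matrix: ExpressionMatrix, factors: NormalizationFactors) -> ExpressionMatrix:
    """Divide each column by its scaling factor; marks the matrix normalized."""
    missing = [s for s in matrix.sample_ids if s not in factors.factors]
    if missing:
        raise KeyError(f"no factor for sample(s) {missing}")
    scaled = matrix.values / pd.Series(factors.factors)[matrix.sample_ids]
    return matrix.with_values(scaled, normalized=True)


def normalize_tmm(
    matrix: ExpressionMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    embryonic_only: bool = False,
) -> tuple[ExpressionMatrix, NormalizationFactors]:
    """Convenience wrapper: compute factors, apply them, return both.

    ``embryonic_only`` restricts factor estimation to the six embryonic
    columns; the adult columns are then scaled with factor 1 relative to
    their own column mass.  Default is joint estimation over all samples.
    """
    if embryonic_only:
        emb = matrix.embryonic_sample_ids()
        sub = ExpressionMatrix(
            values=matrix.values[emb],
            samples=[next(s for s in matrix.samples if s.sample_id == sid) for sid in emb],
            genes=list(matrix.genes),
            normalized=matrix.normalized,
        )
        factors_emb = tmm_factors(sub, trim_m=trim_m, trim_a=trim_a)
        full = dict(factors_emb.factors)
        for sid in matrix.sample_ids:
            full.setdefault(sid, 1.0)
        # re-centre to geometric mean 1 over all applied columns
        log_f = {k: math.log(v) for k, v in full.items()}
        shift = sum(log_f.values()) / len(log_f)
        full = {k: math.exp(v - shift) for k, v in log_f.items()}
        factors = NormalizationFactors(
            factors=full,
            reference_sample=factors_emb.reference_sample,
            trim_m=trim_m,
            trim_a=trim_a,
        )
    else:
        factors = tmm_factors(matrix, trim_m=trim_m, trim_a=trim_a)
    return apply_factors(matrix, factors), factors


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every column onto the common distribution of per-rank means.

    Each column's sorted value vector becomes the across-column mean of
    sorted values; ties within a column receive the mean of their ranks'
    target values (average-rank convention).
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two samples")
    target = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        ranks = stats.rankdata(X[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (target[lo] + target[hi])
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.with_values(values)


#: default lower bound on the per-gene standardization scale, in log2 units.
#: Standardizing a near-flat trajectory by its own (noise-dominated) standard
#: deviation inflates measurement noise to a full-amplitude shape; bounding the
#: scale from below keeps "no change" genes near z = 0.  Must stay below
#: sqrt(2/3) ≈ 0.816 so a clean two-fold-per-stage trajectory standardizes to
#: the usual ±sqrt(3/2).
SD_FLOOR = 0.75


def log_zscore(
    matrix: ExpressionMatrix,
    scope: str = "per-sex",
    pseudocount: float = 1.0,
    sd_floor: float = SD_FLOOR,
) -> ZScoreMatrix:
    """log2(x + pseudocount), then per-gene z-score over the embryonic columns.

    ``scope="per-sex"`` standardizes each gene separately within each sex's
    three embryonic stages (so each sex's trajectory shape is compared on
    its own scale); ``scope="across-sexes"`` standardizes over all six
    embryonic columns jointly.  The divisor is max(row sd, ``sd_floor``);
    pass ``sd_floor=0`` for plain standardization.  Rows constant within
    their scope get z = 0 and a flag.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if sd_floor < 0:
        raise ValueError("sd_floor must be non-negative")
    if scope not in ("per-sex", "across-sexes"):
        raise ValueError(f"unknown z-score scope {scope!r}")

    cols = {}
    for sex in SEXES:
        for stage in EMBRYONIC_STAGES:
            sid = matrix.sample_id_for(sex, stage)
            cols[f"{sex}:{stage}"] = np.log2(
                matrix.values[sid].to_numpy(dtype=float) + pseudocount
            )
    L = pd.DataFrame(cols, index=matrix.values.index)

    if scope == "per-sex":
        groups = {sex: [f"{sex}:{st}" for st in EMBRYONIC_STAGES] for sex in SEXES}
    else:
        groups = {"all": list(L.columns)}

    Z = pd.DataFrame(index=L.index, columns=L.columns, dtype=float)
    constant = pd.DataFrame(False, index=L.index, columns=list(groups))
    for gname, gcols in groups.items():
        block = L[gcols].to_numpy()
        mean = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        const = sd[:, 0] < 1e-12
        scale = np.maximum(sd, sd_floor)
        scale[const, :] = 1.0
        z = (block - mean) / scale
        z[const, :] = 0.0
        Z[gcols] = z
        constant[gname] = const
    return ZScoreMatrix(values=Z, scope=scope, constant=constant)
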
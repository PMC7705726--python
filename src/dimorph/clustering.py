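"""Stage-pattern classification of expression trajectories.

Each expressed gene's standardized log2 trajectory over the three embryonic
stages (HH27 → HH31 → HH38) is reduced to two differences,
Δ1 = z(HH31) − z(HH27) and Δ2 = z(HH38) − z(HH31).  Within each sex and
each transition the genes are split into three groups by k-means on the
one-dimensional Δ values, relabelled by centroid order as up / flat / down,
and the pair of labels places the gene in one of nine clusters laid out on
a 3 × 3 grid:

    =========  ====  =====  =====
    Δ1 \\ Δ2    up    flat   down
    =========  ====  =====  =====
    up          1      2      3
    flat        4      5      6
    down        7      8      9
    =========  ====  =====  =====

Cluster 2 (up then flat) is the pattern followed by the canonical gonadal
sex-differentiation genes (DMRT1, SOX9, AMH in males; FOXL2, CYP19A1 in
females), and its sexually dimorphic members are the candidate genes the
pipeline reports.

For one-dimensional data the k-means optimum is attained by a contiguous
partition of the sorted values, so the default backend solves it exactly by
enumerating the two breakpoints; Lloyd's algorithm (scikit-learn) is
available as an alternative backend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dimorphism import classify_bias
from .model import EMBRYONIC_STAGES, SEXES, ExpressionMatrix
from .normalization import ZScoreMatrix, log_zscore, quantile_normalize

LABELS = ("up", "flat", "down")

#: (label for Δ1, label for Δ2) → cluster id on the 3×3 grid
CLUSTER_GRID = {
    ("up", "up"): 1,
    ("up", "flat"): 2,
    ("up", "down"): 3,
    ("flat", "up"): 4,
    ("flat", "flat"): 5,
    ("flat", "down"): 6,
    ("down", "up"): 7,
    ("down", "flat"): 8,
    ("down", "down"): 9,
}


def filter_expressed(matrix: ExpressionMatrix, threshold: float = 30.0) -> set[str]:
    """Genes whose maximum over the six embryonic columns is ≥ ``threshold``.

    The threshold is on TMM-normalized FPKM; a gene passing in a single
    sample is kept ("at least one of six samples").
    """
    if not matrix.normalized:
        raise ValueError("filter_expressed expects a TMM-normalized matrix")
    emb = matrix.embryonic_sample_ids()
    peak = matrix.values[emb].max(axis=1)
    return set(peak.index[peak >= threshold])


def stage_deltas(z: ZScoreMatrix, sex: str) -> pd.DataFrame:
    """Per-gene (delta_1, delta_2) for one sex: HH31−HH27 and HH38−HH31."""
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    for stage in EMBRYONIC_STAGES:
        if f"{sex}:{stage}" not in z.values.columns:
            raise KeyError(f"z-score matrix lacks stage {stage} for sex {sex}")
    d1 = z.column(sex, "HH31") - z.column(sex, "HH27")
    d2 = z.column(sex, "HH38") - z.column(sex, "HH31")
    return pd.DataFrame({"delta_1": d1, "delta_2": d2})


def exact_kmeans3_1d(x: np.ndarray) -> np.ndarray:
    """Globally optimal 3-means partition of 1-D data.

    An optimal k-means partition of scalars is contiguous in sorted order,
    so it suffices to enumerate the two breakpoints.  Segment SSEs come
    from prefix sums, and the enumeration over the second breakpoint is
    vectorised, giving O(n²) time with small constants.  Returns integer
    group ids 0/1/2 in ascending value order.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.concatenate([[0.0], np.cumsum(xs)])
    s2 = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def seg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        # SSE of xs[a:b]
        cnt = b - a
        tot = s1[b] - s1[a]
        return (s2[b] - s2[a]) - tot * tot / cnt

    best_sse = np.inf
    best = (1, 2)
    js = np.arange(2, n)  # candidate second breakpoints
    for i in range(1, n - 1):
        jj = js[js > i]
        sse = seg(np.array([0]), np.array([i]))[0] + seg(np.full(len(jj), i), jj) + seg(jj, np.full(len(jj), n))
        k = int(np.argmin(sse))
        if sse[k] < best_sse - 1e-12:
            best_sse = float(sse[k])
            best = (i, int(jj[k]))
    i, j = best
    groups = np.empty(n, dtype=int)
    groups[order[:i]] = 0
    groups[order[i:j]] = 1
    groups[order[j:]] = 2
    return groups


#: half-width of the delta band whose cluster centroids are called "flat".
#: Pure centroid ordering would force one "up" and one "down" group even on
#: signal-free data; a centroid within ±FLAT_BAND z-units of zero means the
#: group shows no meaningful change between the stages.
FLAT_BAND = 0.5


def kmeans3_labels(
    deltas: np.ndarray | pd.Series,
    seed: int = 0,
    restarts: int = 10,
    backend: str = "exact",
    flat_band: float = FLAT_BAND,
) -> np.ndarray:
    """Split 1-D delta values into up / flat / down by 3-means.

    The three groups are named by their centroids: centroid > ``flat_band``
    → "up", centroid < −``flat_band`` → "down", otherwise "flat" (with
    ``flat_band=0`` this reduces to ordering: largest → up, smallest →
    down).  ``backend="exact"`` (default) uses the provably optimal
    contiguous-partition solver and ignores the seed; ``backend="lloyd"``
    runs scikit-learn's k-means with ``restarts`` seeded initialisations
    and keeps the best inertia.
    """
    index = deltas.index if isinstance(deltas, pd.Series) else None
    x = np.asarray(deltas, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            "fewer than 3 distinct delta values; label the genes trivially instead"
        )
    if backend == "exact":
        groups = exact_kmeans3_1d(x)
    elif backend == "lloyd":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=3, n_init=restarts, random_state=seed)
        groups = km.fit_predict(x.reshape(-1, 1))
    else:
        raise ValueError(f"unknown backend {backend!r}")

    centroids = np.array([x[groups == g].mean() for g in range(3)])
    if flat_band > 0:
        names = np.where(
            centroids > flat_band, "up", np.where(centroids < -flat_band, "down", "flat")
        )
        label_of = dict(enumerate(names))
    else:
        # descending centroid → up, flat, down
        label_of = {g: LABELS[rank] for rank, g in enumerate(np.argsort(-centroids))}
    labels = np.array([label_of[g] for g in groups], dtype=object)
    if index is not None:
        return pd.Series(labels, index=index)
    return labels


def assign_clusters(labels_1: pd.Series, labels_2: pd.Series) -> pd.Series:
    """Combine the two transition labels into the 1–9 cluster id."""
    if not labels_1.index.equals(labels_2.index):
        raise ValueError("transition label vectors cover different genes")
    return pd.Series(
        [CLUSTER_GRID[(l1, l2)] for l1, l2 in zip(labels_1, labels_2)],
        index=labels_1.index,
        name="cluster",
    )


@dataclass
class PatternResult:
    """Per-sex pattern table plus the inputs that produced it."""

    assignments: pd.DataFrame  # gene_id, sex, delta_1, delta_2, label_1, label_2, cluster
    filtered_genes: list[str]
    zscores: ZScoreMatrix


def cluster_patterns(
    matrix: ExpressionMatrix,
    threshold: float = 30.0,
    scope: str = "per-sex",
    pseudocount: float = 1.0,
    backend: str = "exact",
    seed: int = 0,
    restarts: int = 10,
    sd_floor: float | None = None,
    flat_band: float = FLAT_BAND,
) -> PatternResult:
    """Full pattern-classification chain for a TMM-normalized matrix.

    Filter (≥ ``threshold`` FPKM in ≥ 1 of the six embryonic samples) →
    quantile-normalize the six embryonic columns → log2 → per-gene z-score
    → per-sex, per-transition 3-means → nine-cluster assignment.
    """
    kept = sorted(filter_expressed(matrix, threshold=threshold))
    if not kept:
        raise ValueError("no genes pass the expression filter")
    sub = matrix.subset_genes(kept)
    emb = sub.embryonic_sample_ids()
    emb_matrix = ExpressionMatrix(
        values=sub.values[emb],
        samples=[next(s for s in sub.samples if s.sample_id == sid) for sid in emb],
        genes=list(sub.genes),
        normalized=sub.normalized,
    )
    qn = quantile_normalize(emb_matrix)
    zkw = {} if sd_floor is None else {"sd_floor": sd_floor}
    z = log_zscore(qn, scope=scope, pseudocount=pseudocount, **zkw)

    frames = []
    for sex in SEXES:
        d = stage_deltas(z, sex)
        l1 = kmeans3_labels(
            d["delta_1"], seed=seed, restarts=restarts, backend=backend, flat_band=flat_band
        )
        l2 = kmeans3_labels(
            d["delta_2"], seed=seed, restarts=restarts, backend=backend, flat_band=flat_band
        )
        cluster = assign_clusters(l1, l2)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": d.index,
                    "sex": sex,
                    "delta_1": d["delta_1"].to_numpy(),
                    "delta_2": d["delta_2"].to_numpy(),
                    "label_1": l1.to_numpy(),
                    "label_2": l2.to_numpy(),
                    "cluster": cluster.to_numpy(),
                }
            )
        )
    assignments = pd.concat(frames, ignore_index=True)
    return PatternResult(assignments=assignments, filtered_genes=kept, zscores=z)


def select_candidates(
    assignments: pd.DataFrame,
    matrix: ExpressionMatrix,
    cluster: int = 2,
    stage: str = "HH31",
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Sexually dimorphic members of one cluster.

    For each sex, genes assigned to ``cluster`` in that sex whose
    between-sex fold change at ``stage`` is ≥ ``min_fold`` in that sex's
    direction.  Fold change uses the same pseudocount convention as the
    bias classification.
    """
    m_col = matrix.values[matrix.sample_id_for("male", stage)]
    f_col = matrix.values[matrix.sample_id_for("female", stage)]
    rows = []
    for sex in SEXES:
        in_cluster = assignments[(assignments.sex == sex) & (assignments.cluster == cluster)]
        for gid in in_cluster.gene_id:
            direction, _, fold = classify_bias(
                float(m_col[gid]), float(f_col[gid]), pseudocount
            )
            wanted = "male-biased" if sex == "male" else "female-biased"
            if fold >= min_fold and direction == wanted:
                rows.append((gid, sex, cluster, fold))
    return pd.DataFrame(
        rows, columns=["gene_id", "sex", "cluster", f"fold_change_at_{stage}"]
    )
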
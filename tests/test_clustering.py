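"""Expression filter, delta computation, 3-means labelling and the 3×3 grid."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dimorph.clustering import (
    CLUSTER_GRID,
    assign_clusters,
    cluster_patterns,
    exact_kmeans3_1d,
    filter_expressed,
    kmeans3_labels,
    select_candidates,
    stage_deltas,
)
from dimorph.normalization import log_zscore, normalize_tmm  # noqa: F401 (normalize_tmm used in fixtures)
from dimorph.synthetic import SyntheticSpec, generate, score_cluster_recovery

from conftest import full_design_matrix


# -- independent oracle: exhaustive contiguous 3-splits of sorted values ------

def optimal_sse_bruteforce(x):
    xs = np.sort(np.asarray(x, dtype=float))
    n = len(xs)

    def sse(seg):
        return float(((seg - seg.mean()) ** 2).sum()) if len(seg) else 0.0

    best = np.inf
    for i in range(1, n - 1):
        for j in range(i + 1, n):
            best = min(best, sse(xs[:i]) + sse(xs[i:j]) + sse(xs[j:]))
    return best


def partition_sse(x, groups):
    x = np.asarray(x, dtype=float)
    return sum(
        float(((x[groups == g] - x[groups == g].mean()) ** 2).sum())
        for g in np.unique(groups)
    )


# -- filter -------------------------------------------------------------------

def _matrix_with_embryonic(male_rows, female_rows=None):
    male_rows = np.asarray(male_rows, dtype=float)
    female_rows = male_rows if female_rows is None else np.asarray(female_rows, dtype=float)
    cols = {}
    for i, stage in enumerate(("HH27", "HH31", "HH38")):
        cols[("male", stage)] = np.log2(male_rows[:, i])
        cols[("female", stage)] = np.log2(female_rows[:, i])
    cols[("male", "adult")] = np.log2(male_rows[:, 0])
    cols[("female", "adult")] = np.log2(female_rows[:, 0])
    return full_design_matrix(cols)


def test_filter_keeps_single_sample_peak_and_drops_near_misses():
    matrix = _matrix_with_embryonic(
        [[0.001, 0.001, 31.0], [29.9, 29.9, 29.9], [30.0, 1.0, 1.0]]
    )
    kept = filter_expressed(matrix)
    assert kept == {"g0", "g2"}


def test_filter_requires_normalized_matrix():
    matrix = _matrix_with_embryonic([[31.0, 1.0, 1.0]])
    matrix.normalized = False
    with pytest.raises(ValueError, match="normalized"):
        filter_expressed(matrix)


def test_filter_recovers_planted_expressed_set_at_study_scale():
    """A 9×535-gene planted matrix yields exactly its 4,815 expressed genes."""
    spec = SyntheticSpec(
        seed=2, n_genes_per_cluster=535, n_background_genes=0,
        n_bias_genes_per_class=0, dimorphic_counts={"male": 0, "female": 0},
        below_threshold_genes=200,
    )
    data = generate(spec)
    normalized, _ = normalize_tmm(data.matrix)
    kept = filter_expressed(normalized)
    truth = data.truth
    assert len(kept) == 9 * 535 == 4815
    assert kept == set(truth.gene_id[truth.above_filter])


# -- deltas -------------------------------------------------------------------

def test_stage_deltas_basics():
    matrix = _matrix_with_embryonic([[1000.0, 2000.0, 4000.0], [50.0, 50.0, 50.0]])
    z = log_zscore(matrix)
    d = stage_deltas(z, "male")
    assert d.loc["g0", "delta_1"] == pytest.approx(1.2247, abs=1e-3)
    assert d.loc["g0", "delta_2"] == pytest.approx(1.2247, abs=1e-3)
    assert d.loc["g1"].tolist() == [0.0, 0.0]
    with pytest.raises(ValueError, match="unknown sex"):
        stage_deltas(z, "hermaphrodite")


def test_stage_deltas_antisymmetric_under_stage_reversal():
    rng = np.random.default_rng(0)
    fwd = rng.uniform(4, 12, size=(10, 3))
    rev = fwd[:, ::-1]
    d_f = stage_deltas(log_zscore(_matrix_with_embryonic(fwd)), "male")
    d_r = stage_deltas(log_zscore(_matrix_with_embryonic(rev)), "male")
    assert np.allclose(d_f["delta_1"], -d_r["delta_2"], atol=1e-9)
    assert np.allclose(d_f["delta_2"], -d_r["delta_1"], atol=1e-9)


# -- 3-means ------------------------------------------------------------------

def test_kmeans3_separated_packets_labelled_by_sign():
    rng = np.random.default_rng(1)
    deltas = np.concatenate(
        [rng.normal(-2, 0.1, 100), rng.normal(0, 0.1, 100), rng.normal(2, 0.1, 100)]
    )
    labels = kmeans3_labels(deltas)
    want = np.array(["down"] * 100 + ["flat"] * 100 + ["up"] * 100)
    assert (labels == want).all()


def test_kmeans3_translation_leaves_partition_unchanged():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1.5, 60)
    base = kmeans3_labels(x, flat_band=0.0)
    shifted = kmeans3_labels(x + 7.3, flat_band=0.0)
    # same partition: group co-membership is identical
    for a, b in itertools.combinations(range(60), 2):
        assert (base[a] == base[b]) == (shifted[a] == shifted[b])


@pytest.mark.parametrize("seed", range(10))
def test_exact_solver_attains_bruteforce_optimum(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 13)
    x = rng.normal(0, 1, n)
    groups = exact_kmeans3_1d(x)
    assert partition_sse(x, groups) == pytest.approx(optimal_sse_bruteforce(x), abs=1e-9)


def test_lloyd_backend_agrees_with_exact_on_separated_data():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(c, 0.15, 50) for c in (-2, 0, 2)])
    exact = kmeans3_labels(x, backend="exact")
    lloyd = kmeans3_labels(x, backend="lloyd", seed=0, restarts=10)
    assert (exact == lloyd).all()


def test_kmeans3_rejects_degenerate_input():
    with pytest.raises(ValueError, match="distinct"):
        kmeans3_labels(np.array([1.0, 1.0, 2.0, 2.0]))
    with pytest.raises(ValueError, match="backend"):
        kmeans3_labels(np.array([1.0, 2.0, 3.0]), backend="quantum")


# -- grid assignment ----------------------------------------------------------

@pytest.mark.parametrize(
    "l1,l2,cluster", [(l1, l2, c) for (l1, l2), c in CLUSTER_GRID.items()]
)
def test_grid_assignment(l1, l2, cluster):
    got = assign_clusters(pd.Series([l1], index=["g"]), pd.Series([l2], index=["g"]))
    assert got["g"] == cluster


def test_grid_anchors_match_pattern_table():
    # up–flat is cluster 2, flat–flat cluster 5, down–down cluster 9
    assert CLUSTER_GRID[("up", "flat")] == 2
    assert CLUSTER_GRID[("flat", "flat")] == 5
    assert CLUSTER_GRID[("down", "down")] == 9


def test_assign_clusters_rejects_mismatched_genes():
    with pytest.raises(ValueError, match="different genes"):
        assign_clusters(
            pd.Series(["up"], index=["a"]), pd.Series(["up"], index=["b"])
        )


# -- candidates and the full chain -------------------------------------------

def test_candidate_fold_arithmetic():
    matrix = _matrix_with_embryonic(
        [[100, 200, 200], [100, 60, 60]], [[100, 50, 50], [100, 50, 50]]
    )
    assignments = pd.DataFrame(
        {
            "gene_id": ["g0", "g1", "g0", "g1"],
            "sex": ["male", "male", "female", "female"],
            "cluster": [2, 2, 5, 5],
        }
    )
    selected = select_candidates(assignments, matrix)
    assert list(selected.gene_id) == ["g0"]
    # (200+1)/(50+1) with the default pseudocount
    assert selected.fold_change_at_HH31.iloc[0] == pytest.approx(201 / 51)


def test_cluster_ids_partition_filtered_genes(default_bundle, default_normalized):
    matrix, _ = default_normalized
    result = cluster_patterns(matrix)
    n_filtered = len(result.filtered_genes)
    counts = result.assignments.groupby("sex").cluster.agg(["count", lambda c: c.isin(range(1, 10)).all()])
    for sex in ("male", "female"):
        assert counts.loc[sex, "count"] == n_filtered
        assert bool(counts.loc[sex].iloc[1])
    per_sex_gene = result.assignments.groupby(["gene_id", "sex"]).size()
    assert (per_sex_gene == 1).all()


def test_planted_pattern_recovery_and_candidates(default_bundle, default_normalized):
    matrix, _ = default_normalized
    result = cluster_patterns(matrix)
    recovery = score_cluster_recovery(default_bundle.truth, result.assignments)
    assert recovery >= 0.95
    candidates = select_candidates(result.assignments, matrix)
    truth = default_bundle.truth
    for sex, want in (("male", 52), ("female", 40)):
        got = set(candidates.gene_id[candidates.sex == sex])
        planted = set(truth.gene_id[(truth.is_candidate) & (truth.candidate_sex == sex)])
        assert got == planted
        assert len(got) == want
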
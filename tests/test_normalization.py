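"""TMM factors, quantile normalization and the log/z-score chain."""

import numpy as np
import pytest

from dimorph.model import EMBRYONIC_STAGES, SEXES
from dimorph.normalization import (
    NormalizationFactors,
    apply_factors,
    log_zscore,
    quantile_normalize,
    tmm_factors,
)

from conftest import full_design_matrix, make_matrix


# -- independent brute-force TMM oracle -------------------------------------

def tmm_oracle(X, trim_m=0.30, trim_a=0.05):
    """Direct evaluation of the doubly trimmed, precision-weighted mean of M.

    Written without rank shortcuts: genes are sorted by M and by A and the
    central bands intersected explicitly; the weighted mean uses an explicit
    Python loop.  Returns effective factors with geometric mean 1.
    """
    X = np.asarray(X, dtype=float)
    n_samples = X.shape[1]
    colsum = X.sum(axis=0)
    P = X / colsum
    q75 = [np.quantile(P[:, j], 0.75) for j in range(n_samples)]
    ref = min(range(n_samples), key=lambda j: abs(q75[j] - np.mean(q75)))

    log_eff = []
    for k in range(n_samples):
        if k == ref:
            log_eff.append(np.log2(colsum[k]))
            continue
        genes = [g for g in range(X.shape[0]) if X[g, k] > 0 and X[g, ref] > 0]
        M = {g: np.log2(P[g, k] / P[g, ref]) for g in genes}
        A = {g: 0.5 * np.log2(P[g, k] * P[g, ref]) for g in genes}
        n = len(genes)
        by_m = sorted(genes, key=lambda g: M[g])
        by_a = sorted(genes, key=lambda g: A[g])
        lo_m = int(np.floor(n * trim_m) + 1)
        lo_a = int(np.floor(n * trim_a) + 1)
        keep_m = set(by_m[lo_m - 1 : n + 1 - lo_m])
        keep_a = set(by_a[lo_a - 1 : n + 1 - lo_a])
        keep = keep_m & keep_a
        num = den = 0.0
        for g in keep:
            var = (1.0 - P[g, k]) / P[g, k] + (1.0 - P[g, ref]) / P[g, ref]
            num += M[g] / var
            den += 1.0 / var
        log_eff.append(np.log2(colsum[k]) + num / den)
    log_eff = np.array(log_eff) - np.mean(log_eff)
    return 2.0 ** log_eff


def random_matrix(rng, n_genes=20, n_samples=3, composition_gene=True):
    X = 2.0 ** rng.normal(7, 1.5, size=(n_genes, n_samples))
    if composition_gene:
        X[0, 0] *= 50  # one high-abundance gene distorting sample 0's total
    return X


def test_identical_columns_give_unit_factors():
    col = np.array([5.0, 10.0, 80.0, 40.0])
    matrix = make_matrix(np.stack([col, col], axis=1))
    factors = tmm_factors(matrix)
    assert factors.factors == pytest.approx({"M_HH27": 1.0, "M_HH31": 1.0})


def test_pure_column_scaling_fully_corrected():
    rng = np.random.default_rng(7)
    col = 2.0 ** rng.normal(7, 1.5, 30)
    matrix = make_matrix(np.stack([col, 2 * col], axis=1))
    normalized = apply_factors(matrix, tmm_factors(matrix))
    a, b = normalized.values.iloc[:, 0], normalized.values.iloc[:, 1]
    assert np.allclose(a, b, rtol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_tmm_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    X = random_matrix(rng)
    matrix = make_matrix(X)
    got = np.array(list(tmm_factors(matrix).factors.values()))
    want = tmm_oracle(X)
    assert np.allclose(got, want, atol=1e-6)


def test_tmm_scale_and_permutation_invariance():
    rng = np.random.default_rng(11)
    X = random_matrix(rng)
    base = np.array(list(tmm_factors(make_matrix(X)).factors.values()))
    scaled = np.array(list(tmm_factors(make_matrix(3.7 * X)).factors.values()))
    assert np.allclose(base, scaled, atol=1e-9)
    perm = rng.permutation(X.shape[0])
    permuted = np.array(list(tmm_factors(make_matrix(X[perm])).factors.values()))
    assert np.allclose(base, permuted, atol=1e-12)


def test_tmm_fixed_point_after_applying_factors():
    rng = np.random.default_rng(3)
    X = random_matrix(rng, n_genes=40, n_samples=4)
    matrix = make_matrix(X)
    normalized = apply_factors(matrix, tmm_factors(matrix))
    again = tmm_factors(normalized)
    assert np.allclose(list(again.factors.values()), 1.0, atol=1e-6)


def test_tmm_errors():
    with pytest.raises(ValueError, match="two samples"):
        tmm_factors(make_matrix([[1.0], [2.0]]))
    factors = NormalizationFactors(
        factors={"M_HH27": 2.0, "M_HH31": 0.5}, reference_sample="M_HH27",
        trim_m=0.3, trim_a=0.05,
    )
    with pytest.raises(KeyError, match="no factor"):
        apply_factors(make_matrix([[1.0, 2.0, 3.0]],
                                  sample_pairs=[("male", "HH27"), ("male", "HH31"), ("male", "HH38")]),
                      factors)


def test_factor_invariants_enforced():
    with pytest.raises(ValueError, match="geometric mean"):
        NormalizationFactors({"a": 2.0, "b": 2.0}, "a", 0.3, 0.05)
    with pytest.raises(ValueError, match="positive"):
        NormalizationFactors({"a": -1.0, "b": 1.0}, "a", 0.3, 0.05)


# -- quantile normalization ---------------------------------------------------

def test_quantile_normalize_identical_columns_unchanged():
    col = np.array([4.0, 1.0, 9.0])
    matrix = make_matrix(np.stack([col, col], axis=1))
    out = quantile_normalize(matrix)
    assert np.allclose(out.values.to_numpy(), matrix.values.to_numpy())


def test_quantile_normalize_reversed_ranks_hand_example():
    # columns (1,2,3,4) and (8,7,6,5): sorted-mean target is (3,4,5,6)
    matrix = make_matrix(np.array([[1, 8], [2, 7], [3, 6], [4, 5]], dtype=float))
    out = quantile_normalize(matrix).values.to_numpy()
    assert np.allclose(out[:, 0], [3, 4, 5, 6])
    assert np.allclose(out[:, 1], [6, 5, 4, 3])


def test_quantile_normalize_equalizes_distributions_and_is_idempotent():
    rng = np.random.default_rng(5)
    matrix = make_matrix(2.0 ** rng.normal(6, 2, size=(50, 4)))
    once = quantile_normalize(matrix)
    X = once.values.to_numpy()
    for j in range(1, X.shape[1]):
        assert np.allclose(np.sort(X[:, 0]), np.sort(X[:, j]), atol=1e-12)
    twice = quantile_normalize(once)
    assert np.allclose(twice.values.to_numpy(), X, atol=1e-12)


def test_quantile_normalize_ties_get_mean_of_rank_targets():
    # sorted-mean target = (5.5, 10.5, 18.5, 24.5); the tied pair in column 0
    # occupies ranks 1–2 and receives their target mean, (5.5 + 10.5) / 2
    matrix = make_matrix(np.array([[1, 10], [1, 20], [7, 30], [9, 40]], dtype=float))
    out = quantile_normalize(matrix).values.to_numpy()
    assert np.allclose(out[:, 0], [8.0, 8.0, 18.5, 24.5])
    assert np.allclose(out[:, 1], [5.5, 10.5, 18.5, 24.5])


# -- log2 + z-score -----------------------------------------------------------

def _trajectory_matrix(male_log2, female_log2=None):
    """Full 8-column design from per-stage log2 levels for one gene."""
    if female_log2 is None:
        female_log2 = male_log2
    cols = {}
    for sex, levels in (("male", male_log2), ("female", female_log2)):
        for stage, level in zip(EMBRYONIC_STAGES, levels):
            cols[(sex, stage)] = [level]
        cols[(sex, "adult")] = [levels[0]]
    return full_design_matrix(cols)


def test_constant_row_flagged_and_zeroed():
    matrix = _trajectory_matrix([np.log2(30)] * 3)
    z = log_zscore(matrix)
    assert np.allclose(z.values.to_numpy(), 0.0)
    assert bool(z.constant.loc["g0", "male"]) and bool(z.constant.loc["g0", "female"])


def test_doubling_steps_standardize_to_sqrt_three_halves():
    a = 1000.0
    matrix = _trajectory_matrix(np.log2([a, 2 * a, 4 * a]))
    z = log_zscore(matrix)
    male = [z.column("male", s).iloc[0] for s in EMBRYONIC_STAGES]
    assert male == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-3)


def test_scope_changes_result_when_sexes_differ():
    matrix = _trajectory_matrix(np.log2([100, 200, 400]), np.log2([800, 400, 100]))
    per_sex = log_zscore(matrix, scope="per-sex")
    joint = log_zscore(matrix, scope="across-sexes")
    assert not np.allclose(per_sex.values.to_numpy(), joint.values.to_numpy())


def test_rows_above_floor_have_mean_zero_sd_one():
    rng = np.random.default_rng(2)
    cols = {}
    levels = rng.normal(8, 2, size=(30, 3))  # wide trajectories, sd >> floor
    for sex in SEXES:
        for i, stage in enumerate(EMBRYONIC_STAGES):
            cols[(sex, stage)] = levels[:, i]
        cols[(sex, "adult")] = levels[:, 0]
    matrix = full_design_matrix(cols)
    z = log_zscore(matrix)
    for sex in SEXES:
        log_in = np.stack(
            [
                np.log2(matrix.values[matrix.sample_id_for(sex, s)].to_numpy() + 1.0)
                for s in EMBRYONIC_STAGES
            ],
            axis=1,
        )
        above = log_in.std(axis=1, ddof=0) > 0.76  # strictly above the floor
        assert above.sum() > 20
        block = np.stack([z.column(sex, s).to_numpy() for s in EMBRYONIC_STAGES], axis=1)
        assert np.allclose(block[above].mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(block[above].std(axis=1, ddof=0), 1.0, atol=1e-9)


def test_low_variance_rows_are_shrunk_not_amplified():
    """A near-flat noisy trajectory must not standardize to a full shape."""
    matrix = _trajectory_matrix([8.0, 8.05, 7.95])
    z = log_zscore(matrix)
    assert np.abs(z.values.to_numpy()).max() < 0.1


def test_zscore_rejects_bad_parameters():
    matrix = _trajectory_matrix([5.0, 6.0, 7.0])
    with pytest.raises(ValueError, match="pseudocount"):
        log_zscore(matrix, pseudocount=0.0)
    with pytest.raises(ValueError, match="scope"):
        log_zscore(matrix, scope="weird")
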
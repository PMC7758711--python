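"""Unit and property tests for the trajectory-analysis core."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecoevo.errors import DegenerateTrajectoryError, DesignError
from ecoevo.phenotraj import (
    PhenotypeTable,
    build_trajectories,
    direction_angle,
    fit_factorial_model,
    pairwise_trajectory_tests,
    path_length,
    pca_of_fitted,
    rrpp_interaction_test,
    shape_distance,
    _summarize_perm,
)
from conftest import make_phenotype_table


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def test_ls_means_equal_cell_means_on_balanced_noise_free_design():
    cells = {("A", 1): [0.0, 0.0], ("A", 2): [0.0, 0.0],
             ("B", 1): [0.0, 0.0], ("B", 2): [1.0, 1.0]}
    fit = fit_factorial_model(make_phenotype_table(cells))
    assert np.allclose(fit.ls_means["A"], [[0.0], [0.0]], atol=1e-12)
    assert np.allclose(fit.ls_means["B"], [[0.0], [1.0]], atol=1e-12)


def test_fitted_plus_residuals_reconstructs_observed(multivariate_table):
    fit = fit_factorial_model(multivariate_table)
    assert np.max(np.abs(fit.fitted + fit.residuals - fit.response)) < 1e-8
    # residuals orthogonal to the design columns
    assert np.abs(fit.residuals.mean(axis=0)).max() < 1e-10


def test_univariate_interaction_ss_matches_textbook_two_way_anova(balanced_univariate):
    """Sequential multivariate SS collapses to the classical decomposition at p=1."""
    fit = fit_factorial_model(balanced_univariate)
    meta, y = balanced_univariate.wide()
    y = y.ravel()
    treat = meta["treatment"].to_numpy()
    time = meta["transfer"].to_numpy()
    grand = y.mean()
    # balanced design: textbook cell/margin formulas
    ss_a = sum(
        (y[treat == a].mean() - grand) ** 2 * (treat == a).sum() for a in np.unique(treat)
    )
    ss_b = sum(
        (y[time == b].mean() - grand) ** 2 * (time == b).sum() for b in np.unique(time)
    )
    ss_cells = sum(
        ((y[(treat == a) & (time == b)].mean() - grand) ** 2) * ((treat == a) & (time == b)).sum()
        for a in np.unique(treat) for b in np.unique(time)
    )
    ss_int = ss_cells - ss_a - ss_b
    assert fit.ss["treatment"] == pytest.approx(ss_a, abs=1e-8)
    assert fit.ss["time"] == pytest.approx(ss_b, abs=1e-8)
    assert fit.ss["interaction"] == pytest.approx(ss_int, abs=1e-8)


def test_empty_cell_is_rejected_by_name():
    cells = {("A", 1): [0.0, 1.0], ("A", 2): [0.0, 1.0], ("B", 1): [0.0, 1.0]}
    with pytest.raises(DesignError, match="treatment='B', transfer=2"):
        fit_factorial_model(make_phenotype_table(cells))


def test_single_observation_per_cell_is_rejected():
    cells = {("A", 1): [0.0], ("A", 2): [0.0], ("B", 1): [0.0], ("B", 2): [1.0]}
    with pytest.raises(DesignError):
        fit_factorial_model(make_phenotype_table(cells))


# ---------------------------------------------------------------------------
# RRPP interaction test
# ---------------------------------------------------------------------------

def test_observed_f_equals_classical_interaction_f_univariate(balanced_univariate):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = balanced_univariate.data.pivot_table(
        index=["replicate_id", "treatment", "transfer"], columns="substrate",
        values="value").reset_index().rename(columns={"s1": "y"})
    lm = smf.ols("y ~ C(treatment) * C(transfer)", data=df).fit()
    table = sm.stats.anova_lm(lm, typ=1)
    f_classic = table.loc["C(treatment):C(transfer)", "F"]
    res = rrpp_interaction_test(balanced_univariate, n_permutations=9, seed=1)
    assert res.observed == pytest.approx(f_classic, abs=1e-8)


def test_observed_f_is_permutation_free(multivariate_table):
    r1 = rrpp_interaction_test(multivariate_table, 19, seed=1)
    r2 = rrpp_interaction_test(multivariate_table, 77, seed=999)
    assert r1.observed == r2.observed


def test_permutation_p_equals_complete_enumeration():
    """Monte-Carlo p with all n!-1 non-identity permutations equals exact enumeration.

    The oracle recomputes, for every permutation of the reduced-model
    residuals, the classical balanced two-way ANOVA interaction F from
    margin/cell means -- fully independent of the package's projection
    algebra.
    """
    cells = {("A", 1): [0.3, 1.1], ("A", 2): [0.9, 0.2],
             ("B", 1): [0.5, 2.0], ("B", 2): [1.4, 0.7]}
    table = make_phenotype_table(cells)
    meta, y = table.wide()
    y = y.ravel()
    treat = meta["treatment"].to_numpy()
    time = meta["transfer"].to_numpy()
    n = len(y)

    # additive (reduced) fit on a balanced design: row + column - grand means
    grand = y.mean()
    a_eff = {a: y[treat == a].mean() - grand for a in np.unique(treat)}
    b_eff = {b: y[time == b].mean() - grand for b in np.unique(time)}
    fit_red = np.array([grand + a_eff[a] + b_eff[b] for a, b in zip(treat, time)])
    resid = y - fit_red

    a_masks = [treat == a for a in np.unique(treat)]
    b_masks = [time == b for b in np.unique(time)]
    cell_masks = [am & bm for am in a_masks for bm in b_masks]

    def classic_f(ystars: np.ndarray) -> np.ndarray:
        """Balanced two-way interaction F from margin/cell means, batched over rows."""
        g = ystars.mean(axis=1, keepdims=True)
        ss_a = sum(
            (ystars[:, m].mean(axis=1, keepdims=True) - g) ** 2 * m.sum() for m in a_masks
        ).ravel()
        ss_b = sum(
            (ystars[:, m].mean(axis=1, keepdims=True) - g) ** 2 * m.sum() for m in b_masks
        ).ravel()
        cell_fit = np.empty_like(ystars)
        for m in cell_masks:
            cell_fit[:, m] = ystars[:, m].mean(axis=1, keepdims=True)
        ss_cells = ((cell_fit - g) ** 2).sum(axis=1)
        ss_int = ss_cells - ss_a - ss_b
        ss_res = ((ystars - cell_fit) ** 2).sum(axis=1)
        return (ss_int / 1) / (ss_res / (n - 4))

    f_obs = float(classic_f(y[None, :])[0])
    all_perms = [p for p in itertools.permutations(range(n)) if p != tuple(range(n))]
    f_all = classic_f(fit_red + resid[np.array(all_perms)])
    exact_p = (1 + int(np.sum(f_all >= f_obs - 1e-12))) / (len(all_perms) + 1)

    res = rrpp_interaction_test(table, permutation_indices=all_perms)
    assert res.p == pytest.approx(exact_p, abs=1e-12)
    assert res.observed == pytest.approx(f_obs, abs=1e-8)


def test_p_bounds_and_monotonicity_of_summary():
    dist = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    ps = [
        _summarize_perm("s", obs, dist, len(dist), seed=0).p
        for obs in (0.5, 2.5, 4.5, 6.0)
    ]
    assert all(1 / (len(dist) + 1) <= p <= 1 for p in ps)
    assert ps == sorted(ps, reverse=True)


def test_seed_required_for_randomized_test(multivariate_table):
    with pytest.raises(ValueError, match="seed"):
        rrpp_interaction_test(multivariate_table, 99)


# ---------------------------------------------------------------------------
# trajectory geometry
# ---------------------------------------------------------------------------

def test_path_length_examples():
    assert path_length(np.array([[0, 0], [1, 0], [1, 1]])) == pytest.approx(2.0)
    assert path_length(np.array([[0, 0], [3, 4]])) == pytest.approx(5.0)
    assert path_length(np.array([[2.0, 7.0]])) == 0.0


def test_path_length_matches_naive_loop():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(5, 7))
    naive = sum(
        math.dist(pts[i], pts[i + 1]) for i in range(len(pts) - 1)
    )
    assert path_length(pts) == pytest.approx(naive, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(arrays(np.float64, (4, 3), elements=st.floats(-50, 50)))
def test_path_length_at_least_endpoint_distance(pts):
    assert path_length(pts) >= math.dist(pts[0], pts[-1]) - 1e-9


def test_direction_angle_examples():
    along_x = np.array([[0.0, 0], [1, 0], [2, 0]])
    along_y = np.array([[0.0, 0], [0, 1], [0, 2]])
    assert direction_angle(along_x, along_x) == pytest.approx(0.0)
    assert direction_angle(along_x, along_y) == pytest.approx(90.0)


def test_direction_angle_matches_independent_eigendecomposition():
    rng = np.random.default_rng(11)
    a, b = rng.normal(size=(5, 4)), rng.normal(size=(5, 4))

    def first_axis(p):
        c = p - p.mean(axis=0)
        u, s, vt = np.linalg.svd(c, full_matrices=False)
        return vt[0]

    expected = math.degrees(math.acos(abs(float(first_axis(a) @ first_axis(b)))))
    assert direction_angle(a, b) == pytest.approx(expected, abs=1e-8)


def test_direction_angle_bounds_random_pairs():
    rng = np.random.default_rng(5)
    for _ in range(25):
        ang = direction_angle(rng.normal(size=(4, 6)), rng.normal(size=(4, 6)))
        assert 0.0 <= ang <= 90.0


def test_zero_variance_trajectory_has_no_direction():
    flat = np.ones((3, 2))
    with pytest.raises(DegenerateTrajectoryError):
        direction_angle(flat, np.array([[0.0, 0], [1, 1], [2, 2]]))


def test_shape_distance_invariant_under_similarity_transform():
    rng = np.random.default_rng(8)
    a = rng.normal(size=(4, 3))
    theta = 0.7
    rot = np.array([
        [math.cos(theta), -math.sin(theta), 0],
        [math.sin(theta), math.cos(theta), 0],
        [0, 0, 1],
    ])
    b = 3.7 * a @ rot + np.array([5.0, -2.0, 1.0])
    assert shape_distance(a, b) == pytest.approx(0.0, abs=1e-9)
    assert shape_distance(a, a) == pytest.approx(0.0, abs=1e-12)


def test_shape_distance_matches_svd_procrustes_oracle():
    a = np.array([[0.0, 0], [1, 0], [1, 2]])
    b = np.array([[0.0, 1], [2, 1], [3, -1]])

    def config(p):
        c = p - p.mean(axis=0)
        return c / np.linalg.norm(c)

    ca, cb = config(a), config(b)
    u, s, vt = np.linalg.svd(cb.T @ ca)
    r = u @ vt
    expected = np.linalg.norm(cb @ r - ca)
    assert shape_distance(a, b) == pytest.approx(expected, abs=1e-10)


def test_trajectories_from_fit(multivariate_table):
    fit = fit_factorial_model(multivariate_table)
    trajs = build_trajectories(fit)
    for t in trajs:
        assert t.points.shape == (5, 7)
        assert np.linalg.norm(t.direction) == pytest.approx(1.0)
        cfg = t.shape_config
        assert np.abs(cfg.mean(axis=0)).max() < 1e-12
        assert np.linalg.norm(cfg) == pytest.approx(1.0)


def test_identical_treatment_trajectories_give_zero_differences():
    rng = np.random.default_rng(0)
    base = {1: 1.0, 2: 2.0, 3: 2.5}
    cells = {}
    for treat in ("A", "B"):
        for tr, mu in base.items():
            cells[(treat, tr)] = [(mu, mu * 0.5 + 0.1), (mu, mu * 0.5 + 0.1)]
    table = make_phenotype_table(cells, substrates=("s1", "s2"))
    fit = fit_factorial_model(table)
    trajs = build_trajectories(fit)
    assert trajs["A"].path_length == pytest.approx(trajs["B"].path_length)
    assert direction_angle(trajs["A"], trajs["B"]) == pytest.approx(0.0, abs=1e-6)
    assert shape_distance(trajs["A"], trajs["B"]) == pytest.approx(0.0, abs=1e-9)


def test_trajectory_attributes_invariant_to_substrate_relabeling(multivariate_table):
    df = multivariate_table.data.copy()
    mapping = {s: f"z_{s}" for s in multivariate_table.substrates}
    df2 = df.assign(substrate=df["substrate"].map(mapping))
    t1 = build_trajectories(fit_factorial_model(multivariate_table))
    t2 = build_trajectories(fit_factorial_model(PhenotypeTable(df2)))
    for tr in ("MC", "RP", "DP"):
        assert t1[tr].path_length == pytest.approx(t2[tr].path_length, abs=1e-9)
    assert shape_distance(t1["MC"], t1["DP"]) == pytest.approx(
        shape_distance(t2["MC"], t2["DP"]), abs=1e-9
    )


# ---------------------------------------------------------------------------
# pairwise tests
# ---------------------------------------------------------------------------

def test_pairwise_observed_zero_and_p_one_for_identical_noise_free_trajectories():
    cells = {}
    for treat in ("A", "B"):
        for tr, mu in {1: 1.0, 2: 2.0, 3: 2.2}.items():
            cells[(treat, tr)] = [(mu, 0.5 * mu), (mu, 0.5 * mu)]
    table = make_phenotype_table(cells, substrates=("s1", "s2"))
    results = pairwise_trajectory_tests(table, "distance", n_permutations=49, seed=2)
    assert len(results) == 1
    assert results[0].observed == pytest.approx(0.0, abs=1e-9)
    assert results[0].p == 1.0


def test_pairwise_unknown_attribute_rejected(multivariate_table):
    with pytest.raises(ValueError, match="unknown trajectory attribute"):
        pairwise_trajectory_tests(multivariate_table, "curvature", 9, seed=1)


def test_pairwise_returns_one_result_per_treatment_pair(multivariate_table):
    results = pairwise_trajectory_tests(multivariate_table, "angle", 19, seed=4)
    assert sorted(r.label for r in results) == ["DP:MC", "DP:RP", "MC:RP"]
    for r in results:
        assert 1 / 20 <= r.p <= 1.0
        assert 0.0 <= r.observed <= 90.0


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def test_rank_one_fitted_values_put_all_variance_on_pc1():
    cells = {}
    # means vary along a single direction (1, 2) in substrate space
    for treat, scale in (("A", 1.0), ("B", 2.0)):
        for tr in (1, 2):
            mu = scale * tr
            cells[(treat, tr)] = [(mu, 2 * mu) for _ in range(2)]
    table = make_phenotype_table(cells, substrates=("s1", "s2"))
    ordination = pca_of_fitted(fit_factorial_model(table))
    assert ordination.variance_proportions[0] == pytest.approx(1.0)


def test_variance_proportions_sum_to_one(multivariate_table):
    ordination = pca_of_fitted(fit_factorial_model(multivariate_table))
    assert ordination.variance_proportions.sum() == pytest.approx(1.0, abs=1e-9)
    assert (ordination.variance_proportions >= 0).all()
    assert ordination.scores.shape[0] == len(multivariate_table.data) // 7
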
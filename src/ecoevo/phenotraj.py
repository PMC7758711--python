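"""Phenotypic trajectory analysis (PTA) for multivariate substrate-use evolution.

A focal species' metabolic phenotype is scored as respiration on p substrates,
for each replicate population of each selection treatment at each transfer
(time point). The analysis asks whether the multivariate phenotype moved
through substrate space differently between treatments:

* a factorial treatment x time linear model is fit to the n x p response
  matrix by ordinary least squares, with multivariate sums of squares taken
  as traces of cross-product matrices;
* significance of the treatment x time interaction is assessed by the
  randomization of residuals in a permutation procedure (RRPP): residuals of
  the reduced (additive) model are shuffled across observations, added back
  to the reduced-model fitted values, and the full model is refit to each
  pseudo-dataset;
* per-treatment trajectories are the ordered sequences of least-squares cell
  means across time levels, compared via three geometric attributes -- path
  length (magnitude of change), direction (orientation of the principal axis
  of the trajectory points), and shape (Procrustes-standardized
  configuration);
* ordination for visualisation projects the centred data onto principal
  components of the full-model fitted values.

Time (transfer) is treated as a categorical factor throughout: a trajectory
is a sequence of per-transfer points, not a parametric curve.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes

from .errors import DegenerateTrajectoryError, DesignError, SchemaError

__all__ = [
    "PhenotypeTable",
    "ModelFit",
    "Trajectory",
    "TrajectorySet",
    "PermTestResult",
    "OrdinationResult",
    "fit_factorial_model",
    "rrpp_interaction_test",
    "build_trajectories",
    "path_length",
    "direction_angle",
    "shape_distance",
    "pairwise_trajectory_tests",
    "pca_of_fitted",
]

PHENOTYPE_COLUMNS = ["replicate_id", "treatment", "transfer", "substrate", "value"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeTable:
    """Tidy respiration records: one row per replicate x treatment x transfer x substrate.

    The table must be complete-case: every (replicate, transfer) combination
    carries exactly one value for every substrate. Values are respiration
    readings on their raw assay scale and must be nonnegative.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"phenotype table missing column(s): {missing}")
        if len(df) == 0:
            raise SchemaError("phenotype table is empty")
        if (df["value"] < 0).any():
            bad = df.index[df["value"] < 0][0]
            raise SchemaError(f"negative respiration value at row {bad}")
        dup = df.duplicated(subset=["replicate_id", "treatment", "transfer", "substrate"])
        if dup.any():
            raise SchemaError(
                f"duplicate (replicate, transfer, substrate) key at row {df.index[dup][0]}"
            )
        counts = df.groupby(["replicate_id", "transfer"], sort=False)["substrate"].nunique()
        if counts.nunique() > 1:
            raise SchemaError(
                "incomplete cases: substrate count varies across (replicate, transfer)"
            )

    @property
    def substrates(self) -> list[str]:
        return sorted(self.data["substrate"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    @property
    def transfers(self) -> list[int]:
        return sorted(self.data["transfer"].unique())

    def wide(self) -> tuple[pd.DataFrame, np.ndarray]:
        """Pivot to an observation x substrate matrix.

        Returns ``(meta, Y)`` where ``meta`` has one row per observation with
        columns replicate_id / treatment / transfer, and ``Y`` is the aligned
        n x p response matrix with substrate columns in sorted order.
        """
        piv = self.data.pivot_table(
            index=["replicate_id", "treatment", "transfer"],
            columns="substrate",
            values="value",
            sort=True,
        )
        if piv.isna().any().any():
            raise SchemaError("incomplete cases: some (replicate, transfer) lack a substrate value")
        piv = piv[self.substrates]
        meta = piv.index.to_frame(index=False)
        return meta, piv.to_numpy(dtype=float)


@dataclass
class ModelFit:
    """OLS fit of the treatment x time factorial model to the n x p response.

    Sums of squares are traces of the cross-product matrices of sequential
    (order-entered) projection differences: treatment, then time, then their
    interaction. ``ls_means[t]`` is the k x p matrix of least-squares cell
    means for treatment ``t`` ordered by time level.
    """

    meta: pd.DataFrame
    response: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray
    ss: dict[str, float]
    df: dict[str, int]
    ls_means: dict[str, np.ndarray]
    treatments: list[str]
    transfers: list[int]
    substrates: list[str]
    scaled: bool = False

    def interaction_f(self) -> float:
        """Pseudo-F for the treatment x time interaction term."""
        num = self.ss["interaction"] / self.df["interaction"]
        den = self.ss["residual"] / self.df["residual"]
        return num / den


@dataclass(frozen=True)
class Trajectory:
    """Ordered k x p sequence of least-squares means for one treatment."""

    treatment: str
    points: np.ndarray
    times: tuple[int, ...]

    @property
    def path_length(self) -> float:
        return path_length(self.points)

    @property
    def direction(self) -> np.ndarray:
        return _principal_direction(self.points)

    @property
    def shape_config(self) -> np.ndarray:
        return _shape_config(self.points)


@dataclass(frozen=True)
class TrajectorySet:
    """Per-treatment trajectories from one model fit."""

    trajectories: dict[str, Trajectory]

    def __getitem__(self, treatment: str) -> Trajectory:
        return self.trajectories[treatment]

    def __iter__(self):
        return iter(self.trajectories.values())

    @property
    def treatments(self) -> list[str]:
        return list(self.trajectories)


@dataclass(frozen=True)
class PermTestResult:
    """Outcome of one permutation test.

    ``p`` counts the observed arrangement among the permuted ones,
    p = (b + 1) / (m + 1), so p >= 1/(m+1). ``Z`` is the standard deviate of
    the observed statistic against the permutation distribution (which
    includes the observed value).
    """

    statistic_name: str
    observed: float
    perm_mean: float
    perm_sd: float
    Z: float
    p: float
    n_permutations: int
    seed: int | None
    df: tuple[float, float] | None = None
    label: str | None = None

    def as_dict(self) -> dict:
        out = {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "perm_mean": self.perm_mean,
            "perm_sd": self.perm_sd,
            "Z": self.Z,
            "p": self.p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }
        if self.df is not None:
            out["df"] = list(self.df)
        if self.label is not None:
            out["label"] = self.label
        return out


@dataclass(frozen=True)
class OrdinationResult:
    """PCA of full-model fitted values with observed data projected on."""

    eigenvalues: np.ndarray
    variance_proportions: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _design_matrices(meta: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sequential design matrices: intercept -> +treatment -> +time -> +interaction.

    Treatment-coded (drop-first) dummies; time is categorical.
    """
    treat = pd.Categorical(meta["treatment"])
    time = pd.Categorical(meta["transfer"])
    n = len(meta)
    one = np.ones((n, 1))
    a = pd.get_dummies(treat, drop_first=True, dtype=float).to_numpy()
    b = pd.get_dummies(time, drop_first=True, dtype=float).to_numpy()
    ab = np.einsum("ni,nj->nij", a, b).reshape(n, -1) if a.size and b.size else np.empty((n, 0))
    return {
        "intercept": one,
        "main_a": np.hstack([one, a]),
        "additive": np.hstack([one, a, b]),
        "full": np.hstack([one, a, b, ab]),
    }


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * max(x.shape))
    q = q[:, :rank]
    return q @ q.T


def _check_cells(meta: pd.DataFrame) -> None:
    treatments = meta["treatment"].unique()
    transfers = meta["transfer"].unique()
    have = set(map(tuple, meta[["treatment", "transfer"]].itertuples(index=False)))
    for t in treatments:
        for tr in transfers:
            if (t, tr) not in have:
                raise DesignError(
                    f"empty design cell: treatment={t!r}, transfer={tr} has no observations"
                )


def fit_factorial_model(
    table: PhenotypeTable, scale: bool = False
) -> ModelFit:
    """Fit the treatment x time factorial model to the multivariate response.

    Parameters
    ----------
    table
        Complete-case phenotype table.
    scale
        If True, divide each substrate column by its standard deviation
        before fitting (default analyses raw respiration values).

    Returns
    -------
    ModelFit with sequential sums of squares (traces of cross-product
    matrices), least-squares cell means, fitted values and residuals.
    """
    meta, y = table.wide()
    if len(table.treatments) < 2 or len(table.transfers) < 2:
        raise DesignError("trajectory analysis needs >= 2 treatments and >= 2 time levels")
    _check_cells(meta)
    if scale:
        sd = y.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DesignError("cannot scale: a substrate column has zero variance")
        y = y / sd

    cell_sizes = meta.groupby(["treatment", "transfer"]).size()
    if cell_sizes.nunique() > 1:
        warnings.warn(
            "unbalanced design: sequential sums of squares depend on term order",
            stacklevel=2,
        )
    if int(cell_sizes.min()) < 2:
        raise DesignError(
            "each treatment x transfer cell needs >= 2 observations for a residual term"
        )

    x = _design_matrices(meta)
    hats = {k: _hat(v) for k, v in x.items()}
    n = len(meta)

    def _ss(h_hi: np.ndarray, h_lo: np.ndarray) -> float:
        d = (h_hi - h_lo) @ y
        return float(np.sum(d * d))

    fitted = hats["full"] @ y
    residuals = y - fitted
    a = len(table.treatments)
    b = len(table.transfers)
    ss = {
        "treatment": _ss(hats["main_a"], hats["intercept"]),
        "time": _ss(hats["additive"], hats["main_a"]),
        "interaction": _ss(hats["full"], hats["additive"]),
        "residual": float(np.sum(residuals * residuals)),
        "total": float(np.sum((y - y.mean(axis=0)) ** 2)),
    }
    df = {
        "treatment": a - 1,
        "time": b - 1,
        "interaction": (a - 1) * (b - 1),
        "residual": n - a * b,
    }
    if df["residual"] <= 0:
        raise DesignError("no residual degrees of freedom (need replication within cells)")

    ls_means: dict[str, np.ndarray] = {}
    fitted_df = pd.DataFrame(fitted, columns=table.substrates)
    fitted_df["treatment"] = meta["treatment"].to_numpy()
    fitted_df["transfer"] = meta["transfer"].to_numpy()
    cell = fitted_df.groupby(["treatment", "transfer"]).mean()
    for t in table.treatments:
        ls_means[t] = cell.loc[t].loc[table.transfers].to_numpy(dtype=float)

    return ModelFit(
        meta=meta,
        response=y,
        fitted=fitted,
        residuals=residuals,
        ss=ss,
        df=df,
        ls_means=ls_means,
        treatments=table.treatments,
        transfers=table.transfers,
        substrates=table.substrates,
        scaled=scale,
    )


# ---------------------------------------------------------------------------
# RRPP machinery
# ---------------------------------------------------------------------------

def _perm_matrix(
    rng: np.random.Generator, n: int, m: int, permutation_indices=None
) -> np.ndarray:
    """m x n array of row permutations (the observed identity is NOT included)."""
    if permutation_indices is not None:
        perms = np.asarray(list(permutation_indices), dtype=int)
        if perms.ndim != 2 or perms.shape[1] != n:
            raise ValueError("permutation_indices must be an iterable of length-n index arrays")
        return perms
    return np.array([rng.permutation(n) for _ in range(m)])


def _summarize_perm(
    name: str,
    observed: float,
    perm_stats: np.ndarray,
    n_permutations: int,
    seed: int | None,
    df: tuple[float, float] | None = None,
    label: str | None = None,
    transform: str | None = None,
    two_sided: bool = False,
) -> PermTestResult:
    """Fold the observed statistic into its permutation distribution.

    The distribution used for p, Z contains the observed value plus the
    permuted ones (the observed arrangement counts as one permutation).
    """
    dist = np.concatenate([[observed], perm_stats])
    if two_sided:
        effect = np.abs(dist)
        obs_eff = abs(observed)
    else:
        effect = dist
        obs_eff = observed
    b = int(np.sum(effect >= obs_eff - 1e-12))
    p = b / (len(perm_stats) + 1)
    zdist = dist
    if transform == "log":
        if np.any(dist <= 0):
            raise ValueError("log transform requires strictly positive statistics")
        zdist = np.log(dist)
    sd = float(np.std(zdist, ddof=1))
    mean = float(np.mean(zdist))
    obs_t = math.log(observed) if transform == "log" else observed
    z = (obs_t - mean) / sd if sd > 0 else 0.0
    return PermTestResult(
        statistic_name=name,
        observed=float(observed),
        perm_mean=float(np.mean(dist)),
        perm_sd=float(np.std(dist, ddof=1)),
        Z=float(z),
        p=float(p),
        n_permutations=len(perm_stats),
        seed=seed,
        df=df,
        label=label,
    )


def rrpp_interaction_test(
    table: PhenotypeTable,
    n_permutations: int = 999,
    seed: int | None = None,
    scale: bool = False,
    transform: str | None = None,
    permutation_indices=None,
) -> PermTestResult:
    """Permutational MANOVA of the treatment x time interaction via RRPP.

    The observed pseudo-F is (SS_int/df_int)/(SS_res/df_res) with
    multivariate SS as traces of cross-product matrices; it does not depend
    on the seed. The null distribution shuffles reduced-model (additive)
    residuals across observations, adds them back to the reduced fitted
    values, and refits the full model.

    ``permutation_indices`` overrides random sampling with an explicit set of
    row permutations (e.g. complete enumeration); the identity permutation is
    represented by the observed arrangement itself and should not be included.
    """
    if n_permutations < 1 and permutation_indices is None:
        raise ValueError("n_permutations must be >= 1")
    if seed is None and permutation_indices is None:
        raise ValueError("seed is required for a randomized permutation test")
    fit = fit_factorial_model(table, scale=scale)
    meta, y = fit.meta, fit.response
    x = _design_matrices(meta)
    h_full = _hat(x["full"])
    h_red = _hat(x["additive"])
    d_int = h_full - h_red          # projection onto the interaction subspace
    m_res = np.eye(len(meta)) - h_full
    df_int, df_res = fit.df["interaction"], fit.df["residual"]

    r_red = y - h_red @ y
    obs_f = fit.interaction_f()

    rng = np.random.default_rng(seed)
    perms = _perm_matrix(rng, len(meta), n_permutations, permutation_indices)
    stats = np.empty(len(perms))
    for i, pr in enumerate(perms):
        rp = r_red[pr]
        # reduced fitted values lie in the full-model column space, so only
        # the permuted residuals contribute to both SS terms
        ss_int = float(np.sum((d_int @ rp) ** 2))
        ss_res = float(np.sum((m_res @ rp) ** 2))
        stats[i] = (ss_int / df_int) / (ss_res / df_res)
    return _summarize_perm(
        "interaction_F",
        obs_f,
        stats,
        len(perms),
        seed,
        df=(float(df_int), float(df_res)),
        transform=transform,
    )


# ---------------------------------------------------------------------------
# trajectory geometry
# ---------------------------------------------------------------------------

def path_length(points: np.ndarray) -> float:
    """Sum of Euclidean distances between consecutive trajectory points."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a k x p matrix")
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _principal_direction(points: np.ndarray) -> np.ndarray:
    """Unit first principal axis of the trajectory points.

    The sign is oriented so that the start-to-end displacement projects
    positively; when that projection is numerically zero the first nonzero
    consecutive displacement is used, and a trajectory with zero variance
    raises DegenerateTrajectoryError.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise DegenerateTrajectoryError("direction needs >= 2 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / (len(pts) - 1)
    vals, vecs = np.linalg.eigh(cov)
    if vals[-1] <= 1e-14 * max(1.0, abs(vals).max()):
        raise DegenerateTrajectoryError("zero-variance trajectory has no direction")
    v = vecs[:, -1]
    for disp in [pts[-1] - pts[0], *np.diff(pts, axis=0)]:
        proj = float(v @ disp)
        if abs(proj) > 1e-12:
            return v if proj > 0 else -v
    raise DegenerateTrajectoryError("direction sign is undetermined (symmetric trajectory)")


def direction_angle(traj_a: np.ndarray | Trajectory, traj_b: np.ndarray | Trajectory) -> float:
    """Angle in degrees, in [0, 90], between two trajectories' principal axes."""
    pa = traj_a.points if isinstance(traj_a, Trajectory) else np.asarray(traj_a, float)
    pb = traj_b.points if isinstance(traj_b, Trajectory) else np.asarray(traj_b, float)
    va, vb = _principal_direction(pa), _principal_direction(pb)
    cosang = min(1.0, abs(float(va @ vb)))
    return float(np.degrees(np.arccos(cosang)))


def _shape_config(points: np.ndarray) -> np.ndarray:
    """Translate to centroid 0 and scale to unit centroid size."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    size = float(np.linalg.norm(centered))
    if size <= 1e-14:
        raise DegenerateTrajectoryError("zero centroid size: shape is undefined")
    return centered / size


def shape_distance(traj_a: np.ndarray | Trajectory, traj_b: np.ndarray | Trajectory) -> float:
    """Procrustes distance between two trajectories' shape configurations.

    Both configurations are centred, scaled to centroid size 1, and the
    second is optimally rotated onto the first (orthogonal Procrustes); the
    distance is the square root of the summed squared coordinate differences.
    """
    pa = traj_a.points if isinstance(traj_a, Trajectory) else np.asarray(traj_a, float)
    pb = traj_b.points if isinstance(traj_b, Trajectory) else np.asarray(traj_b, float)
    if pa.shape != pb.shape:
        raise ValueError("shape distance needs trajectories with equal point counts")
    ca, cb = _shape_config(pa), _shape_config(pb)
    rot, _ = orthogonal_procrustes(cb, ca)
    return float(np.linalg.norm(cb @ rot - ca))


def build_trajectories(fit: ModelFit) -> TrajectorySet:
    """Assemble the per-treatment trajectories of least-squares means."""
    if len(fit.transfers) < 2:
        raise DesignError("trajectories need >= 2 time levels")
    trajs = {
        t: Trajectory(treatment=t, points=fit.ls_means[t], times=tuple(fit.transfers))
        for t in fit.treatments
    }
    return TrajectorySet(trajs)


# ---------------------------------------------------------------------------
# pairwise permutation tests on trajectory attributes
# ---------------------------------------------------------------------------

_ATTRIBUTES = ("distance", "angle", "shape")


def _pair_stat(attribute: str, pts_a: np.ndarray, pts_b: np.ndarray) -> float:
    if attribute == "distance":
        return abs(path_length(pts_a) - path_length(pts_b))
    if attribute == "angle":
        return direction_angle(pts_a, pts_b)
    if attribute == "shape":
        return shape_distance(pts_a, pts_b)
    raise ValueError(f"unknown trajectory attribute {attribute!r}; use one of {_ATTRIBUTES}")


def pairwise_trajectory_tests(
    table: PhenotypeTable,
    attribute: str,
    n_permutations: int = 999,
    seed: int | None = None,
    scale: bool = False,
    transform: str | None = None,
) -> list[PermTestResult]:
    """Pairwise treatment comparisons of a trajectory attribute under RRPP.

    For each treatment pair the observed statistic is the absolute difference
    in path length ('distance'), the angle between principal directions
    ('angle'), or the Procrustes shape distance ('shape'). Null datasets are
    generated exactly as in :func:`rrpp_interaction_test` (reduced model =
    treatment + time) and trajectories are rebuilt for every permutation.
    """
    if attribute not in _ATTRIBUTES:
        raise ValueError(f"unknown trajectory attribute {attribute!r}; use one of {_ATTRIBUTES}")
    if seed is None:
        raise ValueError("seed is required for a randomized permutation test")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    fit = fit_factorial_model(table, scale=scale)
    meta, y = fit.meta, fit.response
    x = _design_matrices(meta)
    h_red = _hat(x["additive"])
    x_full = x["full"]
    pinv_full = np.linalg.pinv(x_full)

    # design rows at which to predict the treatment x transfer cell means
    cells = pd.DataFrame(
        [(t, tr) for t in fit.treatments for tr in fit.transfers],
        columns=["treatment", "transfer"],
    )
    cell_x = _design_matrices(
        pd.concat([meta[["treatment", "transfer"]], cells], ignore_index=True)
    )["full"][len(meta):]

    k = len(fit.transfers)

    def _traj_points(y_mat: np.ndarray) -> dict[str, np.ndarray]:
        beta = pinv_full @ y_mat
        means = cell_x @ beta
        return {
            t: means[i * k:(i + 1) * k] for i, t in enumerate(fit.treatments)
        }

    obs_points = _traj_points(y)
    pairs = list(itertools.combinations(fit.treatments, 2))
    observed = {pr: _pair_stat(attribute, obs_points[pr[0]], obs_points[pr[1]]) for pr in pairs}

    fit_red = h_red @ y
    r_red = y - fit_red
    rng = np.random.default_rng(seed)
    perm_stats = {pr: np.empty(n_permutations) for pr in pairs}
    for i in range(n_permutations):
        y_star = fit_red + r_red[rng.permutation(len(meta))]
        pts = _traj_points(y_star)
        for pr in pairs:
            perm_stats[pr][i] = _pair_stat(attribute, pts[pr[0]], pts[pr[1]])

    name = {"distance": "path_distance_diff", "angle": "path_angle", "shape": "path_shape_dist"}
    return [
        _summarize_perm(
            name[attribute],
            observed[pr],
            perm_stats[pr],
            n_permutations,
            seed,
            label=f"{pr[0]}:{pr[1]}",
            transform=transform,
        )
        for pr in pairs
    ]


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

def pca_of_fitted(fit: ModelFit) -> OrdinationResult:
    """PCA of the full-model fitted values, with data projected onto the axes.

    The decomposition uses the covariance of the fitted values (no variable
    scaling beyond any applied at fit time), so the ordination shows the
    structure the factorial model explains; observed data are centred and
    projected onto the same axes for plotting.
    """
    if len(fit.fitted) < 2:
        raise DesignError("ordination needs >= 2 observations")
    centered_fit = fit.fitted - fit.fitted.mean(axis=0)
    cov = centered_fit.T @ centered_fit / (len(fit.fitted) - 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, None)
    vecs = vecs[:, order]
    total = vals.sum()
    props = vals / total if total > 0 else np.zeros_like(vals)
    centered_y = fit.response - fit.response.mean(axis=0)
    scores = centered_y @ vecs
    comp_names = [f"PC{i + 1}" for i in range(len(vals))]
    scores_df = pd.concat(
        [fit.meta.reset_index(drop=True), pd.DataFrame(scores, columns=comp_names)], axis=1
    )
    loadings_df = pd.DataFrame(vecs, index=fit.substrates, columns=comp_names)
    return OrdinationResult(
        eigenvalues=vals,
        variance_proportions=props,
        scores=scores_df,
        loadings=loadings_df,
    )
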
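"""Community-structure statistics: Bray-Curtis divergence and its covariance
with evolved metabolic phenotype.

Replicate communities are compositional profiles (species relative
abundances summing to 1 per replicate and transfer). Divergence among
replicates at a transfer is the Bray-Curtis dissimilarity

    BC(x, y) = sum |x_i - y_i| / sum (x_i + y_i)

computed over all unordered replicate pairs. The same measure applied to the
replicate substrate-use profiles of the focal species gives phenotypic
divergence, and regressing phenotypic on community dissimilarity with a
continuous time covariate and their product tests whether the
phenotype-community association strengthens over the experiment (the
interaction term). Endpoint associations between one species' relative
abundance and the focal species' respiration on one substrate use simple
linear regression.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .errors import DesignError, SchemaError
from .phenotraj import PhenotypeTable

__all__ = [
    "ABUNDANCE_COLUMNS",
    "AbundanceTable",
    "RegressionResult",
    "bray_curtis",
    "pairwise_dissimilarity",
    "dissimilarity_timeseries",
    "covariance_regression",
    "abundance_phenotype_regression",
]

ABUNDANCE_COLUMNS = ["replicate_id", "transfer", "species", "rel_abundance"]


@dataclass(frozen=True)
class AbundanceTable:
    """Tidy compositional table: relative abundance per replicate x transfer x species.

    Every (replicate, transfer) block must sum to 1 within 1e-6 and carry the
    same species set.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in ABUNDANCE_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"abundance table missing column(s): {missing}")
        if len(df) == 0:
            raise SchemaError("abundance table is empty")
        if ((df["rel_abundance"] < 0) | (df["rel_abundance"] > 1)).any():
            bad = df.index[(df["rel_abundance"] < 0) | (df["rel_abundance"] > 1)][0]
            raise SchemaError(f"relative abundance outside [0, 1] at row {bad}")
        sums = df.groupby(["replicate_id", "transfer"])["rel_abundance"].sum()
        off = sums[(sums - 1.0).abs() > 1e-6]
        if len(off):
            rep, tr = off.index[0]
            raise SchemaError(
                f"abundances for replicate {rep!r} transfer {tr} sum to {off.iloc[0]:.6f}, not 1"
            )
        nsp = df.groupby(["replicate_id", "transfer"])["species"].nunique()
        if nsp.nunique() > 1:
            raise SchemaError("species set differs across (replicate, transfer) blocks")

    @property
    def species(self) -> list[str]:
        return sorted(self.data["species"].unique())

    @property
    def transfers(self) -> list[int]:
        return sorted(self.data["transfer"].unique())

    def profiles(self, transfer: int) -> pd.DataFrame:
        """Replicate x species abundance matrix at one transfer."""
        sub = self.data[self.data["transfer"] == transfer]
        if len(sub) == 0:
            raise DesignError(f"no abundance records at transfer {transfer}")
        return sub.pivot_table(index="replicate_id", columns="species",
                               values="rel_abundance", sort=True)[self.species]


@dataclass(frozen=True)
class RegressionResult:
    """Linear-model summary: coefficients, R^2, the focal F test and its p."""

    coefficients: dict[str, float]
    r_squared: float
    F: float
    df: tuple[float, float]
    p: float

    def as_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "r_squared": self.r_squared,
            "F": self.F,
            "df": list(self.df),
            "p": self.p,
        }


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between nonnegative profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative entries")
    denom = float((x + y).sum())
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero profiles")
    return float(np.abs(x - y).sum() / denom)


def _replicate_profiles(table, transfer: int) -> pd.DataFrame:
    if isinstance(table, AbundanceTable):
        return table.profiles(transfer)
    if isinstance(table, PhenotypeTable):
        sub = table.data[table.data["transfer"] == transfer]
        if len(sub) == 0:
            raise DesignError(f"no phenotype records at transfer {transfer}")
        return sub.pivot_table(index="replicate_id", columns="substrate",
                               values="value", sort=True)[table.substrates]
    raise TypeError("expected an AbundanceTable or PhenotypeTable")


def pairwise_dissimilarity(table, transfer: int) -> pd.DataFrame:
    """Bray-Curtis dissimilarity for all unordered replicate pairs at a transfer.

    Works on an :class:`AbundanceTable` (species profiles) or a
    :class:`~ecoevo.phenotraj.PhenotypeTable` (substrate-use profiles).
    Returns a long table with columns replicate_a, replicate_b, transfer,
    dissimilarity.
    """
    prof = _replicate_profiles(table, transfer)
    reps = list(prof.index)
    if len(reps) < 2:
        raise DesignError(f"need >= 2 replicates at transfer {transfer}")
    rows = [
        {
            "replicate_a": a,
            "replicate_b": b,
            "transfer": transfer,
            "dissimilarity": bray_curtis(prof.loc[a], prof.loc[b]),
        }
        for a, b in itertools.combinations(reps, 2)
    ]
    return pd.DataFrame(rows)


def dissimilarity_timeseries(table, transfers=None) -> pd.DataFrame:
    """Concatenated pairwise dissimilarities over several transfers."""
    if transfers is None:
        transfers = (
            table.transfers if isinstance(table, AbundanceTable)
            else sorted(table.data["transfer"].unique())
        )
    return pd.concat(
        [pairwise_dissimilarity(table, t) for t in transfers], ignore_index=True
    )


def covariance_regression(
    phenotype_dissim: pd.DataFrame, community_dissim: pd.DataFrame
) -> RegressionResult:
    """Test whether phenotype-community covariance strengthens over time.

    Inputs are long pair x transfer dissimilarity tables (as returned by
    :func:`pairwise_dissimilarity` / :func:`dissimilarity_timeseries`),
    matched on (replicate_a, replicate_b, transfer). Fits OLS

        phenotype ~ community + transfer + community:transfer

    with transfer continuous, and reports the interaction term's partial
    F(1, df_res) and p, plus the model R^2.
    """
    keys = ["replicate_a", "replicate_b", "transfer"]
    merged = pd.merge(
        phenotype_dissim.rename(columns={"dissimilarity": "phen"}),
        community_dissim.rename(columns={"dissimilarity": "comm"}),
        on=keys,
    )
    if len(merged) < 4 or merged[["comm", "transfer"]].drop_duplicates().shape[0] < 4:
        raise DesignError("covariance regression needs >= 4 distinct observations")
    merged = merged.astype({"transfer": float})
    fit = smf.ols("phen ~ comm * transfer", data=merged).fit()
    t_int = fit.tvalues["comm:transfer"]
    f_int = float(t_int**2)
    p_int = float(fit.pvalues["comm:transfer"])
    if fit.params["comm:transfer"] == 0 and np.isnan(f_int):
        f_int, p_int = 0.0, 1.0
    return RegressionResult(
        coefficients={k: float(v) for k, v in fit.params.items()},
        r_squared=float(fit.rsquared),
        F=f_int,
        df=(1.0, float(fit.df_resid)),
        p=p_int,
    )


def abundance_phenotype_regression(final_abundance, substrate_value) -> RegressionResult:
    """Simple linear regression of a substrate phenotype on a species' abundance.

    Regresses per-replicate respiration on one substrate against the final
    relative abundance of one community member; reports R^2, the slope
    F(1, n-2) and p.
    """
    x = np.asarray(final_abundance, dtype=float)
    y = np.asarray(substrate_value, dtype=float)
    if len(x) != len(y):
        raise ValueError("predictor and response must have equal length")
    if len(x) < 3:
        raise DesignError("regression needs >= 3 replicates")
    if np.var(x) == 0:
        raise DesignError("zero variance in the predictor")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = float(res.rvalue**2)
    if r2 >= 1.0:
        f = np.inf
    else:
        f = float(r2 / (1 - r2) * (n - 2))
    return RegressionResult(
        coefficients={"Intercept": float(res.intercept), "slope": float(res.slope)},
        r_squared=r2,
        F=f,
        df=(1.0, float(n - 2)),
        p=float(res.pvalue),
    )
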
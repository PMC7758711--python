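"""Seed-reproducible synthetic datasets with the structure the pipeline assumes.

The generators emulate the four data shapes of a lignocellulose
community-evolution experiment in which a focal degrader species evolves for
16 serial transfers alone (MC), alongside a community reset to its ancestral
composition every transfer (RP), or within a freely co-evolving dynamic
polyculture (DP):

* ``simulate_phenotypes`` -- respiration of the focal species on 7
  lignocellulose substrates per replicate x treatment x transfer, built as
  baseline + treatment-specific displacement per transfer + a shared
  replicate effect + residual noise, truncated at the assay floor of zero;
* ``simulate_mutations`` -- per-clone Poisson mutation counts over an
  abstract locus pool with treatment-specific hotspot weights (emulating
  parallel mutation of a regulator in some treatments);
* ``simulate_community`` -- compositional species time series per replicate
  from a log-abundance random walk (species sorting), with an optional
  reinvasion scenario that crashes and then recovers one species in half the
  replicates;
* ``simulate_growth`` -- paired start/end CFU densities per population and
  growth condition with lognormal noise around a true Malthusian rate.

Each generator draws from its own RNG stream seeded at config.seed plus a
fixed per-generator offset, so adding one generator to a pipeline never
perturbs another's draws, and equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .community import AbundanceTable
from .errors import ConfigurationError
from .parallelism import MUTATION_CLASSES, CloneProfile, MutationProfileSet
from .phenotraj import PhenotypeTable

__all__ = [
    "DEFAULT_SUBSTRATES",
    "DEFAULT_SPECIES",
    "SimulationConfig",
    "simulate_phenotypes",
    "simulate_mutations",
    "simulate_community",
    "simulate_growth",
    "simulate_all",
]

# labile (readily digested) then recalcitrant lignocellulose components
DEFAULT_SUBSTRATES = (
    "xylan", "arabinoxylan", "galactomannan", "pectin",
    "beta-glucan", "cellulose", "lignin",
)
DEFAULT_SPECIES = (
    "Stenotrophomonas", "Bacillus", "Pseudomonas", "Achromobacter", "Ochrobactrum",
)
DEFAULT_TREATMENTS = ("MC", "RP", "DP")
DEFAULT_TRANSFERS = (0, 4, 8, 12, 16)

# RNG stream offsets: one independent stream per generator
_STREAM = {"phenotypes": 0, "mutations": 1, "community": 2, "growth": 3}

_LABILE = slice(0, 4)
_RECALCITRANT = slice(4, 7)


def _default_trajectory_effects(
    treatments: tuple[str, ...],
    transfers: tuple[int, ...],
    substrates: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Treatment-divergent mean displacement per transfer (respiration units).

    The monoculture drifts a short distance; the reset polyculture moves
    steadily toward labile substrates; the dynamic polyculture first follows
    the labile direction then turns toward recalcitrant substrates mid-series
    (a direction/shape change). Unknown treatment labels get a small generic
    drift.
    """
    p = len(substrates)
    k = len(transfers)
    steps = {}
    for t in treatments:
        step = np.zeros((k, p))
        for i in range(1, k):
            if t == "MC":
                step[i] = 0.05
            elif t == "RP":
                step[i, _LABILE] = 0.25
            elif t == "DP":
                if i <= (k - 1) // 2:
                    step[i, _LABILE] = 0.22
                else:
                    step[i, _RECALCITRANT] = 0.30
            else:
                step[i] = 0.05
        steps[t] = np.cumsum(step, axis=0)
    return steps


def _default_hotspot_weights(
    treatments: tuple[str, ...], pool: int
) -> dict[str, np.ndarray]:
    """Per-treatment multinomial locus weights with a shared MC/DP hotspot.

    Locus 0 plays the role of the parallel-evolving regulator: heavily
    weighted in DP, moderately in MC, and not favoured in RP; remaining mass
    is uniform over the pool.
    """
    out = {}
    for t in treatments:
        w = np.ones(pool)
        if t == "DP":
            w[0] = pool * 0.5 / 0.5 if pool > 1 else 1.0
        elif t == "MC":
            w[0] = pool * 0.33 / 0.67 if pool > 1 else 1.0
        out[t] = w / w.sum()
    return out


def _default_growth_rates(
    treatments: tuple[str, ...]
) -> dict[tuple[str, str], tuple[float, float]]:
    """(mean Malthusian per cycle, lognormal sd) per treatment x condition.

    All populations grow ~100-fold alone over the cycle (m = ln 100); the
    community boosts everyone, and the reset-polyculture-evolved populations
    get an extra competitive boost (a treatment x condition interaction).
    """
    alone = math.log(100.0)
    rates: dict[tuple[str, str], tuple[float, float]] = {}
    for t in ("ancestor", *treatments):
        rates[(t, "alone")] = (alone, 0.2)
        boost = 1.6 if t == "RP" else 0.8
        rates[(t, "with_community")] = (alone + boost, 0.2)
    return rates


@dataclass
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the source design: 3 selection treatments, transfers
    0/4/8/12/16, 7 substrates, 6 replicates per treatment, a mean of 1.375
    mutations per clone, two-thirds of mutations nonsynonymous, and a shared
    MC/DP mutational hotspot.
    """

    n_replicates_per_treatment: int = 6
    treatments: tuple[str, ...] = DEFAULT_TREATMENTS
    transfers: tuple[int, ...] = DEFAULT_TRANSFERS
    substrates: tuple[str, ...] = DEFAULT_SUBSTRATES
    species: tuple[str, ...] = DEFAULT_SPECIES
    baseline: float = 1.0
    trajectory_effects: dict[str, np.ndarray] | None = None
    replicate_sd: float = 0.05
    residual_sd: float = 0.10
    mutation_rate_lambda: float = 1.375
    locus_pool_size: int = 50
    hotspot_weights: dict[str, np.ndarray] | None = None
    nonsyn_fraction: float = 0.666
    sorting_drift_sd: float = 0.4
    reinvasion_scenario: bool = False
    reinvasion_species: str = "Bacillus"
    growth_rates: dict[tuple[str, str], tuple[float, float]] | None = None
    start_density: float = 1e6
    growth_duration: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates_per_treatment < 1:
            raise ConfigurationError("n_replicates_per_treatment must be positive")
        if not self.treatments or not self.substrates or not self.transfers:
            raise ConfigurationError("treatments, substrates and transfers must be non-empty")
        if len(set(self.transfers)) != len(self.transfers):
            raise ConfigurationError("transfers must be distinct")
        for name in ("replicate_sd", "residual_sd", "sorting_drift_sd",
                     "mutation_rate_lambda"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.locus_pool_size < 1:
            raise ConfigurationError("locus_pool_size must be >= 1")
        if not 0.0 <= self.nonsyn_fraction <= 1.0:
            raise ConfigurationError("nonsyn_fraction must be in [0, 1]")
        if self.start_density <= 0:
            raise ConfigurationError("start_density must be positive")
        if self.trajectory_effects is None:
            self.trajectory_effects = _default_trajectory_effects(
                self.treatments, self.transfers, self.substrates
            )
        k, p = len(self.transfers), len(self.substrates)
        for t in self.treatments:
            if t not in self.trajectory_effects:
                raise ConfigurationError(f"trajectory_effects missing treatment {t!r}")
            eff = np.asarray(self.trajectory_effects[t], dtype=float)
            if eff.shape != (k, p):
                raise ConfigurationError(
                    f"trajectory_effects[{t!r}] must be {k} x {p} (one row per transfer)"
                )
            self.trajectory_effects[t] = eff
        if self.hotspot_weights is None:
            self.hotspot_weights = _default_hotspot_weights(
                self.treatments, self.locus_pool_size
            )
        for t in self.treatments:
            if t not in self.hotspot_weights:
                raise ConfigurationError(f"hotspot_weights missing treatment {t!r}")
            w = np.asarray(self.hotspot_weights[t], dtype=float)
            if w.shape != (self.locus_pool_size,):
                raise ConfigurationError(
                    f"hotspot_weights[{t!r}] must have length {self.locus_pool_size}"
                )
            if (w < 0).any() or w.sum() <= 0:
                raise ConfigurationError(
                    f"hotspot_weights[{t!r}] must be nonnegative and normalizable"
                )
            self.hotspot_weights[t] = w / w.sum()
        if self.growth_rates is None:
            self.growth_rates = _default_growth_rates(self.treatments)
        for key, (_, sd) in self.growth_rates.items():
            if sd < 0:
                raise ConfigurationError(f"growth rate sd for {key} must be >= 0")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(config.seed + _STREAM[stream])


def simulate_phenotypes(config: SimulationConfig) -> PhenotypeTable:
    """Respiration table: baseline + trajectory displacement + replicate effect + noise.

    The replicate effect is a single additive scalar shared across substrates
    (population-level growth differences); values are truncated at the assay
    floor of zero.
    """
    rng = _rng(config, "phenotypes")
    rows = []
    for t in config.treatments:
        eff = config.trajectory_effects[t]
        for r in range(1, config.n_replicates_per_treatment + 1):
            rep_id = f"{t}_r{r}"
            rep_effect = rng.normal(0.0, config.replicate_sd) if config.replicate_sd else 0.0
            for i, transfer in enumerate(config.transfers):
                noise = (
                    rng.normal(0.0, config.residual_sd, size=len(config.substrates))
                    if config.residual_sd else np.zeros(len(config.substrates))
                )
                vals = np.maximum(config.baseline + eff[i] + rep_effect + noise, 0.0)
                for j, sub in enumerate(config.substrates):
                    rows.append((rep_id, t, transfer, sub, vals[j]))
    df = pd.DataFrame(rows, columns=["replicate_id", "treatment", "transfer",
                                     "substrate", "value"])
    return PhenotypeTable(df)


def simulate_mutations(config: SimulationConfig) -> MutationProfileSet:
    """Clone variant profiles: Poisson counts over a weighted locus pool.

    Per clone the mutation count is Poisson(mutation_rate_lambda), capped at
    the pool size; loci are drawn without replacement with the treatment's
    hotspot weights; each mutation is nonsynonymous with probability
    nonsyn_fraction, otherwise uniformly synonymous / indel / intergenic.
    """
    rng = _rng(config, "mutations")
    width = len(str(config.locus_pool_size))
    locus_names = [f"L{i:0{width}d}" for i in range(config.locus_pool_size)]
    other = [c for c in MUTATION_CLASSES if c != "nonsynonymous"]
    clones = []
    for t in config.treatments:
        w = config.hotspot_weights[t]
        # without-replacement draws cannot exceed the support of the weights
        support = int(np.count_nonzero(w))
        for r in range(1, config.n_replicates_per_treatment + 1):
            n_mut = min(int(rng.poisson(config.mutation_rate_lambda)), support)
            loci = (
                rng.choice(config.locus_pool_size, size=n_mut, replace=False, p=w)
                if n_mut else np.empty(0, dtype=int)
            )
            muts = []
            for li in loci:
                if rng.random() < config.nonsyn_fraction:
                    mclass = "nonsynonymous"
                else:
                    mclass = other[rng.integers(len(other))]
                muts.append((locus_names[li], mclass))
            clones.append(CloneProfile(f"{t}_c{r}", t, frozenset(muts)))
    return MutationProfileSet(tuple(clones))


def simulate_community(config: SimulationConfig) -> AbundanceTable:
    """Compositional species time series from a log-abundance random walk.

    Per replicate, species log-abundances start equal and take i.i.d. normal
    steps of sd ``sorting_drift_sd`` per transfer (species sorting); the
    composition at each transfer is the softmax of the log-abundances. With
    ``reinvasion_scenario`` the designated species is forced to near-zero
    over the middle transfers and released afterwards in ceil(n/2)
    replicates, emulating reinvasion from low density.
    """
    if len(config.species) < 2:
        raise ConfigurationError("community simulation needs >= 2 species")
    rng = _rng(config, "community")
    s = len(config.species)
    k = len(config.transfers)
    n_rep = config.n_replicates_per_treatment
    affected = set(range(math.ceil(n_rep / 2))) if config.reinvasion_scenario else set()
    if config.reinvasion_scenario:
        if config.reinvasion_species not in config.species:
            raise ConfigurationError(
                f"reinvasion_species {config.reinvasion_species!r} not in species list"
            )
        sp_idx = config.species.index(config.reinvasion_species)
        mid = range(max(1, k // 3), max(1, 2 * k // 3))
    rows = []
    for r in range(n_rep):
        rep_id = f"DP_r{r + 1}"
        z = np.zeros(s)
        for i, transfer in enumerate(config.transfers):
            if i > 0 and config.sorting_drift_sd:
                z = z + rng.normal(0.0, config.sorting_drift_sd, size=s)
            z_eff = z.copy()
            if config.reinvasion_scenario and r in affected and i in mid:
                z_eff[sp_idx] -= 12.0   # crash to near-zero abundance
            comp = np.exp(z_eff - z_eff.max())
            comp /= comp.sum()
            for j, sp in enumerate(config.species):
                rows.append((rep_id, transfer, sp, comp[j]))
    df = pd.DataFrame(rows, columns=["replicate_id", "transfer", "species",
                                     "rel_abundance"])
    return AbundanceTable(df)


def simulate_growth(config: SimulationConfig) -> pd.DataFrame:
    """Start/end density pairs: end = start * exp(m_true + Normal(0, sd)).

    One record per replicate population per (treatment, condition) key in
    ``config.growth_rates``. The true Malthusian rate is recoverable exactly
    when sd = 0.
    """
    rng = _rng(config, "growth")
    rows = []
    for (treatment, condition), (m_true, sd) in config.growth_rates.items():
        for r in range(1, config.n_replicates_per_treatment + 1):
            m = m_true + (rng.normal(0.0, sd) if sd else 0.0)
            n0 = config.start_density
            rows.append((f"{treatment}_{condition}_p{r}", treatment, condition,
                         n0, n0 * math.exp(m), config.growth_duration))
    return pd.DataFrame(rows, columns=["population_id", "treatment", "condition",
                                       "t0_cfu", "t6_cfu", "duration_days"])


def simulate_all(config: SimulationConfig) -> dict:
    """All four synthetic tables from one config (independent RNG streams)."""
    return {
        "phenotypes": simulate_phenotypes(config),
        "mutations": simulate_mutations(config),
        "community": simulate_community(config),
        "growth": simulate_growth(config),
    }
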
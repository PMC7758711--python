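import numpy as np
import pandas as pd
import pytest

from ecoevo.parallelism import CloneProfile, MutationProfileSet
from ecoevo.phenotraj import PhenotypeTable
from ecoevo.synthdata import SimulationConfig


def make_phenotype_table(cells: dict, substrates=("s1",)) -> PhenotypeTable:
    """Build a tidy table from {(treatment, transfer): [obs, ...]} per substrate.

    Each obs is a scalar (univariate) or a length-p sequence.
    """
    rows = []
    for (treat, transfer), obs_list in cells.items():
        for r, obs in enumerate(obs_list):
            vals = np.atleast_1d(obs)
            for sub, v in zip(substrates, vals):
                rows.append((f"{treat}_r{r + 1}", treat, transfer, sub, float(v)))
    return PhenotypeTable(
        pd.DataFrame(rows, columns=["replicate_id", "treatment", "transfer",
                                    "substrate", "value"])
    )


@pytest.fixture
def balanced_univariate():
    """2 treatments x 2 transfers x 3 reps, univariate, with an interaction."""
    rng = np.random.default_rng(42)
    cells = {
        ("A", 1): list(1.0 + rng.normal(0, 0.3, 3)),
        ("A", 2): list(1.5 + rng.normal(0, 0.3, 3)),
        ("B", 1): list(1.0 + rng.normal(0, 0.3, 3)),
        ("B", 2): list(3.0 + rng.normal(0, 0.3, 3)),
    }
    return make_phenotype_table(cells)


@pytest.fixture
def multivariate_table():
    """Default synthetic phenotype table (3 treatments, 5 transfers, 7 substrates)."""
    from ecoevo.synthdata import simulate_phenotypes

    return simulate_phenotypes(SimulationConfig(seed=7))


@pytest.fixture
def toy_profiles():
    """Four clones, two treatments, hand-specified locus sets."""
    return MutationProfileSet((
        CloneProfile("c1", "X", frozenset({("g1", "nonsynonymous"), ("g2", "nonsynonymous")})),
        CloneProfile("c2", "X", frozenset({("g1", "nonsynonymous")})),
        CloneProfile("c3", "Y", frozenset({("g3", "nonsynonymous"), ("g4", "synonymous")})),
        CloneProfile("c4", "Y", frozenset({("g3", "nonsynonymous"), ("g5", "indel")})),
    ))
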
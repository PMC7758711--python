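"""Genomic parallelism statistics for evolved clones.

Each sequenced clone carries a (possibly empty) set of mutated loci. Parallel
evolution within and between selection treatments is quantified by the
Jaccard index between the locus sets of every pair of clones:

    J(A, B) = |A intersect B| / |A union B|

The clone x clone similarity matrix is then analysed as a one-way layout:
every ordered matrix cell (including the diagonal) is an observation, grouped
by the unordered treatment pair of the two clones (T treatments give
T(T+1)/2 groups). Group differences are tested with a permutational ANOVA;
by default the clone -> treatment labels are permuted, which respects the
dependence structure of the matrix. Pairwise treatment contrasts compare
between-treatment cells against the pooled within-treatment cells of the two
treatments with a two-sample t statistic (negative t = clones are less
similar across the two treatments than within them, i.e. genetically
differentiated).

Mutation-count comparisons between treatments use Welch's heteroscedastic
one-way ANOVA (clone counts are small and group variances need not be equal).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, SchemaError
from .phenotraj import PermTestResult, _summarize_perm

__all__ = [
    "MUTATION_CLASSES",
    "CloneProfile",
    "MutationProfileSet",
    "SimilarityMatrix",
    "jaccard_index",
    "similarity_matrix",
    "parallelism_perm_anova",
    "pairwise_treatment_contrasts",
    "mutation_count_anova",
]

MUTATION_CLASSES = ("nonsynonymous", "synonymous", "indel", "intergenic")


@dataclass(frozen=True)
class CloneProfile:
    """One evolved clone: its treatment and its set of (locus, class) mutations."""

    clone_id: str
    treatment: str
    mutations: frozenset[tuple[str, str]]

    def loci(self, class_filter: frozenset[str] | None = None) -> frozenset[str]:
        """Locus tags carried by this clone, optionally restricted by mutation class."""
        if class_filter is None:
            return frozenset(l for l, _ in self.mutations)
        return frozenset(l for l, c in self.mutations if c in class_filter)


@dataclass(frozen=True)
class MutationProfileSet:
    """Collection of clone mutation profiles; clones with zero mutations are valid."""

    clones: tuple[CloneProfile, ...]

    def __post_init__(self) -> None:
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise SchemaError("clone_ids must be unique")
        for c in self.clones:
            for _, mclass in c.mutations:
                if mclass not in MUTATION_CLASSES:
                    raise SchemaError(
                        f"unknown mutation class {mclass!r} on clone {c.clone_id!r}; "
                        f"expected one of {MUTATION_CLASSES}"
                    )

    @property
    def clone_ids(self) -> list[str]:
        return [c.clone_id for c in self.clones]

    @property
    def treatments(self) -> dict[str, str]:
        return {c.clone_id: c.treatment for c in self.clones}

    def counts(self, class_filter: frozenset[str] | None = None) -> pd.Series:
        """Mutations per clone (after class filtering), indexed by clone_id."""
        return pd.Series(
            {c.clone_id: len(c.loci(class_filter)) for c in self.clones}, name="n_mutations"
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clone_id": c.clone_id, "treatment": c.treatment,
             "locus_tag": locus, "mutation_class": mclass}
            for c in self.clones
            for locus, mclass in sorted(c.mutations)
        ]
        # clones without mutations still appear, with empty locus fields
        for c in self.clones:
            if not c.mutations:
                rows.append({"clone_id": c.clone_id, "treatment": c.treatment,
                             "locus_tag": "", "mutation_class": ""})
        return pd.DataFrame(rows, columns=["clone_id", "treatment", "locus_tag", "mutation_class"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationProfileSet":
        required = {"clone_id", "treatment", "locus_tag", "mutation_class"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"mutation table missing column(s): {sorted(missing)}")
        clones = []
        for (cid, treat), grp in df.groupby(["clone_id", "treatment"], sort=False):
            muts = frozenset(
                (str(r.locus_tag), str(r.mutation_class))
                for r in grp.itertuples()
                if str(r.locus_tag) not in ("", "nan")
            )
            clones.append(CloneProfile(str(cid), str(treat), muts))
        return cls(tuple(clones))


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric clone x clone Jaccard matrix with the class filter that produced it."""

    values: pd.DataFrame
    class_filter: frozenset[str] | None
    empty_union: float = 1.0

    @property
    def clone_ids(self) -> list[str]:
        return list(self.values.index)

    def as_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def jaccard_index(loci_a, loci_b, empty_union: float = 1.0) -> float:
    """Jaccard similarity |A n B| / |A u B| between two locus sets.

    Two mutation-free clones have identical (empty) profiles; by default the
    empty-union case scores 1, configurable to 0 via ``empty_union``.
    """
    a, b = set(loci_a), set(loci_b)
    union = a | b
    if not union:
        return float(empty_union)
    return len(a & b) / len(union)


def similarity_matrix(
    profiles: MutationProfileSet,
    class_filter=frozenset({"nonsynonymous"}),
    empty_union: float = 1.0,
) -> SimilarityMatrix:
    """Jaccard similarity for every clone pair after mutation-class filtering.

    ``class_filter=None`` keeps all mutation classes.
    """
    if len(profiles.clones) < 2:
        raise DesignError("similarity matrix needs >= 2 clones")
    if class_filter is not None:
        class_filter = frozenset(class_filter)
        unknown = class_filter - set(MUTATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown mutation class(es) {sorted(unknown)}")
    sets = [c.loci(class_filter) for c in profiles.clones]
    n = len(sets)
    mat = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            mat[i, j] = mat[j, i] = jaccard_index(sets[i], sets[j], empty_union)
    ids = profiles.clone_ids
    return SimilarityMatrix(
        values=pd.DataFrame(mat, index=ids, columns=ids),
        class_filter=class_filter,
        empty_union=empty_union,
    )


# ---------------------------------------------------------------------------
# permutational ANOVA over treatment-pair groups
# ---------------------------------------------------------------------------

def _group_codes(treat_codes: np.ndarray, n_treatments: int) -> np.ndarray:
    """N x N matrix of unordered treatment-pair group codes for all cells."""
    lo = np.minimum.outer(treat_codes, treat_codes)
    hi = np.maximum.outer(treat_codes, treat_codes)
    # map unordered pair (lo, hi), lo <= hi < T, to 0..T(T+1)/2-1
    return (lo * (2 * n_treatments - lo - 1)) // 2 + hi


def _oneway_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Classical one-way ANOVA F over grouped cells; F := 0 when SSB = 0."""
    n = len(values)
    counts = np.bincount(codes, minlength=n_groups)
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    present = counts > 0
    g = int(present.sum())
    if g < 2:
        raise DesignError("permutational ANOVA needs >= 2 treatment-pair groups")
    grand = values.sum() / n
    ssb = float(np.sum(sums[present] ** 2 / counts[present]) - n * grand**2)
    sst = float(np.sum(values**2) - n * grand**2)
    ssw = max(sst - ssb, 0.0)
    if ssb <= 1e-14 * max(1.0, sst):
        return 0.0
    if ssw <= 0:
        return np.inf
    return (ssb / (g - 1)) / (ssw / (n - g))


def _matrix_setup(matrix: SimilarityMatrix, treatments: dict[str, str]):
    ids = matrix.clone_ids
    missing = [c for c in ids if c not in treatments]
    if missing:
        raise SchemaError(f"clones without a treatment label: {missing}")
    labels = sorted(set(treatments[c] for c in ids))
    t_index = {t: i for i, t in enumerate(labels)}
    codes = np.array([t_index[treatments[c]] for c in ids])
    values = matrix.as_array().ravel()
    return ids, labels, codes, values


def parallelism_perm_anova(
    matrix: SimilarityMatrix,
    treatments: dict[str, str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    scheme: str = "clone_labels",
) -> PermTestResult:
    """Permutational one-way ANOVA of Jaccard similarity across treatment pairs.

    Observations are all N^2 ordered matrix cells (diagonal included); groups
    are the unordered treatment pairs of the two clones. ``scheme`` selects
    the permutation unit: 'clone_labels' (default) shuffles the
    clone -> treatment map and regroups cells, preserving the matrix
    dependence structure; 'cell_values' shuffles cell values over the fixed
    grouping.
    """
    if scheme not in ("clone_labels", "cell_values"):
        raise ValueError("scheme must be 'clone_labels' or 'cell_values'")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if seed is None:
        raise ValueError("seed is required for a randomized permutation test")
    ids, labels, codes, values = _matrix_setup(matrix, treatments)
    n_t = len(labels)
    n_groups = n_t * (n_t + 1) // 2
    cell_codes = _group_codes(codes, n_t).ravel()
    obs_f = _oneway_f(values, cell_codes, n_groups)
    n_cells = len(values)
    g_obs = len(np.unique(cell_codes))

    rng = np.random.default_rng(seed)
    stats = np.empty(n_permutations)
    for i in range(n_permutations):
        if scheme == "clone_labels":
            perm_codes = codes[rng.permutation(len(ids))]
            cc = _group_codes(perm_codes, n_t).ravel()
            stats[i] = _oneway_f(values, cc, n_groups)
        else:
            stats[i] = _oneway_f(values[rng.permutation(n_cells)], cell_codes, n_groups)
    return _summarize_perm(
        "jaccard_permanova_F",
        obs_f,
        stats,
        n_permutations,
        seed,
        df=(float(g_obs - 1), float(n_cells - g_obs)),
    )


def pairwise_treatment_contrasts(
    matrix: SimilarityMatrix,
    treatments: dict[str, str],
    n_permutations: int = 10_000,
    seed: int | None = None,
    scheme: str = "clone_labels",
) -> list[PermTestResult]:
    """Two-sample t contrasts of between- vs within-treatment similarity.

    For each treatment pair (A, B) the contrast compares the cells of the
    between-group A:B against the pooled within-group cells A:A and B:B.
    A negative t means clones from different treatments are less similar
    than clones within a treatment (genetic differentiation). p-values are
    two-sided, by the same permutation scheme as the ANOVA.
    """
    if scheme not in ("clone_labels", "cell_values"):
        raise ValueError("scheme must be 'clone_labels' or 'cell_values'")
    if seed is None:
        raise ValueError("seed is required for a randomized permutation test")
    ids, labels, codes, values = _matrix_setup(matrix, treatments)
    n_t = len(labels)
    cell_codes = _group_codes(codes, n_t).ravel()

    def pair_code(i: int, j: int) -> int:
        lo, hi = min(i, j), max(i, j)
        return (lo * (2 * n_t - lo - 1)) // 2 + hi

    def contrast_t(cc: np.ndarray, ia: int, ib: int) -> float:
        between = values[cc == pair_code(ia, ib)]
        within = values[np.isin(cc, [pair_code(ia, ia), pair_code(ib, ib)])]
        if len(between) < 2 or len(within) < 2:
            raise DesignError("contrast group with < 2 cells")
        na, nb = len(between), len(within)
        va, vb = between.var(ddof=1), within.var(ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 <= 0:
            return 0.0
        return float((between.mean() - within.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))

    rng = np.random.default_rng(seed)
    pairs = list(itertools.combinations(range(n_t), 2))
    observed = {pr: contrast_t(cell_codes, *pr) for pr in pairs}
    perm_stats = {pr: np.empty(n_permutations) for pr in pairs}
    for i in range(n_permutations):
        if scheme == "clone_labels":
            cc = _group_codes(codes[rng.permutation(len(ids))], n_t).ravel()
            vals = values
        else:
            cc = cell_codes
            vals_perm = values[rng.permutation(len(values))]
            vals = vals_perm
        for pr in pairs:
            if scheme == "clone_labels":
                perm_stats[pr][i] = contrast_t(cc, *pr)
            else:
                between = vals[cc == pair_code(*pr)]
                within = vals[np.isin(cc, [pair_code(pr[0], pr[0]), pair_code(pr[1], pr[1])])]
                na, nb = len(between), len(within)
                va, vb = between.var(ddof=1), within.var(ddof=1)
                sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
                perm_stats[pr][i] = (
                    0.0 if sp2 <= 0
                    else (between.mean() - within.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
                )
    return [
        _summarize_perm(
            "between_vs_within_t",
            observed[pr],
            perm_stats[pr],
            n_permutations,
            seed,
            label=f"{labels[pr[0]]}:{labels[pr[1]]}",
            two_sided=True,
        )
        for pr in pairs
    ]


def mutation_count_anova(profiles: MutationProfileSet, class_filter=None):
    """Welch's heteroscedastic ANOVA of per-clone mutation counts across treatments.

    ``class_filter=None`` counts all mutation classes; pass e.g.
    ``{'nonsynonymous'}`` to restrict. Delegates to
    :func:`ecoevo.growth_stats.welch_anova`.
    """
    from .growth_stats import welch_anova

    if class_filter is not None:
        class_filter = frozenset(class_filter)
        unknown = class_filter - set(MUTATION_CLASSES)
        if unknown:
            raise ValueError(f"unknown mutation class(es) {sorted(unknown)}")
    counts = profiles.counts(class_filter)
    treat = pd.Series(profiles.treatments)
    groups = treat.loc[counts.index]
    by_group = counts.groupby(groups)
    if by_group.ngroups < 2 or (by_group.size() < 2).any():
        raise DesignError("mutation count ANOVA needs >= 2 treatments with >= 2 clones each")
    return welch_anova(counts.to_numpy(dtype=float), groups.to_numpy())
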
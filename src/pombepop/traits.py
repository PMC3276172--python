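"""Trait-profile construction, clustering and similarity analysis.

A strain's trait profile is its vector of reference-relative values
log2(strain / reference) over all traits (fitness component ×
environment). Profiles are compared by Pearson correlation computed
over pairwise-complete traits; hierarchical clustering uses the
distance 1 − r with average linkage. Group-level structure is tested by
comparing same-group against different-group pairwise correlations
(two-sample t-test), atypicality by correlating each strain against the
collection mean profile, and per-strain trait deviation by per-trait
t-tests against the rest of the collection with Benjamini–Hochberg FDR
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TraitMatrix",
    "ClusterTree",
    "SimilarityReport",
    "build_trait_matrix",
    "cluster_profiles",
    "group_similarity",
    "atypicality_ranking",
    "deviant_trait_fraction",
]


@dataclass
class TraitMatrix:
    """Strains × traits matrix of log2(strain/reference); NaN = missing."""

    values: pd.DataFrame
    annotations: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.annotations is None:
            self.annotations = pd.DataFrame(index=self.values.index)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClusterTree:
    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            l, r = walk(node.left), walk(node.right)
            dl = node.dist - node.left.dist
            dr = node.dist - node.right.dist
            return f"({l}:{dl:.6g},{r}:{dr:.6g})"

        return walk(tree) + ";"


@dataclass
class SimilarityReport:
    within_mean: float
    between_mean: float
    within_sem: float
    between_sem: float
    t_statistic: float
    p_value: float
    n_within: int
    n_between: int


def build_trait_matrix(
    components: pd.DataFrame,
    reference: str,
    annotations: pd.DataFrame | None = None,
) -> TraitMatrix:
    """log2(strain/reference) per trait from a long component table.

    ``components`` columns: strain, environment, component, value (raw,
    positive); replicate runs should be averaged beforehand or carry a
    'run' column (then they are averaged here). The reference must be
    measured in every trait it is compared on; strains missing a trait
    get NaN.
    """
    required = {"strain", "environment", "component", "value"}
    if not required.issubset(components.columns):
        raise ValueError(f"components table needs columns {sorted(required)}")
    df = components.groupby(["strain", "environment", "component"], as_index=False)[
        "value"
    ].mean()
    df["trait"] = df["component"] + ":" + df["environment"]
    wide = df.pivot(index="strain", columns="trait", values="value")
    if reference not in wide.index:
        raise ValueError(f"reference strain {reference!r} not measured")
    ref = wide.loc[reference]
    if ref.isna().any():
        missing = list(ref[ref.isna()].index)
        raise ValueError(f"reference missing for traits {missing[:5]}")
    values = np.log2(wide.divide(ref, axis=1))
    if annotations is not None:
        annotations = annotations.reindex(values.index)
    return TraitMatrix(values=values, annotations=annotations)


def _pairwise_complete_corr(values: pd.DataFrame, min_shared: int = 3) -> np.ndarray:
    """Pearson r matrix over pairwise-complete traits; errors when a
    strain pair shares fewer than ``min_shared`` traits."""
    m = values.to_numpy(dtype=float)
    n = m.shape[0]
    out = np.ones((n, n))
    offenders = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(np.isnan(m[i]) | np.isnan(m[j]))
            if ok.sum() < min_shared:
                offenders.append((values.index[i], values.index[j]))
                continue
            x, y = m[i, ok], m[j, ok]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                r = 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            out[i, j] = out[j, i] = r
    if offenders:
        raise ValueError(
            f"strain pairs share <{min_shared} traits: {offenders[:10]}"
        )
    return out


def cluster_profiles(tm: TraitMatrix) -> ClusterTree:
    """Average-linkage hierarchical clustering on 1 − Pearson r."""
    if len(tm.strains) < 3:
        raise ValueError("clustering needs at least 3 strains")
    corr = _pairwise_complete_corr(tm.values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    link = hierarchy.average(condensed)
    return ClusterTree(linkage=link, labels=tm.strains)


def group_similarity(
    tm: TraitMatrix,
    grouping: str | pd.Series,
    equal_var: bool = False,
) -> SimilarityReport:
    """Same-group vs different-group pairwise-correlation comparison.

    ``grouping`` is an annotation column name (e.g. 'haplotype_id' or
    'origin') or a Series indexed by strain. The test is two-sample
    Welch by default; ``equal_var=True`` gives the pooled-variance
    Student form.
    """
    if isinstance(grouping, str):
        if grouping not in tm.annotations.columns:
            raise ValueError(f"annotation column {grouping!r} missing")
        labels = tm.annotations[grouping]
    else:
        labels = grouping.reindex(tm.values.index)
    corr = _pairwise_complete_corr(tm.values)
    same, diff = [], []
    lab = labels.to_numpy()
    n = len(lab)
    for i in range(n):
        for j in range(i + 1, n):
            if pd.isna(lab[i]) or pd.isna(lab[j]):
                continue
            (same if lab[i] == lab[j] else diff).append(corr[i, j])
    if not same:
        raise ValueError("no same-group strain pairs")
    if not diff:
        raise ValueError("no different-group strain pairs")
    same_a, diff_a = np.asarray(same), np.asarray(diff)
    t, p = ttest_ind(same_a, diff_a, equal_var=equal_var)
    return SimilarityReport(
        within_mean=float(same_a.mean()),
        between_mean=float(diff_a.mean()),
        within_sem=float(same_a.std(ddof=1) / np.sqrt(same_a.size))
        if same_a.size > 1 else float("nan"),
        between_sem=float(diff_a.std(ddof=1) / np.sqrt(diff_a.size))
        if diff_a.size > 1 else float("nan"),
        t_statistic=float(t),
        p_value=float(p),
        n_within=same_a.size,
        n_between=diff_a.size,
    )


def atypicality_ranking(tm: TraitMatrix) -> pd.DataFrame:
    """Rank strains by similarity to the collection mean profile.

    Returns a frame sorted ascending in r (most atypical first) with
    columns strain, similarity, rank.
    """
    if len(tm.strains) < 3:
        raise ValueError("ranking needs at least 3 strains")
    m = tm.values.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_profile = np.nanmean(m, axis=0)
    sims = []
    for i, strain in enumerate(tm.strains):
        ok = ~(np.isnan(m[i]) | np.isnan(mean_profile))
        x, y = m[i, ok], mean_profile[ok]
        if ok.sum() < 3 or x.std() == 0 or y.std() == 0:
            sims.append(float("nan"))
        else:
            sims.append(float(np.corrcoef(x, y)[0, 1]))
    out = pd.DataFrame({"strain": tm.strains, "similarity": sims})
    out = out.sort_values("similarity", na_position="last").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def deviant_trait_fraction(
    replicates: pd.DataFrame,
    strain: str,
    fdr: float = 0.05,
    equal_var: bool = False,
) -> float:
    """Fraction of traits where a strain deviates from the collection.

    ``replicates`` columns: strain, trait, value — replicate-level
    measurements. Per trait, the focal strain's replicates are tested
    against all other strains' values (two-sample t-test); p-values are
    Benjamini–Hochberg corrected at the given FDR and the significant
    fraction returned. Traits with <2 focal replicates are skipped with
    a warning.
    """
    required = {"strain", "trait", "value"}
    if not required.issubset(replicates.columns):
        raise ValueError(f"replicates table needs columns {sorted(required)}")
    pvals = []
    n_tested = n_skipped = 0
    for trait, sub in replicates.groupby("trait"):
        focal = sub.loc[sub["strain"] == strain, "value"].to_numpy()
        others = sub.loc[sub["strain"] != strain, "value"].to_numpy()
        if focal.size < 2 or others.size < 2:
            n_skipped += 1
            continue
        if np.allclose(focal.std(), 0) and np.allclose(others.std(), 0):
            pvals.append(0.0 if not np.isclose(focal.mean(), others.mean()) else 1.0)
            n_tested += 1
            continue
        _, p = ttest_ind(focal, others, equal_var=equal_var)
        pvals.append(float(p) if np.isfinite(p) else 1.0)
        n_tested += 1
    if n_skipped:
        warnings.warn(f"{n_skipped} traits skipped (too few replicates)")
    if n_tested == 0:
        return 0.0
    reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return float(reject.sum()) / n_tested
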
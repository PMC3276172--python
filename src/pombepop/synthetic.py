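"""Synthetic-data generators with known ground truth.

Every pipeline input can be generated here at desk scale:

* ``simulate_coalescent`` — a standard neutral coalescent (single deme)
  or symmetric-island structured coalescent, with infinite-sites
  mutations placed uniformly on branches. θ is the per-locus population
  mutation rate (2Nₑu·L for haploids), so E[S] = θ·a₁ in a single deme.
* ``simulate_growth_curve`` — three-phase OD series (flat lag,
  exponential at μ_max, ceiling at the final OD) sampled every 20 min,
  with additive Gaussian noise floored at OD 0.001. The ground-truth
  lag, doubling time ln2/μ and efficiency are exact by construction.
* ``simulate_trait_matrix`` — strain × trait values as planted group
  means plus strain noise, with optional outlier strains whose traits
  are shifted by several noise SDs.
* ``fixture_isolate_collection`` — the 84-strain, seven-locus synthetic
  collection whose identity partition reproduces the published 40
  compound-haplotype groups with the printed origins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthCurve
from .loci import SEVEN_LOCI, LocusAlignment, LocusDef
from .traits import TraitMatrix

__all__ = [
    "CoalescentParams",
    "GrowthParams",
    "TraitMatrixParams",
    "simulate_coalescent",
    "simulate_growth_curve",
    "simulate_trait_matrix",
    "simulate_trait_replicates",
    "fixture_isolate_collection",
]

BASES = np.array(["A", "C", "G", "T"])

#: Extra pre-merger divergence (coalescent time units) applied when
#: demes are completely isolated (migration_rate = 0), so that a
#: deep-split scenario is expressible without a divergence parameter.
ISOLATED_DEME_SPLIT_TIME = 5.0


@dataclass(frozen=True)
class CoalescentParams:
    n_samples: int
    theta: float
    seq_length: int = 1000
    n_demes: int = 1
    migration_rate: float = 0.0
    recombination: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need n_samples >= 2")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be >= 0")
        if self.recombination:
            raise ValueError("intra-locus recombination is not modelled")


@dataclass(frozen=True)
class GrowthParams:
    lag_h: float = 4.0
    mu_max: float = 0.3465
    od_start: float = 0.1
    od_final: float = 1.3
    noise_sd: float = 0.01
    sample_interval_min: float = 20.0
    duration_h: float = 48.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.od_final > self.od_start > 0:
            raise ValueError("need od_final > od_start > 0")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be positive")
        if self.lag_h < 0:
            raise ValueError("lag_h must be >= 0")
        if self.sample_interval_min <= 0:
            raise ValueError("sample_interval_min must be positive")


@dataclass(frozen=True)
class TraitMatrixParams:
    n_strains: int = 40
    n_traits: int = 126
    n_groups: int = 2
    group_effect_sd: float = 1.0
    noise_sd: float = 0.1
    outlier_ids: tuple[int, ...] = ()
    outlier_fraction: float = 0.2
    outlier_shift: float = 5.0  # in units of noise_sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups > self.n_strains or self.n_groups < 1:
            raise ValueError("need 1 <= n_groups <= n_strains")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if any(i < 0 or i >= self.n_strains for i in self.outlier_ids):
            raise ValueError("outlier_ids out of range")


# ---------------------------------------------------------------------------
# Coalescent


@dataclass
class _Lineage:
    leaves: frozenset
    deme: int
    blen: float = 0.0


def _coalesce(params: CoalescentParams, rng: np.random.Generator):
    """Run the (structured) coalescent; return finalized branches as
    (leafset, length) pairs and the per-sample deme labels."""
    n, d = params.n_samples, params.n_demes
    demes = [i % d for i in range(n)]
    active = [_Lineage(frozenset([i]), demes[i]) for i in range(n)]
    branches: list[tuple[frozenset, float]] = []

    while len(active) > 1:
        counts = np.bincount([l.deme for l in active], minlength=d)
        # within-deme coalescence: rate d per pair (deme size N/d, time
        # in units of 2N·d generations is avoided by scaling rates)
        coal_rates = d * counts * (counts - 1) / 2.0
        mig_rate = params.migration_rate * len(active) if d > 1 else 0.0
        total = coal_rates.sum() + mig_rate
        if total == 0:
            # isolated demes, each down to one lineage: deep split, then
            # merge everything into one ancestral deme
            for l in active:
                l.blen += ISOLATED_DEME_SPLIT_TIME
            for l in active:
                l.deme = 0
            continue
        dt = rng.exponential(1.0 / total)
        for l in active:
            l.blen += dt
        if rng.random() < coal_rates.sum() / total:
            probs = coal_rates / coal_rates.sum()
            deme = rng.choice(d, p=probs)
            idx = [i for i, l in enumerate(active) if l.deme == deme]
            i, j = rng.choice(idx, size=2, replace=False)
            a, b = active[i], active[j]
            branches.append((a.leaves, a.blen))
            branches.append((b.leaves, b.blen))
            parent = _Lineage(a.leaves | b.leaves, deme)
            active = [l for k, l in enumerate(active) if k not in (i, j)]
            active.append(parent)
        else:
            i = rng.integers(len(active))
            others = [k for k in range(d) if k != active[i].deme]
            active[i].deme = int(rng.choice(others))
    return branches, demes


def simulate_coalescent(
    params: CoalescentParams,
    locus: LocusDef | None = None,
) -> LocusAlignment:
    """Simulate an infinite-sites alignment on a neutral coalescent.

    Mutations are Poisson with mean θ/2 × total tree length, placed on
    branches proportionally to length, each at its own site (so every
    segregating site is biallelic). Sample labels are s1..sn; deme
    labels are attached for structured simulations.
    """
    rng = np.random.default_rng(params.seed)
    if locus is None:
        locus = LocusDef("sim", "I", 1, 1 + params.seq_length, "gene")
    branches, demes = _coalesce(params, rng)
    ancestral = rng.choice(BASES, size=params.seq_length)
    matrix = np.tile(ancestral, (params.n_samples, 1))
    total_len = sum(b for _, b in branches)
    n_mut = rng.poisson(params.theta / 2.0 * total_len) if params.theta > 0 else 0
    if n_mut > params.seq_length:
        raise ValueError(
            f"{n_mut} mutations exceed seq_length={params.seq_length}; "
            "increase seq_length or lower theta"
        )
    if n_mut > 0:
        weights = np.array([b for _, b in branches])
        weights = weights / weights.sum()
        picks = rng.choice(len(branches), size=n_mut, p=weights)
        sites = rng.choice(params.seq_length, size=n_mut, replace=False)
        for b_idx, site in zip(picks, sites):
            leaves = branches[b_idx][0]
            derived = rng.choice(BASES[BASES != ancestral[site]])
            for leaf in leaves:
                matrix[leaf, site] = derived
    strains = [f"s{i + 1}" for i in range(params.n_samples)]
    return LocusAlignment(
        locus=locus, strains=strains, matrix=matrix, demes=demes
    )


# ---------------------------------------------------------------------------
# Growth curves


def growth_curve_truth(params: GrowthParams) -> dict[str, float]:
    """Analytic ground-truth fitness components for a parameter set."""
    return {
        "lag_h": params.lag_h,
        "doubling_h": np.log(2) / params.mu_max,
        "efficiency": params.od_final - params.od_start,
    }


def simulate_growth_curve(
    params: GrowthParams,
    strain: str = "sim",
    environment: str = "YES",
    run: int = 1,
) -> GrowthCurve:
    """Three-phase OD curve: flat until lag, exponential at μ_max,
    ceiling at od_final; Gaussian noise, floored at OD 0.001."""
    rng = np.random.default_rng(params.seed)
    t_min = np.arange(0.0, params.duration_h * 60.0 + 0.5,
                      params.sample_interval_min)
    t_h = t_min / 60.0
    od = params.od_start * np.exp(params.mu_max * np.maximum(t_h - params.lag_h, 0.0))
    od = np.minimum(od, params.od_final)
    if params.noise_sd > 0:
        od = od + rng.normal(0.0, params.noise_sd, size=od.shape)
    od = np.maximum(od, 0.001)
    return GrowthCurve(strain=strain, environment=environment, run=run,
                       time_min=t_min, od=od)


# ---------------------------------------------------------------------------
# Trait matrices


def _trait_means(params: TraitMatrixParams, rng: np.random.Generator):
    groups = np.array([i % params.n_groups for i in range(params.n_strains)])
    group_means = rng.normal(0.0, params.group_effect_sd,
                             size=(params.n_groups, params.n_traits))
    means = group_means[groups]
    shifted = np.zeros((params.n_strains, params.n_traits), dtype=bool)
    n_shift = int(round(params.outlier_fraction * params.n_traits))
    for idx in params.outlier_ids:
        cols = rng.choice(params.n_traits, size=n_shift, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_shift)
        means[idx, cols] += signs * params.outlier_shift * params.noise_sd
        shifted[idx, cols] = True
    return means, groups, shifted


def simulate_trait_matrix(params: TraitMatrixParams) -> TraitMatrix:
    """Planted-structure strain × trait matrix.

    The annotations frame carries the ground-truth 'group' label and an
    'is_outlier' flag per strain.
    """
    rng = np.random.default_rng(params.seed)
    means, groups, _ = _trait_means(params, rng)
    values = means + rng.normal(0.0, params.noise_sd, size=means.shape)
    strains = [f"strain{i + 1}" for i in range(params.n_strains)]
    traits = [f"trait{j + 1}" for j in range(params.n_traits)]
    ann = pd.DataFrame(
        {
            "group": groups,
            "is_outlier": [i in params.outlier_ids
                           for i in range(params.n_strains)],
        },
        index=strains,
    )
    return TraitMatrix(
        values=pd.DataFrame(values, index=strains, columns=traits),
        annotations=ann,
    )


def simulate_trait_replicates(
    params: TraitMatrixParams, n_replicates: int = 2
) -> pd.DataFrame:
    """Replicate-level long table (strain, trait, replicate, value)
    drawn around the same planted means as ``simulate_trait_matrix``."""
    rng = np.random.default_rng(params.seed)
    means, _, _ = _trait_means(params, rng)
    rows = []
    strains = [f"strain{i + 1}" for i in range(params.n_strains)]
    traits = [f"trait{j + 1}" for j in range(params.n_traits)]
    noise = rng.normal(
        0.0, params.noise_sd,
        size=(n_replicates, params.n_strains, params.n_traits),
    )
    for rep in range(n_replicates):
        vals = means + noise[rep]
        for i, s in enumerate(strains):
            for j, t in enumerate(traits):
                rows.append((s, t, rep + 1, vals[i, j]))
    return pd.DataFrame(rows, columns=["strain", "trait", "replicate", "value"])


# ---------------------------------------------------------------------------
# The 84-strain isolate-collection fixture

#: Published compound-haplotype groups: (members, origin). Group ids are
#: the row order (1-based). 84 strains in 40 groups.
ISOLATE_GROUPS: tuple[tuple[tuple[str, ...], str], ...] = (
    (("UWOPS 92.229.4",), "Mexico"),
    (("UWOPS 94.422.2",), "Mexico"),
    (("UFMG A529", "UFMG 790", "UFMG A826"), "Brazil, Belo Horizonte and Vicosa"),
    (("UFMG R416", "UFMG R418", "UFMG R420", "UFMG R424", "UFMG R435"),
     "Brazil; Aracaju"),
    (("UFMG R427",), "Brazil; Aracaju"),
    (("UFMG A1263",), "Brazil, Vicosa"),
    (("UFMG A521", "UFMG A571", "UFMG A602"), "Brazil, Belo Horizonte"),
    (("UFMG A1000", "UFMG A1153"), "Brazil, Belo Horizonte and Salinas"),
    (("UFMG R434",), "Brazil; Aracaju"),
    (("UFMG R428",), "Brazil; Aracaju"),
    (("UFMG A1152",), "Brazil, Salinas"),
    (("UFMG R437",), "Brazil; Aracaju"),
    (("UFMG A738",), "Brazil, Belo Horizonte"),
    (("NCYC 683", "NCYC 2387", "DBVPG4435", "AWRI 442"),
     "Spain, Italy, South Australia"),
    (("NCYC 936", "NCYC 2355-1"), "Sri Lanka, Japan"),
    (("CBS 356", "NCYC 132", "NCYC535", "DBVPG2817", "DBVPG4437", "AWRI 141"),
     "Eastern Mediterranean, Africa, Italy, Australia"),
    (("NCYC 380", "CBS 1063", "DBVPG 6281", "CBS 355", "DBVPG 6417"),
     "Sicily, Spain"),
    (("DBVPG 4433", "DBVPG 6279", "DBVPG 6610", "DBVPG 6699", "Y0036",
      "Y0037", "CRUK 972", "CRUK 975", "Y 468", "Y 469"),
     "Germany, Indo-China, South Africa, France"),
    (("CBS 2628",), "Pakistan"),
    (("CBS 2775", "CBS 2776", "CBS 2777"), "Japan (all)"),
    (("CBS 5680",), "Poland"),
    (("CBS 5682",), "South Africa"),
    (("CBS 7335",), "Spain"),
    (("DBVPG 2801",), "Tunisia"),
    (("DBVPG 2805",), "Malta"),
    (("DBVPG 2804", "DBVPG 2806", "DBVPG 2807", "DBVPG 2808", "DBVPG 2809"),
     "Malta (all)"),
    (("DBVPG 2810",), "Malta"),
    (("DBVPG 2811", "DBVPG 2812", "DBVPG 2814", "DBVPG 2815", "DBVPG 2816",
      "DBVPG 2818"), "Sicily (all)"),
    (("Y470",), ""),
    (("Y 831", "Y 832"), "South Africa (both)"),
    (("CBS 374",), "Delft"),
    (("DBVPG 6447", "DBVPG 6449"), ""),
    (("CBS 358",), ""),
    (("CBS 1058",), "Java"),
    (("CBS 357",), "Jamaica"),
    (("CBS 352",), "Indonesia"),
    (("CBS 1057",), "Sweden"),
    (("CBS 1059",), "Mauritius"),
    (("CBS 1044",), ""),
    (("L2470",), "Chile"),
)

#: Per-locus haplotype variant assigned to each compound group; the
#: first two loci jointly distinguish all 40 groups (8 × 5 variants),
#: the rest add shared locus-level haplotypes for realism.
_LOCUS_VARIANT_RULES = (
    lambda g: g % 8,
    lambda g: g // 8,
    lambda g: g % 3,
    lambda g: g % 2,
    lambda g: g % 5,
    lambda g: g % 4,
    lambda g: g % 6,
)


def _variant_sequence(base: np.ndarray, variant: int) -> np.ndarray:
    """Apply variant-specific substitutions at two dedicated columns."""
    seq = base.copy()
    if variant > 0:
        for col in (10 + 2 * variant, 11 + 2 * variant):
            seq[col] = BASES[(int(np.where(BASES == seq[col])[0][0]) + 1) % 4]
    return seq


def fixture_isolate_collection(
    seed: int = 0,
) -> tuple[dict[str, LocusAlignment], pd.DataFrame]:
    """84 synthetic strains at the seven sequenced loci.

    The identity partition of the concatenated sequences reproduces the
    published 40 compound-haplotype groups exactly; sequences are
    otherwise random (seeded). Returns per-locus alignments (keyed by
    locus name) and a metadata frame (strain, haplotype_id, origin).
    """
    rng = np.random.default_rng(seed)
    strains: list[str] = []
    group_of: list[int] = []
    meta_rows = []
    for gid0, (members, origin) in enumerate(ISOLATE_GROUPS):
        for s in members:
            strains.append(s)
            group_of.append(gid0)
            meta_rows.append({"strain": s, "haplotype_id": gid0 + 1,
                              "origin": origin})
    alignments: dict[str, LocusAlignment] = {}
    for locus, rule in zip(SEVEN_LOCI, _LOCUS_VARIANT_RULES):
        base = rng.choice(BASES, size=locus.span)
        variants = {v: _variant_sequence(base, v)
                    for v in {rule(g) for g in range(len(ISOLATE_GROUPS))}}
        matrix = np.vstack([variants[rule(g)] for g in group_of])
        alignments[locus.name] = LocusAlignment(
            locus=locus, strains=list(strains), matrix=matrix
        )
    return alignments, pd.DataFrame(meta_rows)
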
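"""Linkage disequilibrium among informative SNPs and the four-gamete test.

For each pair of biallelic markers the gametic disequilibrium
D = p_AB − p_A·p_B is computed together with its normalized form D′
(sign preserved), the allele correlation r, and the association
chi-square χ² = n·r² (no continuity correction) with significance codes
at the 5%/1%/0.1% levels. The four-gamete test declares recombination
between a marker pair when all four gametic types are observed; the
minimum number of recombination events Rm follows the interval-reduction
rule of Hudson and Kaplan.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .loci import GAP_CHARS, LocusAlignment

__all__ = [
    "SNPMarker",
    "LDResult",
    "informative_snps",
    "ld_statistics",
    "four_gamete_test",
]

_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class SNPMarker:
    """A biallelic site: alleles ordered (major, minor), states coded
    0 = major, 1 = minor, NaN = missing."""

    position: int
    alleles: tuple[str, str]
    states: np.ndarray

    @property
    def minor_count(self) -> int:
        return int(np.nansum(self.states))


@dataclass
class LDResult:
    markers: list[SNPMarker]
    D: np.ndarray
    Dprime: np.ndarray
    r: np.ndarray
    chi2: np.ndarray
    n_pair: np.ndarray
    stars: np.ndarray
    four_gamete: np.ndarray

    @property
    def positions(self) -> list[int]:
        return [m.position for m in self.markers]


def informative_snps(aln: LocusAlignment) -> list[SNPMarker]:
    """Parsimony-informative biallelic columns (minor-allele count ≥ 2).

    Columns with more than two observed alleles, singleton variants or
    no variation are excluded. Gap/N cells become missing states.
    """
    out: list[SNPMarker] = []
    for j in range(aln.width):
        col = aln.matrix[:, j]
        missing = np.isin(col, list(GAP_CHARS))
        obs = col[~missing]
        alleles, counts = np.unique(obs, return_counts=True)
        if alleles.size != 2:
            continue
        order = np.argsort(-counts, kind="stable")
        major, minor = alleles[order[0]], alleles[order[1]]
        if counts[order[1]] < 2:
            continue
        states = np.full(col.shape, np.nan)
        states[col == major] = 0.0
        states[col == minor] = 1.0
        out.append(
            SNPMarker(
                position=int(aln.positions[j]),
                alleles=(str(major), str(minor)),
                states=states,
            )
        )
    return out


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, int]:
    ok = ~(np.isnan(a) | np.isnan(b))
    x, y = a[ok].astype(int), b[ok].astype(int)
    table = np.zeros((2, 2))
    for xi, yi in zip(x, y):
        table[xi, yi] += 1
    return table, int(ok.sum())


def _gamete_types(a: np.ndarray, b: np.ndarray) -> int:
    table, _ = _pair_counts(a, b)
    return int((table > 0).sum())


def ld_statistics(markers: list[SNPMarker], n: int | None = None) -> LDResult:
    """All-pairs LD statistics.

    Missing genotypes are excluded pairwise; χ² uses the pairwise-
    complete sample size (or ``n`` if given, overriding it for complete
    data). Pairs where either marker is monomorphic among complete
    cases get NaN entries.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    k = len(markers)
    D = np.full((k, k), np.nan)
    Dp = np.full((k, k), np.nan)
    r = np.full((k, k), np.nan)
    chi2 = np.full((k, k), np.nan)
    npair = np.zeros((k, k), dtype=int)
    stars = np.full((k, k), "", dtype=object)
    fg = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(D, 0.0)
    for i, j in itertools.combinations(range(k), 2):
        table, nc = _pair_counts(markers[i].states, markers[j].states)
        npair[i, j] = npair[j, i] = nc
        if nc == 0:
            continue
        n_eff = n if (n is not None and nc == len(markers[i].states)) else nc
        pA = table[1].sum() / nc  # minor-allele freq at marker i
        pB = table[:, 1].sum() / nc
        if pA in (0.0, 1.0) or pB in (0.0, 1.0):
            continue
        pAB = table[1, 1] / nc
        d = pAB - pA * pB
        if d >= 0:
            dmax = min(pA * (1 - pB), (1 - pA) * pB)
        else:
            dmax = min(pA * pB, (1 - pA) * (1 - pB))
        rij = d / np.sqrt(pA * (1 - pA) * pB * (1 - pB))
        c = n_eff * rij**2
        D[i, j] = D[j, i] = d
        Dp[i, j] = Dp[j, i] = d / dmax if dmax > 0 else np.nan
        r[i, j] = r[j, i] = rij
        chi2[i, j] = chi2[j, i] = c
        p = chi2_dist.sf(c, df=1)
        code = ""
        for level, sym in _STAR_LEVELS:
            if p < level:
                code = sym
                break
        stars[i, j] = stars[j, i] = code
        four = _gamete_types(markers[i].states, markers[j].states) == 4
        fg[i, j] = fg[j, i] = four
    return LDResult(
        markers=list(markers),
        D=D, Dprime=Dp, r=r, chi2=chi2, n_pair=npair, stars=stars,
        four_gamete=fg,
    )


def four_gamete_test(markers: list[SNPMarker]) -> tuple[np.ndarray, int]:
    """Pairwise four-gamete matrix and the minimum recombination count Rm.

    Rm counts disjoint marker intervals whose endpoints show all four
    gametic types (Hudson–Kaplan interval reduction); Rm = 0 means the
    data are compatible with no recombination.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 markers")
    k = len(markers)
    fg = np.zeros((k, k), dtype=bool)
    intervals = []
    for i, j in itertools.combinations(range(k), 2):
        if _gamete_types(markers[i].states, markers[j].states) == 4:
            fg[i, j] = fg[j, i] = True
            lo = min(markers[i].position, markers[j].position)
            hi = max(markers[i].position, markers[j].position)
            intervals.append((lo, hi))
    # greedy disjoint-interval count = minimum number of recombinations
    rm = 0
    last_end = -np.inf
    for lo, hi in sorted(intervals, key=lambda iv: iv[1]):
        if lo >= last_end:
            rm += 1
            last_end = hi
    return fg, rm
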
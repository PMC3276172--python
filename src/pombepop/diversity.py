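"""Nucleotide diversity, neutrality statistics and effective population size.

Implements the classic summary statistics for a sample of n haploid
sequences: mean pairwise diversity π, Watterson's θ_W = S/a₁ with
a₁ = Σ_{i=1}^{n−1} 1/i, Tajima's D with the standard coefficient chain,
and the haploid effective-size estimate Nₑ = π/(2u). Standard deviations
of π and θ use Tajima's total-variance formulas (evolutionary plus
sampling variance), the convention of the classic population-genetics
packages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .loci import GAP_CHARS, LocusAlignment, collapse_haplotypes

__all__ = [
    "DiversitySummary",
    "NeEstimate",
    "harmonic_number",
    "segregating_sites",
    "pairwise_pi",
    "watterson_theta",
    "tajimas_d",
    "effective_population_size",
    "diversity_table",
]


def harmonic_number(n: int, power: int = 1) -> float:
    """Σ_{i=1}^{n} 1/i**power by direct summation."""
    return sum(1.0 / i**power for i in range(1, n + 1))


@dataclass
class DiversitySummary:
    locus: str
    n: int
    L: int
    S: int
    pi_site: float
    pi_seq: float
    theta_site: float
    theta_seq: float
    tajima_d: float
    sd_pi: float
    sd_theta: float


@dataclass
class NeEstimate:
    pi_site: float
    mu: float
    ne: float

    def rounded(self) -> float:
        """Nₑ rounded to one significant figure, the headline convention."""
        if self.ne == 0:
            return 0.0
        exp = math.floor(math.log10(abs(self.ne)))
        return round(self.ne, -exp)


def _complete_columns(matrix: np.ndarray) -> np.ndarray:
    bad = np.zeros(matrix.shape[1], dtype=bool)
    for ch in GAP_CHARS:
        bad |= (matrix == ch).any(axis=0)
    return matrix[:, ~bad]


def segregating_sites(aln: LocusAlignment) -> int:
    """Count columns with more than one allele (complete deletion)."""
    m = _complete_columns(aln.matrix)
    return int(sum((np.unique(m[:, j]).size > 1) for j in range(m.shape[1])))


def pairwise_pi(aln: LocusAlignment, mode: str = "complete") -> tuple[float, float]:
    """Mean pairwise difference per site and per sequence.

    π_seq is the average Hamming distance over all n(n−1)/2 unordered
    pairs; π_site divides by the number of sites used. ``mode`` is
    'complete' (drop columns with any gap/N; default, consistent with S)
    or 'pairwise' (each pair compared over its own complete columns,
    rescaled to the full filtered length).
    """
    n = aln.n
    if n < 2:
        raise ValueError("pairwise diversity needs at least 2 sequences")
    if mode == "complete":
        m = _complete_columns(aln.matrix)
        L = m.shape[1]
        if L == 0:
            return 0.0, 0.0
        npairs = n * (n - 1) / 2
        diffs = 0.0
        for j in range(L):
            _, counts = np.unique(m[:, j], return_counts=True)
            same = sum(c * (c - 1) / 2 for c in counts)
            diffs += npairs - same
        pi_seq = diffs / npairs
        return pi_seq / L, pi_seq
    elif mode == "pairwise":
        m = aln.matrix
        ok = ~np.isin(m, list(GAP_CHARS))
        L = m.shape[1]
        tot, npairs = 0.0, 0
        for i in range(n):
            for j in range(i + 1, n):
                shared = ok[i] & ok[j]
                ns = int(shared.sum())
                if ns == 0:
                    continue
                d = int((m[i, shared] != m[j, shared]).sum())
                tot += d * L / ns
                npairs += 1
        if npairs == 0:
            raise ValueError("no comparable pairs")
        pi_seq = tot / npairs
        return pi_seq / L, pi_seq
    raise ValueError(f"unknown mode {mode!r}")


def watterson_theta(S: int, n: int, L: int) -> tuple[float, float]:
    """Watterson's estimator: θ_seq = S/a₁, θ_site = θ_seq/L."""
    if n < 2:
        raise ValueError("need n >= 2")
    if L < 1:
        raise ValueError("need L >= 1")
    a1 = harmonic_number(n - 1)
    theta_seq = S / a1
    return theta_seq / L, theta_seq


def _tajima_coefficients(n: int) -> tuple[float, float]:
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(pi_seq: float, S: int, n: int) -> float:
    """Tajima's D = (π_seq − S/a₁)/√(e₁S + e₂S(S−1))."""
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        warnings.warn("Tajima's D undefined for S=0; returning NaN")
        return float("nan")
    a1 = harmonic_number(n - 1)
    e1, e2 = _tajima_coefficients(n)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_seq - S / a1) / math.sqrt(var)


def _sd_pi_seq(pi_seq: float, n: int) -> float:
    # Tajima's total variance of pi (evolutionary + sampling), theta -> pi_seq
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    return math.sqrt(b1 * pi_seq + b2 * pi_seq**2)


def _sd_theta_seq(theta_seq: float, n: int) -> float:
    a1 = harmonic_number(n - 1)
    a2 = harmonic_number(n - 1, power=2)
    return math.sqrt(theta_seq / a1 + a2 * theta_seq**2 / a1**2)


def effective_population_size(pi_site: float, mu: float = 0.33e-9) -> NeEstimate:
    """Haploid effective size from π = 2Nₑu."""
    if mu <= 0:
        raise ValueError("mutation rate must be positive")
    return NeEstimate(pi_site=pi_site, mu=mu, ne=pi_site / (2 * mu))


def diversity_table(
    alns: Iterable[LocusAlignment],
    use_all_strains: bool = False,
) -> pd.DataFrame:
    """Per-locus diversity summary (one row per locus).

    By default diversity is computed over one representative per
    compound-haplotype group (the collection-level analysis deliberately
    discounts clonal resampling of identical strains); pass
    ``use_all_strains=True`` to use every sequence.
    """
    alns = list(alns)
    if not use_all_strains:
        table = collapse_haplotypes(alns)
        reps = table.representatives()
        subset = []
        for a in alns:
            idx = [a.strains.index(s) for s in reps]
            subset.append(
                LocusAlignment(
                    locus=a.locus,
                    strains=reps,
                    matrix=a.matrix[idx],
                    positions=a.positions,
                )
            )
        alns = subset
    rows = []
    for a in alns:
        m = _complete_columns(a.matrix)
        L = m.shape[1]
        n = a.n
        S = segregating_sites(a)
        pi_site, pi_seq = pairwise_pi(a)
        theta_site, theta_seq = watterson_theta(S, n, L)
        d = tajimas_d(pi_seq, S, n) if (S > 0 and n >= 4) else float("nan")
        rows.append(
            DiversitySummary(
                locus=a.locus.name,
                n=n,
                L=L,
                S=S,
                pi_site=pi_site,
                pi_seq=pi_seq,
                theta_site=theta_site,
                theta_seq=theta_seq,
                tajima_d=d,
                sd_pi=_sd_pi_seq(pi_seq, n) / L if L else 0.0,
                sd_theta=_sd_theta_seq(theta_seq, n) / L if L else 0.0,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
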
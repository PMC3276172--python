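"""Pairwise F_st between geographically labelled haplotype groups.

The default estimator is the pairwise-difference (AMOVA/Hudson) form:
for two populations, F_st = (π_between − π_within)/π_between, where
π_between is the mean number of differences between sequences drawn from
different populations and π_within the average of the two within-
population means. This form can legitimately go negative when within-
population diversity exceeds between-population divergence. A
variance-components ("wc") estimator over biallelic sites is provided
as an alternative.

Haplotypes whose member strains have several known origins are assigned
to every such population ("multiple assignment"), so population sizes
may sum to more than the number of haplotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PopulationMap", "FstMatrix", "pairwise_fst"]


@dataclass
class PopulationMap:
    """Assignment of haplotype ids (or sequence labels) to populations."""

    assignment: dict[object, set[str]]
    populations: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for hap, pops in self.assignment.items():
            if not pops:
                raise ValueError(f"haplotype {hap!r} assigned to no population")
        if self.populations is None:
            seen: list[str] = []
            for pops in self.assignment.values():
                for p in sorted(pops):
                    if p not in seen:
                        seen.append(p)
            self.populations = seen

    def members(self, pop: str) -> list[object]:
        return [h for h, pops in self.assignment.items() if pop in pops]

    @property
    def sizes(self) -> dict[str, int]:
        return {p: len(self.members(p)) for p in self.populations}


@dataclass
class FstMatrix:
    labels: list[str]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _seq_matrix(sequences: dict[object, str]) -> tuple[list[object], np.ndarray]:
    labels = list(sequences)
    arrs = [np.frombuffer(sequences[l].encode(), dtype="S1") for l in labels]
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise ValueError("sequences must have equal length")
    return labels, np.vstack(arrs)


def _fst_hudson(m: np.ndarray, idx_a: list[int], idx_b: list[int]) -> float:
    def mean_diff(ix, iy, exclude_same=False):
        tot, cnt = 0, 0
        for i in ix:
            for j in iy:
                if exclude_same and j <= i:
                    continue
                tot += int((m[i] != m[j]).sum())
                cnt += 1
        return tot / cnt if cnt else 0.0

    pi_b = mean_diff(idx_a, idx_b)
    if pi_b == 0:
        return 0.0
    pi_w = 0.5 * (
        mean_diff(idx_a, idx_a, exclude_same=True)
        + mean_diff(idx_b, idx_b, exclude_same=True)
    )
    return (pi_b - pi_w) / pi_b


def _fst_wc(m: np.ndarray, idx_a: list[int], idx_b: list[int]) -> float:
    # haploid variance-components estimator, summed over biallelic sites
    num = den = 0.0
    sub = m[idx_a + idx_b]
    na, nb = len(idx_a), len(idx_b)
    for j in range(m.shape[1]):
        col = sub[:, j]
        alleles = np.unique(col)
        if alleles.size != 2:
            continue
        x = (col == alleles[1]).astype(float)
        p1, p2 = x[:na].mean(), x[na:].mean()
        n_tot = na + nb
        pbar = (na * p1 + nb * p2) / n_tot
        msp = (na * (p1 - pbar) ** 2 + nb * (p2 - pbar) ** 2) / 1.0
        msg = (na * p1 * (1 - p1) + nb * p2 * (1 - p2)) / (n_tot - 2)
        nc = n_tot - (na**2 + nb**2) / n_tot
        num += msp - msg
        den += msp + (nc - 1) * msg
    return num / den if den else 0.0


def pairwise_fst(
    sequences: dict[object, str],
    pops: PopulationMap,
    method: str = "hudson",
) -> FstMatrix:
    """Pairwise F_st matrix over populations.

    ``sequences`` maps haplotype id -> filtered concatenated sequence.
    Populations with fewer than 2 assigned haplotypes are excluded with
    a warning. Negative estimates are retained.
    """
    if method not in ("hudson", "wc"):
        raise ValueError(f"unknown method {method!r}")
    labels, m = _seq_matrix(sequences)
    index = {l: i for i, l in enumerate(labels)}
    kept: list[str] = []
    members: dict[str, list[int]] = {}
    for p in pops.populations:
        ms = [index[h] for h in pops.members(p) if h in index]
        if len(ms) < 2:
            warnings.warn(f"population {p!r} has <2 sequences; excluded")
            continue
        kept.append(p)
        members[p] = ms
    if len(kept) < 2:
        raise ValueError("need at least 2 populations with >=2 sequences")
    k = len(kept)
    out = np.zeros((k, k))
    fn = _fst_hudson if method == "hudson" else _fst_wc
    for i in range(k):
        for j in range(i + 1, k):
            v = fn(m, members[kept[i]], members[kept[j]])
            out[i, j] = out[j, i] = v
    return FstMatrix(labels=kept, values=out)
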
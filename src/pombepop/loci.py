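"""Per-locus alignment handling and compound-haplotype collapse.

Haploid strains are sequenced at a handful of non-coding loci; each locus
arrives as an aligned FASTA. Columns carrying indels (or, optionally,
masked repeat tracts such as micro/minisatellites) are removed, the loci
are concatenated, and strains are collapsed into *compound haplotypes*:
identity classes of strains whose filtered, concatenated sequences are
exactly equal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

GAP_CHARS = frozenset("-N")

__all__ = [
    "LocusDef",
    "LocusAlignment",
    "SiteFilter",
    "HaplotypeTable",
    "SEVEN_LOCI",
    "read_locus_fasta",
    "apply_site_filter",
    "collapse_haplotypes",
    "total_locus_span",
]


class FormatError(ValueError):
    """Malformed sequence input (ragged alignment, duplicate IDs, empty file)."""


@dataclass(frozen=True)
class LocusDef:
    """A sequenced genomic interval. Coordinates are end-exclusive."""

    name: str
    chromosome: str
    start: int
    end: int
    role: str = "gene"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus {self.name}: end must exceed start")

    @property
    def span(self) -> int:
        return self.end - self.start


#: The seven sequenced intervals of the S. pombe isolate collection.
#: Under the end-exclusive convention their spans sum to 5,777 bp.
SEVEN_LOCI: tuple[LocusDef, ...] = (
    LocusDef("CEN2_core", "II", 1_621_085, 1_621_800, "centromere-core"),
    LocusDef("TER1", "I", 3_084_446, 3_086_143, "gene"),
    LocusDef("SPBC660.16_intron", "II", 230_740, 231_501, "intron"),
    LocusDef("CEN2_flank_L", "II", 1_572_330, 1_572_988, "flank"),
    LocusDef("CEN2_flank_R", "II", 1_658_033, 1_658_751, "flank"),
    LocusDef("TER1_distal_1", "I", 3_113_975, 3_114_540, "flank"),
    LocusDef("TER1_distal_2", "I", 3_194_538, 3_195_201, "flank"),
)


@dataclass
class LocusAlignment:
    """Strain-by-site character matrix for one locus.

    ``matrix`` is a 2-D array of single characters over {A,C,G,T,-,N};
    ``positions`` gives the genome coordinate of every column so that
    coordinates survive column filtering.
    """

    locus: LocusDef
    strains: list[str]
    matrix: np.ndarray
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    demes: list[int] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2:
            raise FormatError("alignment matrix must be 2-D")
        if len(self.strains) != self.matrix.shape[0]:
            raise FormatError("strain labels do not match matrix rows")
        if len(set(self.strains)) != len(self.strains):
            raise FormatError("duplicate strain IDs in alignment")
        if self.positions is None:
            self.positions = self.locus.start + np.arange(self.matrix.shape[1])
        self.positions = np.asarray(self.positions)
        if self.positions.shape[0] != self.matrix.shape[1]:
            raise FormatError("positions do not match alignment width")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, strain: str) -> str:
        return "".join(self.matrix[self.strains.index(strain)])


@dataclass(frozen=True)
class SiteFilter:
    """Column-removal rules applied before any downstream statistic.

    ``masked_ranges`` are half-open column intervals (0-based, relative to
    the alignment) covering repeat tracts to strip, e.g. the minisatellite
    inside the SPBC660.16 intron.
    """

    drop_indel_columns: bool = True
    masked_ranges: tuple[tuple[int, int], ...] = ()
    drop_missing_columns: bool = True


@dataclass
class HaplotypeTable:
    """Partition of strains into compound-haplotype groups."""

    groups: list[tuple[int, list[str]]]
    strain_to_group: dict[str, int]
    per_locus_haplotypes: dict[str, dict[str, int]]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def representatives(self) -> list[str]:
        """First member of each group, in group-id order."""
        return [members[0] for _, members in self.groups]

    def to_frame(self):
        import pandas as pd

        loci = list(self.per_locus_haplotypes)
        rows = []
        for hap_id, members in self.groups:
            for s in members:
                row = {"strain": s, "haplotype_id": hap_id}
                for loc in loci:
                    row[f"hap_{loc}"] = self.per_locus_haplotypes[loc][s]
                rows.append(row)
        return pd.DataFrame(rows)


def read_locus_fasta(path, locus: LocusDef) -> LocusAlignment:
    """Read an aligned FASTA into a LocusAlignment.

    Preserves record order, uppercases bases. Raises FormatError on
    ragged record lengths, duplicate IDs or an empty file.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    # strain names may contain spaces; use the whole header line
    strains = [r.description.strip() for r in records]
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise FormatError(f"{path}: ragged record lengths {sorted(lengths)}")
    matrix = np.array([list(s) for s in seqs], dtype="U1")
    return LocusAlignment(locus=locus, strains=strains, matrix=matrix)


def apply_site_filter(aln: LocusAlignment, f: SiteFilter) -> LocusAlignment:
    """Remove columns per the filter; returns a new alignment."""
    width = aln.width
    keep = np.ones(width, dtype=bool)
    for lo, hi in f.masked_ranges:
        if not (0 <= lo <= hi <= width):
            raise ValueError(f"masked range ({lo},{hi}) outside width {width}")
        keep[lo:hi] = False
    if f.drop_indel_columns:
        keep &= ~(aln.matrix == "-").any(axis=0)
    if f.drop_missing_columns:
        keep &= ~(aln.matrix == "N").any(axis=0)
    if not keep.any():
        warnings.warn(f"locus {aln.locus.name}: filter removed every column")
    return LocusAlignment(
        locus=aln.locus,
        strains=list(aln.strains),
        matrix=aln.matrix[:, keep],
        positions=aln.positions[keep],
        demes=aln.demes,
    )


def _identity_partition(labels: Sequence[str], seqs: Sequence[str]) -> dict[str, int]:
    """Map label -> 1-based group id, ids in first-occurrence order."""
    seen: dict[str, int] = {}
    out: dict[str, int] = {}
    for lab, s in zip(labels, seqs):
        if s not in seen:
            seen[s] = len(seen) + 1
        out[lab] = seen[s]
    return out


def collapse_haplotypes(alns: Iterable[LocusAlignment]) -> HaplotypeTable:
    """Collapse strains into compound haplotypes across loci.

    Strains share a group iff their concatenated (already filtered)
    sequences are identical. Group ids are 1-based in first-occurrence
    order of the input strain list. Per-locus haplotype ids are emitted
    the same way for each locus separately.
    """
    alns = list(alns)
    if not alns:
        raise ValueError("no alignments given")
    strains = alns[0].strains
    sset = set(strains)
    for a in alns[1:]:
        if set(a.strains) != sset:
            raise ValueError(
                f"strain sets differ across loci (locus {a.locus.name})"
            )
    concat = {s: "" for s in strains}
    per_locus: dict[str, dict[str, int]] = {}
    for a in alns:
        rows = {s: "".join(a.matrix[a.strains.index(s)]) for s in strains}
        for s in strains:
            concat[s] += rows[s]
        per_locus[a.locus.name] = _identity_partition(
            strains, [rows[s] for s in strains]
        )
    assignment = _identity_partition(strains, [concat[s] for s in strains])
    groups: dict[int, list[str]] = {}
    for s in strains:
        groups.setdefault(assignment[s], []).append(s)
    return HaplotypeTable(
        groups=[(gid, groups[gid]) for gid in sorted(groups)],
        strain_to_group=assignment,
        per_locus_haplotypes=per_locus,
    )


def total_locus_span(loci: Iterable[LocusDef]) -> int:
    """Total sequenced base pairs, Σ(end − start)."""
    return sum(l.span for l in loci)
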
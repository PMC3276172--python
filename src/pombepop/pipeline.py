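"""End-to-end pipeline orchestration.

A single YAML config drives two entry points: ``run_popgen`` (alignments
→ haplotype table → diversity / F_st / LD reports) and ``run_phenomics``
(growth curves → fitness components → LSC → trait-profile reports).
Every report directory gets a ``run_info.json`` embedding the config
hash and seed so identical runs are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity as div
from . import growth as gw
from . import linkage as ld
from . import structure as st
from . import traits as tr
from .loci import (
    SEVEN_LOCI,
    LocusDef,
    SiteFilter,
    apply_site_filter,
    collapse_haplotypes,
    read_locus_fasta,
)

__all__ = ["PipelineConfig", "run_popgen", "run_phenomics"]


class StageError(RuntimeError):
    """Pipeline failure, tagged with the stage that raised it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    locus_fastas: dict[str, str] = field(default_factory=dict)
    loci: dict[str, dict] = field(default_factory=dict)
    metadata: str | None = None
    curves: str | None = None
    reference: str | None = None
    masked_ranges: dict[str, list[list[int]]] = field(default_factory=dict)
    mu: float = 0.33e-9
    fdr: float = 0.05
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def locus_def(self, name: str) -> LocusDef:
        if name in self.loci:
            d = self.loci[name]
            return LocusDef(name, d.get("chromosome", "?"), d["start"],
                            d["end"], d.get("role", "gene"))
        for locus in SEVEN_LOCI:
            if locus.name == name:
                return locus
        raise StageError("config", f"no locus definition for {name!r}")


def _write_run_info(cfg: PipelineConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_info.json", "w") as fh:
        json.dump({"config_sha256": cfg.digest(), "seed": cfg.seed}, fh,
                  indent=2)


def _load_filtered_alignments(cfg: PipelineConfig):
    alns = []
    for name, path in cfg.locus_fastas.items():
        if not Path(path).exists():
            raise StageError("locus_io", f"missing FASTA for locus {name}: {path}")
        aln = read_locus_fasta(path, cfg.locus_def(name))
        masked = tuple(tuple(r) for r in cfg.masked_ranges.get(name, []))
        alns.append(apply_site_filter(aln, SiteFilter(masked_ranges=masked)))
    if not alns:
        raise StageError("locus_io", "no locus FASTAs configured")
    return alns


def run_popgen(cfg: PipelineConfig) -> dict[str, Path]:
    """Alignments → haplotypes, diversity, F_st and LD reports (TSV)."""
    out = Path(cfg.out_dir)
    _write_run_info(cfg, out)
    written: dict[str, Path] = {}

    alns = _load_filtered_alignments(cfg)
    try:
        table = collapse_haplotypes(alns)
    except ValueError as e:
        raise StageError("haplotypes", str(e)) from e
    hap_path = out / "haplotypes.tsv"
    table.to_frame().to_csv(hap_path, sep="\t", index=False)
    written["haplotypes"] = hap_path

    try:
        dtab = div.diversity_table(alns)
    except ValueError as e:
        raise StageError("diversity", str(e)) from e
    div_path = out / "diversity.tsv"
    dtab.to_csv(div_path, sep="\t", index=False)
    written["diversity"] = div_path

    if cfg.metadata:
        meta = pd.read_csv(cfg.metadata, sep="\t")
        if {"strain", "origin"}.issubset(meta.columns):
            concat = {}
            for gid, members in table.groups:
                rep = members[0]
                concat[gid] = "".join(
                    "".join(a.matrix[a.strains.index(rep)]) for a in alns
                )
            origin_of = dict(zip(meta["strain"], meta["origin"].fillna("")))
            assignment: dict[object, set[str]] = {}
            for gid, members in table.groups:
                pops = {origin_of.get(s, "") or "Unknown" for s in members}
                assignment[gid] = pops
            try:
                fst = st.pairwise_fst(concat, st.PopulationMap(assignment))
                fst_path = out / "fst.tsv"
                fst.to_frame().to_csv(fst_path, sep="\t")
                written["fst"] = fst_path
            except ValueError as e:
                raise StageError("fst", str(e)) from e

    # LD on the concatenated filtered alignment of each chromosome region
    try:
        markers: list[ld.SNPMarker] = []
        for a in alns:
            markers.extend(ld.informative_snps(a))
        if len(markers) >= 2:
            res = ld.ld_statistics(markers)
            ld_path = out / "ld.tsv"
            pos = res.positions
            frame = pd.DataFrame(res.chi2, index=pos, columns=pos)
            frame.to_csv(ld_path, sep="\t")
            written["ld"] = ld_path
            fg, rm = ld.four_gamete_test(markers)
            fg_path = out / "four_gamete.tsv"
            pd.DataFrame(fg, index=pos, columns=pos).to_csv(fg_path, sep="\t")
            written["four_gamete"] = fg_path
            with open(out / "rm.json", "w") as fh:
                json.dump({"Rm": rm}, fh)
            written["rm"] = out / "rm.json"
    except ValueError as e:
        raise StageError("ld", str(e)) from e
    return written


def read_curve_table(path) -> list[gw.GrowthCurve]:
    """Parse a TSV of curves (strain, environment, run, time_min, od);
    malformed rows are dropped with a count logged to the return."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "environment", "run", "time_min", "od"}
    if not required.issubset(df.columns):
        raise StageError("growth", f"curve table needs columns {sorted(required)}")
    n_bad = int(df[["time_min", "od"]].isna().any(axis=1).sum())
    df = df.dropna(subset=["time_min", "od"])
    curves = []
    for (strain, env, run), sub in df.groupby(["strain", "environment", "run"]):
        sub = sub.sort_values("time_min")
        curves.append(
            gw.GrowthCurve(
                strain=str(strain), environment=str(env), run=int(run),
                time_min=sub["time_min"].to_numpy(),
                od=sub["od"].to_numpy(),
            )
        )
    if n_bad:
        import warnings

        warnings.warn(f"dropped {n_bad} malformed curve rows")
    return curves


def run_phenomics(cfg: PipelineConfig) -> dict[str, Path]:
    """Growth curves → components, LSC, clustering and similarity reports."""
    out = Path(cfg.out_dir)
    _write_run_info(cfg, out)
    written: dict[str, Path] = {}
    if not cfg.curves:
        raise StageError("growth", "no curve table configured")
    curves = read_curve_table(cfg.curves)

    comp_rows = []
    for c in curves:
        try:
            fc = gw.extract_fitness(c)
        except ValueError as e:
            raise StageError("growth", f"{c.strain}/{c.environment}: {e}") from e
        for comp, val in (
            ("lag", fc.lag_h), ("doubling", fc.doubling_h),
            ("efficiency", fc.efficiency),
        ):
            comp_rows.append(
                {"strain": fc.strain, "environment": fc.environment,
                 "run": fc.run, "component": comp, "value": val,
                 "is_grower": fc.is_grower}
            )
    comp_df = pd.DataFrame(comp_rows)
    comp_path = out / "components.tsv"
    comp_df.to_csv(comp_path, sep="\t", index=False)
    written["components"] = comp_path

    growers = comp_df[comp_df["is_grower"]].drop(columns="is_grower")
    if cfg.reference:
        try:
            lsc = gw.lsc_table(growers, reference=cfg.reference)
        except ValueError as e:
            raise StageError("lsc", str(e)) from e
        lsc_path = out / "lsc.tsv"
        lsc.to_csv(lsc_path, sep="\t", index=False)
        written["lsc"] = lsc_path

        try:
            tm = tr.build_trait_matrix(growers, reference=cfg.reference)
        except ValueError as e:
            raise StageError("traits", str(e)) from e
        tm_path = out / "trait_matrix.tsv"
        tm.values.to_csv(tm_path, sep="\t")
        written["trait_matrix"] = tm_path
        if len(tm.strains) >= 3:
            tree = tr.cluster_profiles(tm)
            nwk_path = out / "dendrogram.nwk"
            nwk_path.write_text(tree.to_newick() + "\n")
            written["dendrogram"] = nwk_path
            atyp = tr.atypicality_ranking(tm)
            atyp_path = out / "atypicality.tsv"
            atyp.to_csv(atyp_path, sep="\t", index=False)
            written["atypicality"] = atyp_path
    return written
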
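"""End-to-end orchestration: screen arm (counts → tests → hits) and proteome
arm (ratios → regulation → enrichment), with a JSON run manifest.

Every intermediate is a plain TSV so any stage can be re-run independently;
rerunning with the same config and seeds reproduces outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrich import hypergeometric_enrichment, read_term_map
from .hits import (
    FilterParams,
    HairpinHitSet,
    call_gene_hits,
    integrate_evidence,
    intersect_screens,
    select_depleted_hairpins,
)
from .proteomics import (
    apply_regulation_filters,
    differential_analysis,
    filter_phosphosites,
    load_phosphosite_table,
    load_ratio_table,
    phosphosite_ratio_table,
    regulated_directions,
    write_ratio_table,
)
from .quant import CountMatrix, HairpinLibrary, SampleSheet, read_counts, write_counts
from .screenstats import (
    estimate_size_factors,
    screen_differential,
    treated_vs_dmso,
)
from .simulate import (
    PlantedEssential,
    PlantedSensitizer,
    ProteomeSimConfig,
    ScreenSimConfig,
    simulate_proteome,
    simulate_screen,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class Manifest:
    """Records versions, seeds, parameters and checksums of all files touched.

    Output paths are stored relative to the run directory so that identical
    runs in different locations produce byte-identical manifests.
    """

    def __init__(self, config: dict, outdir: str | Path | None = None):
        import numpy, scipy

        self.outdir = Path(outdir) if outdir is not None else None
        self.data: dict = {
            "versions": {
                "sensikit": __version__,
                "numpy": numpy.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
            },
            "config": config,
            "inputs": {},
            "outputs": {},
        }

    def add_input(self, path: str | Path) -> None:
        self.data["inputs"][Path(path).name] = _sha256(Path(path))

    def add_output(self, path: str | Path) -> None:
        path = Path(path)
        key = str(path.relative_to(self.outdir)) if self.outdir else path.name
        self.data["outputs"][key] = _sha256(path)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)
            fh.write("\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config", f"{path} did not parse to a mapping")
    return cfg


def screen_sim_config_from_dict(d: dict) -> ScreenSimConfig:
    d = dict(d)
    d["planted_sensitizers"] = tuple(
        PlantedSensitizer(**s) for s in d.get("planted_sensitizers", [])
    )
    d["planted_essentials"] = tuple(
        PlantedEssential(**e) for e in d.get("planted_essentials", [])
    )
    for key in ("arms", "days", "size_factor_range"):
        if key in d:
            d[key] = tuple(d[key])
    return ScreenSimConfig(**d)


def filter_params_from_dict(d: dict | None) -> FilterParams:
    return FilterParams(**(d or {}))


def run_screen_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Counts → per-arm day-7/day-4 tests → filter cascade → gene hits.

    ``cfg`` keys: either ``sim`` (a ScreenSimConfig mapping) or ``counts`` +
    ``library`` + ``samples`` paths; optional ``filter`` (FilterParams),
    ``sharing``, ``arms``. Returns a dict of result tables; writes TSVs and
    ``manifest.json`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest({"screen": cfg}, outdir)
    try:
        if "sim" in cfg:
            sim_cfg = screen_sim_config_from_dict(cfg["sim"])
            lib, sheet, cm, truth = simulate_screen(sim_cfg)
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            lib.to_tsv(outdir / "library.tsv")
            sheet.to_tsv(outdir / "samples.tsv")
            write_counts(cm, outdir / "counts.tsv")
            for name in ("truth.tsv", "library.tsv", "samples.tsv", "counts.tsv"):
                manifest.add_output(outdir / name)
            arms = list(sim_cfg.arms)
        else:
            lib = HairpinLibrary.from_tsv(cfg["library"])
            sheet = SampleSheet.from_tsv(cfg["samples"])
            cm = read_counts(cfg["counts"], sheet, library=lib)
            for key in ("library", "samples", "counts"):
                manifest.add_input(cfg[key])
            arms = cfg.get("arms") or sorted(
                set(sheet.df.loc[sheet.df["condition"] == "treated", "treatment"])
            )
    except (KeyError, ValueError) as exc:
        raise PipelineError("screen_quant", str(exc)) from exc

    params = filter_params_from_dict(cfg.get("filter"))
    sharing = cfg.get("sharing", "max")
    try:
        sf = estimate_size_factors(cm)
        hitsets: dict[str, HairpinHitSet] = {}
        for arm in arms:
            day7 = screen_differential(
                cm, treated_vs_dmso(arm, 7), library=lib, size_factors=sf, sharing=sharing
            )
            day4 = screen_differential(
                cm, treated_vs_dmso(arm, 4), library=lib, size_factors=sf, sharing=sharing
            )
            day7.to_csv(outdir / f"{arm}_day7_results.tsv", sep="\t", index=False)
            day4.to_csv(outdir / f"{arm}_day4_results.tsv", sep="\t", index=False)
            manifest.add_output(outdir / f"{arm}_day7_results.tsv")
            manifest.add_output(outdir / f"{arm}_day4_results.tsv")
            hitsets[arm] = select_depleted_hairpins(day7, day4, params, screen=arm)
    except ValueError as exc:
        raise PipelineError("screen_stats", str(exc)) from exc

    try:
        if len(arms) != 2:
            raise ValueError(f"gene-hit calling needs exactly 2 arms, got {arms}")
        a, b = arms
        shared = intersect_screens(hitsets[a], hitsets[b])
        gene_hits = call_gene_hits(hitsets[a], hitsets[b], lib, params)
    except ValueError as exc:
        raise PipelineError("hit_calling", str(exc)) from exc

    for arm in arms:
        hitsets[arm].table.to_csv(outdir / f"{arm}_selected_hairpins.tsv", sep="\t", index=False)
        manifest.add_output(outdir / f"{arm}_selected_hairpins.tsv")
    pd.DataFrame({"hairpin_id": shared}).to_csv(
        outdir / "shared_hairpins.tsv", sep="\t", index=False
    )
    gene_hits.to_csv(outdir / "gene_hits.tsv", sep="\t", index=False)
    manifest.add_output(outdir / "shared_hairpins.tsv")
    manifest.add_output(outdir / "gene_hits.tsv")
    manifest.write(outdir / "manifest.json")
    return {
        "hitsets": hitsets,
        "shared_hairpins": shared,
        "gene_hits": gene_hits,
        "size_factors": sf,
    }


def run_proteome_pipeline(cfg: dict, outdir: str | Path) -> dict:
    """Ratio tables → t-tests → regulation filters (→ enrichment).

    ``cfg`` keys: either ``sim`` (ProteomeSimConfig mapping) or ``table`` (+
    optional ``phospho``) paths; optional ``min_replicates``, ``fc_min``,
    ``p_max``, ``min_loc_prob``, ``terms``/``term_labels`` for enrichment.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest({"proteome": cfg}, outdir)
    try:
        if "sim" in cfg:
            d = dict(cfg["sim"])
            if "effect_log2fc_range" in d:
                d["effect_log2fc_range"] = tuple(d["effect_log2fc_range"])
            sim_cfg = ProteomeSimConfig(**d)
            prot_df, phospho_df, truth = simulate_proteome(sim_cfg)
            prot_df.to_csv(outdir / "proteins.tsv", sep="\t", index=False)
            phospho_df.to_csv(outdir / "phosphosites.tsv", sep="\t", index=False)
            truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
            from .proteomics import ProteinRatioTable

            table = ProteinRatioTable(prot_df, n_replicates=sim_cfg.n_replicates)
            sites = phospho_df
        else:
            table = load_ratio_table(cfg["table"])
            manifest.add_input(cfg["table"])
            sites = None
            if cfg.get("phospho"):
                sites = load_phosphosite_table(cfg["phospho"])
                manifest.add_input(cfg["phospho"])
    except (KeyError, ValueError) as exc:
        raise PipelineError("proteomics_load", str(exc)) from exc

    min_rep = int(cfg.get("min_replicates", 3))
    fc_min = float(cfg.get("fc_min", 1.5))
    p_max = float(cfg.get("p_max", 0.05))
    try:
        results = differential_analysis(table, min_replicates=min_rep)
        summary = apply_regulation_filters(results, fc_min=fc_min, p_max=p_max)
        summary.results.to_csv(outdir / "protein_regulation.tsv", sep="\t", index=False)
        manifest.add_output(outdir / "protein_regulation.tsv")
        phospho_summary = None
        if sites is not None:
            kept, retention = filter_phosphosites(
                sites, min_prob=float(cfg.get("min_loc_prob", 0.75))
            )
            logger.info("phosphosite localization filter retained %.1f%%", 100 * retention)
            site_table = phosphosite_ratio_table(kept, n_replicates=table.n_replicates)
            site_results = differential_analysis(site_table, min_replicates=min_rep)
            phospho_summary = apply_regulation_filters(site_results, fc_min=fc_min, p_max=p_max)
            phospho_summary.results.to_csv(
                outdir / "phosphosite_regulation.tsv", sep="\t", index=False
            )
            manifest.add_output(outdir / "phosphosite_regulation.tsv")
    except ValueError as exc:
        raise PipelineError("proteomics_diff", str(exc)) from exc

    enrichment = None
    if cfg.get("terms"):
        try:
            terms, labels = read_term_map(cfg["terms"], cfg.get("term_labels"))
            manifest.add_input(cfg["terms"])
            background = set(table.df["gene"].astype(str))
            target = {
                str(g)
                for g in table.df.loc[
                    table.df["protein_id"].isin(summary.union), "gene"
                ]
            }
            if target:
                enrichment = hypergeometric_enrichment(target, background, terms, labels)
                enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
                manifest.add_output(outdir / "enrichment.tsv")
        except ValueError as exc:
            raise PipelineError("enrichment", str(exc)) from exc

    manifest.write(outdir / "manifest.json")
    return {
        "summary": summary,
        "phospho_summary": phospho_summary,
        "enrichment": enrichment,
        "directions": regulated_directions(summary),
    }


def run_all(config_path: str | Path, outdir: str | Path | None = None) -> dict:
    """Full integrated run: screen arm, proteome arm, evidence integration."""
    cfg = load_config(config_path)
    outdir = Path(outdir or cfg.get("outdir", "results"))
    out: dict = {}
    if "screen" in cfg:
        out["screen"] = run_screen_pipeline(cfg["screen"], outdir / "screen")
    if "proteome" in cfg:
        out["proteome"] = run_proteome_pipeline(cfg["proteome"], outdir / "proteome")
    if "screen" in out and "proteome" in out and cfg.get("integration", {}).get("regulator_map"):
        map_df = pd.read_csv(cfg["integration"]["regulator_map"], sep="\t")
        ranked = integrate_evidence(
            out["screen"]["gene_hits"], out["proteome"]["directions"], map_df
        )
        ranked.to_csv(outdir / "ranked_candidates.tsv", sep="\t", index=False)
        out["ranked_candidates"] = ranked
    return out
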
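"""End-to-end orchestration: simulate/load → segregate → filter → discover →
associate, with one consolidated report.

A run is configured by a YAML (or dict) with these blocks::

    seed: 1
    out_dir: run_out            # optional; artifacts written when present
    simulate: {...}             # SimulationConfig overrides, OR
    inputs:
      vcfs: {FAM1: fam1.vcf, ...}
      ped: cohort.ped
    filters: {...}              # FilterConfig overrides
    segregation: {model: dominant, allow_hom_alt: false}
    discovery:
      min_families: 2
      margin_bp: 1000000
      loci: loci.tsv            # optional
      loci_units: Mb
    assoc:                      # optional block
      counts: counts.csv        # or "simulate"
      models: [allelic, dominant, recessive]

The family analysis and the case-control analysis share a report but no
state: one run is one cohort of discovery families plus an optional
validation block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__ as _version
from .assoc import MODELS, association
from .discovery import (
    gene_calls_from_cascade,
    locus_proximity,
    overlapping_genes,
)
from .exceptions import ConfigError, PipelineStageError
from .filters import CascadeResult, FilterConfig, run_cascade
from .io import read_annotated_vcf, read_counts_csv, read_loci, read_pedigree
from .simulate import SimulationConfig, simulate_case_control_counts, simulate_family_cohort
from .variants import GenotypeMatrix

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """Everything a run produced, recomputable from the echoed config."""

    config: dict
    seed: int
    version: str
    trace: pd.DataFrame  # long format: family, stage, stage_index, survivors
    candidates: pd.DataFrame  # gene, families, n_families, tier, locus columns
    assoc: pd.DataFrame | None
    truth: pd.DataFrame | None = None

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "trace": out_dir / "trace.csv",
            "candidates": out_dir / "candidates.csv",
            "report": out_dir / "report.json",
        }
        self.trace.to_csv(paths["trace"], index=False)
        self.candidates.to_csv(paths["candidates"], index=False)
        if self.assoc is not None:
            paths["assoc"] = out_dir / "assoc.csv"
            self.assoc.to_csv(paths["assoc"], index=False)
        if self.truth is not None and not self.truth.empty:
            paths["truth"] = out_dir / "truth.csv"
            self.truth.to_csv(paths["truth"], index=False)
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "trace": self.trace.to_dict(orient="records"),
            "candidates": self.candidates.to_dict(orient="records"),
            "assoc": None if self.assoc is None else self.assoc.to_dict(orient="records"),
        }
        with open(paths["report"], "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
        return paths


def _load_config(config: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(config, (str, Path)):
        path = Path(config)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return loaded
    return dict(config)


def _validate_inputs(cfg: dict) -> None:
    """Fail before any stage runs if referenced inputs are absent."""
    if "simulate" in cfg and "inputs" in cfg:
        raise ConfigError("config may have either 'simulate' or 'inputs', not both")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs a 'simulate' or an 'inputs' block")
    if "inputs" in cfg:
        inputs = cfg["inputs"]
        vcfs = inputs.get("vcfs")
        if not vcfs:
            raise ConfigError("inputs.vcfs must map family ids to VCF paths")
        for family, path in vcfs.items():
            if not Path(path).exists():
                raise ConfigError(f"inputs.vcfs[{family!r}]: {path} does not exist")
        ped = inputs.get("ped")
        if not ped or not Path(ped).exists():
            raise ConfigError(f"inputs.ped: {ped!r} does not exist")
    disc = cfg.get("discovery", {})
    if disc.get("loci") and not Path(disc["loci"]).exists():
        raise ConfigError(f"discovery.loci: {disc['loci']} does not exist")
    assoc_cfg = cfg.get("assoc")
    if assoc_cfg:
        counts = assoc_cfg.get("counts")
        if counts is None:
            raise ConfigError("assoc.counts must be a CSV path or 'simulate'")
        if counts != "simulate" and not Path(counts).exists():
            raise ConfigError(f"assoc.counts: {counts} does not exist")


def _candidate_table(variants, cascade: CascadeResult, cfg: dict) -> pd.DataFrame:
    disc = cfg.get("discovery", {})
    min_families = int(disc.get("min_families", 2))
    margin_bp = int(disc.get("margin_bp", 1_000_000))
    calls = gene_calls_from_cascade(variants, cascade)
    candidates = overlapping_genes(calls, min_families=min_families)
    loci = None
    if disc.get("loci"):
        loci = read_loci(disc["loci"], units=disc.get("loci_units", "bp"))
    annotations = (
        locus_proximity(candidates, loci, margin_bp=margin_bp) if loci else {}
    )
    rows = []
    for gene in sorted(candidates):
        cand = candidates[gene]
        ann = annotations.get(gene)
        rows.append(
            {
                "gene": gene,
                "families": ";".join(sorted(cand.families_observed)),
                "n_families": len(cand.families_observed),
                "tier": "rare" if cand.has_rare_variant else "common",
                "chrom": cand.chrom,
                "positions": ";".join(str(p) for _, p in cand.all_positions),
                "locus_status": ann.status if ann else "",
                "locus": (ann.locus or "") if ann else "",
                "locus_distance_bp": (
                    "" if ann is None or ann.distance_bp is None else ann.distance_bp
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "families", "n_families", "tier", "chrom", "positions",
            "locus_status", "locus", "locus_distance_bp",
        ],
    )


def _assoc_table(cfg: dict, seed: int) -> pd.DataFrame:
    assoc_cfg = cfg["assoc"]
    models = assoc_cfg.get("models", list(MODELS))
    if assoc_cfg["counts"] == "simulate":
        sim_overrides = dict(cfg.get("simulate") or {})
        sim_overrides.setdefault("seed", seed)
        sim = _build_sim_config(sim_overrides)
        counts = simulate_case_control_counts(sim)
    else:
        counts = read_counts_csv(assoc_cfg["counts"])
    alpha = float(assoc_cfg.get("alpha", 0.05))
    correction = assoc_cfg.get("correction", "haldane")
    fisher = bool(assoc_cfg.get("fisher", False))
    rows = []
    for cc in counts:
        for model in models:
            res = association(
                cc, model, alpha=alpha, correction=correction, fisher=fisher
            )
            a, b, c, d = res.table
            rows.append(
                {
                    "snp": res.snp,
                    "model": model,
                    "a_case_exposed": a,
                    "b_case_unexposed": b,
                    "c_control_exposed": c,
                    "d_control_unexposed": d,
                    "odds_ratio": round(res.odds_ratio, 4),
                    "ci_low": round(res.ci_low, 4),
                    "ci_high": round(res.ci_high, 4),
                    "correction_applied": res.correction_applied,
                    "fisher_p": "" if res.fisher_p is None else round(res.fisher_p, 6),
                    "n_tests": len(counts) * len(models),
                }
            )
    return pd.DataFrame(rows)


def _build_sim_config(overrides: Mapping[str, Any]) -> SimulationConfig:
    from .simulate import CaseControlSNP, PlantedCausal

    kwargs = dict(overrides)
    if isinstance(kwargs.get("planted"), Mapping):
        kwargs["planted"] = PlantedCausal(**kwargs["planted"])
    if "case_control_snps" in kwargs:
        kwargs["case_control_snps"] = tuple(
            CaseControlSNP(**s) if isinstance(s, Mapping) else s
            for s in kwargs["case_control_snps"]
        )
    try:
        return SimulationConfig(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"bad simulate block: {exc}") from exc


def run_pipeline(config: str | Path | Mapping[str, Any]) -> RunReport:
    """Execute the full pipeline described by a config; see module docstring.

    Any stage failure is re-raised as :class:`PipelineStageError` naming the
    stage; configuration problems are detected up front so no partial outputs
    are produced for an unrunnable config.
    """
    cfg = _load_config(config)
    _validate_inputs(cfg)
    seed = int(cfg.get("seed", 0))

    truth: pd.DataFrame | None = None
    try:
        if "simulate" in cfg:
            sim_overrides = dict(cfg["simulate"] or {})
            sim_overrides.setdefault("seed", seed)
            sim = _build_sim_config(sim_overrides)
            cohort = simulate_family_cohort(sim)
            variants = cohort.all_variants()
            genotypes = cohort.merged_genotypes()
            ped = cohort.pedigree
            truth = cohort.truth
        else:
            per_family = {
                fam: read_annotated_vcf(path)
                for fam, path in cfg["inputs"]["vcfs"].items()
            }
            seen: set = set()
            variants = []
            for fam_variants, _ in per_family.values():
                for v in fam_variants:
                    if v.key not in seen:
                        seen.add(v.key)
                        variants.append(v)
            genotypes = GenotypeMatrix.merge(m for _, m in per_family.values())
            ped = read_pedigree(cfg["inputs"]["ped"])
    except Exception as exc:
        raise PipelineStageError("load", exc) from exc

    try:
        filter_cfg = FilterConfig.from_dict(cfg.get("filters", {}))
        seg_cfg = cfg.get("segregation", {})
        cascade = run_cascade(
            variants,
            genotypes,
            ped,
            filter_cfg,
            model=seg_cfg.get("model", "dominant"),
            allow_hom_alt=bool(seg_cfg.get("allow_hom_alt", False)),
        )
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("prioritize", exc) from exc

    try:
        candidates = _candidate_table(variants, cascade, cfg)
    except Exception as exc:
        raise PipelineStageError("discover", exc) from exc

    assoc_df = None
    if cfg.get("assoc"):
        try:
            assoc_df = _assoc_table(cfg, seed)
        except Exception as exc:
            raise PipelineStageError("assoc", exc) from exc

    echo = dict(cfg)
    echo["filters"] = filter_cfg.to_dict()
    report = RunReport(
        config=echo,
        seed=seed,
        version=_version,
        trace=cascade.trace.to_dataframe(),
        candidates=candidates,
        assoc=assoc_df,
        truth=truth,
    )
    if cfg.get("out_dir"):
        report.write(cfg["out_dir"])
    return report
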
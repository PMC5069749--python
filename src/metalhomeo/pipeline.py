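"""Pipeline configuration, tab-separated I/O with provenance, and the
end-to-end run: spots -> gene signals -> comparisons -> patterns
(+ optional growth curves and dose-response fits).

All tables are plain TSV with a header row, preceded by ``# key=value``
provenance lines carrying the cutoffs and seed of the run, so no output
ever depends on hidden defaults. A run manifest (JSON) records versions,
seed, cutoffs and row counts in/out of every filtering stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .array_stats import (D_CUT_DEFAULT, Q_DOWN_DEFAULT, Q_UP_DEFAULT,
                          compare_table, gene_signal_table, spot_signal_table)
from .dose_response import DoseResponseModel
from .growth import GrowthCurveModel, NoExponentialPhase
from .patterns import classify_table, cluster_ratio_table, count_patterns

__all__ = ["PipelineConfig", "ComparisonSpec", "run_pipeline",
            "read_table", "write_table", "read_cluster_map"]

log = logging.getLogger("metalhomeo")


class InputError(ValueError):
    """Bad configuration or malformed input file (CLI exit code 2)."""


# ---------------------------------------------------------------------------
# TSV with provenance headers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, provenance: Mapping | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, val in (provenance or {}).items():
            fh.write(f"# {key}={val}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def read_cluster_map(path) -> dict[str, str]:
    """Two-column (gene_id, cluster_id) TSV -> mapping."""
    df = read_table(path)
    if df.shape[1] < 2:
        raise InputError("cluster map needs two columns: gene_id, cluster_id")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonSpec:
    """One Q-ratio comparison: numerator / denominator (strain, condition)."""

    comparison_id: str
    numerator: tuple[str, str]
    denominator: tuple[str, str]

    @classmethod
    def parse(cls, comparison_id: str, numerator: str,
              denominator: str) -> "ComparisonSpec":
        def split(s: str) -> tuple[str, str]:
            if ":" not in s:
                raise InputError(
                    f"comparison side {s!r} must be 'strain:condition'")
            strain, condition = s.split(":", 1)
            return strain, condition
        return cls(comparison_id, split(numerator), split(denominator))


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; serialised into every output."""

    spot_table: str | None = None
    growth_tables: Sequence[str] = ()
    dose_tables: Sequence[str] = ()
    cluster_map: str | None = None
    comparisons: Sequence[ComparisonSpec] = ()
    cluster_comparison_id: str | None = None
    q_up: float = Q_UP_DEFAULT
    q_down: float = Q_DOWN_DEFAULT
    d_cut: float = D_CUT_DEFAULT
    growth_window: int = 4
    growth_r2_min: float = 0.98
    ic50_bootstrap: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.q_up > 1:
            raise InputError("q_up must be > 1")
        if not 0 < self.q_down < 1:
            raise InputError("q_down must be in (0, 1)")
        if self.d_cut < 0:
            raise InputError("d_cut must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        comps = [ComparisonSpec.parse(c["id"], c["numerator"], c["denominator"])
                 for c in raw.pop("comparisons", [])]
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(comparisons=comps, **raw)

    def provenance(self) -> dict:
        return {"metalhomeo_version": __version__, "q_up": self.q_up,
                "q_down": self.q_down, "d_cut": self.d_cut,
                "rng_seed": self.rng_seed}


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all configured stages; write tables and a manifest.

    Returns the manifest dict. Deterministic: identical inputs and seed
    give byte-identical outputs. Stage failures raise with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = cfg.provenance()
    manifest: dict = {"config": {**prov,
                                 "growth_window": cfg.growth_window,
                                 "growth_r2_min": cfg.growth_r2_min,
                                 "ic50_bootstrap": cfg.ic50_bootstrap},
                      "stages": {}}

    comparisons_df = None
    if cfg.spot_table is not None:
        spots = read_table(cfg.spot_table)
        signals = spot_signal_table(spots)
        n_pass = int(signals["passes_filter"].sum())
        log.info("spots: %d in, %d pass D > 1", len(signals), n_pass)
        write_table(signals, outdir / "spot_signals.tsv", prov)
        manifest["stages"]["spots"] = {"n_in": len(signals),
                                       "n_pass_filter": n_pass}

        genes = gene_signal_table(signals)
        n_nf = int((genes["status"] == "NF").sum())
        log.info("genes: %d cells, %d NF", len(genes), n_nf)
        write_table(genes, outdir / "gene_signals.tsv", prov)
        manifest["stages"]["genes"] = {"n_cells": len(genes), "n_nf": n_nf}

        if cfg.comparisons:
            frames = []
            for spec in cfg.comparisons:
                frames.append(compare_table(
                    genes, spec.numerator, spec.denominator,
                    comparison_id=spec.comparison_id, q_up=cfg.q_up,
                    q_down=cfg.q_down, d_cut=cfg.d_cut))
            comparisons_df = pd.concat(frames, ignore_index=True)
            n_nq = int((comparisons_df["status"] == "NQ").sum())
            write_table(comparisons_df, outdir / "comparisons.tsv", prov)
            manifest["stages"]["compare"] = {
                "n_rows": len(comparisons_df), "n_nq": n_nq,
                "n_significant": int(comparisons_df["significant"].sum())}

            ids = [s.comparison_id for s in cfg.comparisons]
            classified = classify_table(comparisons_df, ids)
            counts = count_patterns(classified)
            write_table(classified, outdir / "gene_patterns.tsv", prov)
            write_table(counts, outdir / "pattern_counts.tsv", prov)
            manifest["stages"]["classify"] = {
                "n_genes": len(classified), "n_patterns": len(counts)}

            if cfg.cluster_map is not None:
                cid = cfg.cluster_comparison_id or ids[0]
                ratios = cluster_ratio_table(
                    comparisons_df, read_cluster_map(cfg.cluster_map), cid)
                write_table(ratios, outdir / "cluster_ratios.tsv", prov)
                manifest["stages"]["clusters"] = {"n_clusters": len(ratios)}

    if cfg.growth_tables:
        rows = []
        for path in cfg.growth_tables:
            name = Path(path).stem
            model = GrowthCurveModel.from_dataframe(read_table(path))
            try:
                res = model.fit(window=cfg.growth_window,
                                r2_min=cfg.growth_r2_min)
                rows.append({"curve": name, "status": "OK", **res.as_dict()})
            except NoExponentialPhase as exc:
                rows.append({"curve": name, "status": "no_exponential_phase"})
                log.warning("growth %s: %s", name, exc)
        growth_df = pd.DataFrame(rows)
        write_table(growth_df, outdir / "growth_params.tsv", prov)
        manifest["stages"]["growth"] = {
            "n_curves": len(rows),
            "n_fitted": int((growth_df["status"] == "OK").sum())}

    if cfg.dose_tables:
        rows = []
        for i, path in enumerate(cfg.dose_tables):
            name = Path(path).stem
            fit = DoseResponseModel(read_table(path)).fit(
                n_boot=cfg.ic50_bootstrap, seed=cfg.rng_seed + i)
            rows.append({"series": name, "converged": fit.converged,
                         "ic50_uM": fit.ic50, "ic50_err_uM": fit.ic50_err,
                         "slope": fit.slope, "od0_hat": fit.od0_hat})
        dose_df = pd.DataFrame(rows)
        write_table(dose_df, outdir / "ic50.tsv", prov)
        manifest["stages"]["ic50"] = {
            "n_series": len(rows),
            "n_converged": int(dose_df["converged"].sum())}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
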
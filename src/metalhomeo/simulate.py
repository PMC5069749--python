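"""Synthetic-data generators with planted ground truth.

Three generators emulate the raw inputs of the analysis pipeline:

* :func:`simulate_spot_table` — single-channel microarray spot summaries
  (per-spot pixel mean/deviation and local-background pixel mean/deviation)
  for a strains × conditions × replicates design with fold changes planted
  on chosen genes;
* :func:`simulate_growth_curve` — OD600 turbidity time series following a
  lag → exponential → hard-cap growth model;
* :func:`simulate_dose_response` — endpoint turbidity declining as a
  logistic function of inhibitor concentration, half-maximal at the true
  IC50.

Every generator takes an explicit seed from its config; there is no hidden
global randomness, and identical configs yield identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArraySimConfig",
    "GrowthSimConfig",
    "DoseSimConfig",
    "SimulatedArray",
    "simulate_spot_table",
    "simulate_growth_curve",
    "simulate_dose_response",
]


class ConfigError(ValueError):
    """Raised when a simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# microarray spots
# ---------------------------------------------------------------------------

#: degrees of freedom of the chi-scaled factor applied to reported pixel
#: deviations; plays the role of the (unmodelled) per-spot pixel count.
PIXEL_DEV_DF = 30


@dataclass
class ArraySimConfig:
    """Design and noise model of a simulated spot-level array experiment.

    ``planted_effects`` maps gene id -> {(strain, condition): fold change};
    an absent entry means expression at ``baseline_signal``. ``pixel_cv`` is
    the coefficient of variation of the reported pixel-summary means.
    """

    n_genes: int
    probes_per_gene: int = 2
    n_replicates: int = 3          # triplicate biological replicates
    strains: Sequence[str] = ("wt",)
    conditions: Sequence[str] = ("ctrl",)
    baseline_signal: float = 1000.0
    background_level: float = 200.0
    pixel_cv: float = 0.05
    planted_effects: Mapping[str, Mapping[tuple, float]] = field(default_factory=dict)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.probes_per_gene <= 0:
            raise ConfigError("n_genes and probes_per_gene must be positive")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if not self.pixel_cv > 0:
            raise ConfigError("pixel_cv must be > 0")
        if self.baseline_signal <= 0 or self.background_level <= 0:
            raise ConfigError("baseline_signal and background_level must be positive")
        if not self.strains or not self.conditions:
            raise ConfigError("strains and conditions must be nonempty")
        for gene, per_cond in self.planted_effects.items():
            for key, fold in per_cond.items():
                if not fold > 0:
                    raise ConfigError(
                        f"planted fold change for {gene}/{key} must be > 0"
                    )

    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


class SimulatedArray(NamedTuple):
    """Spot table plus the ground truth used to generate it."""

    spots: pd.DataFrame
    truth: pd.DataFrame


def _planted_fold(cfg: ArraySimConfig, gene: str, strain: str, condition: str) -> float:
    per_cond = cfg.planted_effects.get(gene)
    if not per_cond:
        return 1.0
    return float(per_cond.get((strain, condition), 1.0))


def simulate_spot_table(cfg: ArraySimConfig) -> SimulatedArray:
    """Generate one spot row per (gene, probe, replicate, strain, condition).

    The true spot-pixel mean is ``baseline_signal * fold + background_level``
    and the true background-pixel mean is ``background_level``. Reported
    means are normal around the truth with SD = ``pixel_cv`` × truth;
    reported deviations are the true SD times a chi-distributed factor
    (``sqrt(chi2(k)/k)``, k = :data:`PIXEL_DEV_DF`), so deviations are
    strictly positive. Returns the spot table and a truth table holding the
    expression fold of every (gene, strain, condition) cell.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genes = cfg.gene_ids()

    records: dict[str, list] = {k: [] for k in (
        "gene_id", "probe_id", "replicate", "strain", "condition")}
    true_spot = []
    truth_rows = []
    for strain in cfg.strains:
        for condition in cfg.conditions:
            for gene in genes:
                fold = _planted_fold(cfg, gene, strain, condition)
                truth_rows.append((gene, strain, condition, fold))
                tspot = cfg.baseline_signal * fold + cfg.background_level
                for p in range(cfg.probes_per_gene):
                    for r in range(cfg.n_replicates):
                        records["gene_id"].append(gene)
                        records["probe_id"].append(f"{gene}_p{p}")
                        records["replicate"].append(r + 1)
                        records["strain"].append(strain)
                        records["condition"].append(condition)
                        true_spot.append(tspot)

    n = len(true_spot)
    true_spot = np.asarray(true_spot)
    true_bg = np.full(n, cfg.background_level)

    sd_spot = cfg.pixel_cv * true_spot
    sd_bg = cfg.pixel_cv * true_bg
    spot_mean = rng.normal(true_spot, sd_spot)
    bg_mean = rng.normal(true_bg, sd_bg)
    chi = np.sqrt(rng.chisquare(PIXEL_DEV_DF, size=(2, n)) / PIXEL_DEV_DF)
    spot_dev = sd_spot * chi[0]
    bg_dev = sd_bg * chi[1]

    tiny = np.finfo(float).tiny
    spots = pd.DataFrame(records)
    spots["spot_mean"] = np.maximum(spot_mean, tiny)
    spots["spot_dev"] = np.maximum(spot_dev, tiny)
    spots["bg_mean"] = np.maximum(bg_mean, tiny)
    spots["bg_dev"] = np.maximum(bg_dev, tiny)

    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "strain", "condition", "true_fold"]
    )
    return SimulatedArray(spots=spots, truth=truth)


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthSimConfig:
    """Lag → exponential → hard-cap turbidity curve with additive noise."""

    od0: float = 0.05
    mu_true: float = 0.25          # h^-1
    lag_true: float = 2.0          # h
    od_max: float = 2.0
    noise_sd: float = 0.005        # OD600 units, additive
    sampling_times: Sequence[float] = tuple(np.arange(0.0, 40.5, 1.0))
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu_true > 0:
            raise ConfigError("mu_true must be > 0")
        if self.lag_true < 0:
            raise ConfigError("lag_true must be >= 0")
        if not self.od_max > self.od0 > 0:
            raise ConfigError("need od_max > od0 > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(self.sampling_times) == 0:
            raise ConfigError("sampling_times must be nonempty")


def growth_model(t: np.ndarray, od0: float, mu: float, lag: float,
                 od_max: float) -> np.ndarray:
    """Noise-free OD(t): flat at od0 until lag, then exponential, capped."""
    t = np.asarray(t, dtype=float)
    od = od0 * np.exp(mu * np.clip(t - lag, 0.0, None))
    return np.minimum(od, od_max)


def simulate_growth_curve(cfg: GrowthSimConfig) -> pd.DataFrame:
    """Return a (time_h, od) table; noise is additive and clipped at zero."""
    rng = np.random.default_rng(cfg.rng_seed)
    t = np.asarray(cfg.sampling_times, dtype=float)
    od = growth_model(t, cfg.od0, cfg.mu_true, cfg.lag_true, cfg.od_max)
    if cfg.noise_sd > 0:
        od = od + rng.normal(0.0, cfg.noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return pd.DataFrame({"time_h": t, "od": od})


# ---------------------------------------------------------------------------
# dose-response endpoints
# ---------------------------------------------------------------------------

@dataclass
class DoseSimConfig:
    """Logistic endpoint decline, half-maximal at ``ic50_true``."""

    ic50_true: float = 150.0       # µM
    slope_true: float = 0.03       # per µM
    od_uninhibited: float = 1.0
    concentrations: Sequence[float] = (0.0, 25.0, 50.0, 100.0, 150.0,
                                       200.0, 300.0, 400.0)
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.ic50_true > 0:
            raise ConfigError("ic50_true must be > 0")
        c = np.asarray(self.concentrations, dtype=float)
        if c.size < 2 or np.any(np.diff(c) <= 0):
            raise ConfigError("concentrations must be ascending")
        if np.any(c < 0):
            raise ConfigError("concentrations must be non-negative")
        if c[0] != 0:
            raise ConfigError("first concentration must be 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def logistic_decline(c: np.ndarray, od0: float, slope: float,
                     ic50: float) -> np.ndarray:
    """Endpoint model od0 / (1 + exp(slope * (c - ic50)))."""
    c = np.asarray(c, dtype=float)
    return od0 / (1.0 + np.exp(slope * (c - ic50)))


def simulate_dose_response(cfg: DoseSimConfig) -> pd.DataFrame:
    """Return a (concentration_uM, od600) endpoint table for one replicate."""
    rng = np.random.default_rng(cfg.rng_seed)
    c = np.asarray(cfg.concentrations, dtype=float)
    od = logistic_decline(c, cfg.od_uninhibited, cfg.slope_true, cfg.ic50_true)
    if cfg.noise_sd > 0:
        od = od + rng.normal(0.0, cfg.noise_sd, size=od.shape)
    od = np.clip(od, 0.0, None)
    return pd.DataFrame({"concentration_uM": c, "od600": od})
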
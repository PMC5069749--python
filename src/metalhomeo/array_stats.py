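"""Single-channel microarray signal and significance statistics.

The algorithm has four stages:

(i)   per spot, the local-background pixel mean is subtracted from the spot
      pixel mean to give the signal; the signal's deviation is half the sum
      of the two pixel deviations, and the separation statistic
      ``D = |spot_mean - bg_mean| / (spot_dev + bg_dev)`` gates the spot
      (kept iff D > 1, i.e. the spot and background error bars do not touch);
(ii)  per probe, surviving replicate signals are averaged; their sample
      standard deviation and smallest spot D (D_min) are carried along;
(iii) per gene, probe summaries are averaged into a gene-level mean signal,
      mean deviation and overall D_min;
(iv)  per comparison, the ratio of two gene mean signals gives the fold
      change Q, and the comparison statistic
      ``D = |mean_a - mean_b| / (dev_a + dev_b)`` gates significance:
      a change is significant iff (Q >= 2 or Q <= 0.5) and D > 1.

D > 1 is exactly the statement that the two ± deviation bars do not overlap.
Genes whose signal cannot be established carry status codes: ``NF`` (not
found: no spot survived the D filter) and ``NQ`` (not quantifiable: a
comparison with a missing or non-positive operand).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotMeasurement", "SpotSignal", "GeneSignal", "ComparisonResult",
    "compute_spot_signal", "summarize_replicates", "aggregate_gene",
    "compare_signals", "spot_signal_table", "gene_signal_table",
    "compare_table", "separation_d",
    "Q_UP_DEFAULT", "Q_DOWN_DEFAULT", "D_CUT_DEFAULT",
]

Q_UP_DEFAULT = 2.0
Q_DOWN_DEFAULT = 0.5
D_CUT_DEFAULT = 1.0

SPOT_COLUMNS = ["gene_id", "probe_id", "replicate", "strain", "condition",
                "spot_mean", "spot_dev", "bg_mean", "bg_dev"]


def separation_d(mean_a: float, dev_a: float, mean_b: float, dev_b: float) -> float:
    """Error-bar separation statistic |mean_a - mean_b| / (dev_a + dev_b).

    Zero denominator: +inf when the means differ (infinitely well separated
    point values), 0 when they coincide — the continuous limit of the ratio.
    """
    num = abs(mean_a - mean_b)
    den = dev_a + dev_b
    if den == 0:
        return math.inf if num > 0 else 0.0
    return num / den


# ---------------------------------------------------------------------------
# scalar records and operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotMeasurement:
    gene_id: str
    probe_id: str
    replicate: int
    strain: str
    condition: str
    spot_mean: float
    spot_dev: float
    bg_mean: float
    bg_dev: float


@dataclass(frozen=True)
class SpotSignal:
    signal: float
    deviation: float
    d_value: float
    passes_filter: bool


@dataclass(frozen=True)
class GeneSignal:
    gene_id: str
    strain: str
    condition: str
    mean_signal: float
    deviation: float
    d_min: float
    n_spots_used: int
    status: str = "OK"            # OK | NF


@dataclass(frozen=True)
class ComparisonResult:
    gene_id: str
    comparison_id: str
    q_value: float                # NaN when status != OK
    d_comparison: float
    direction: str                # U | D | N
    significant: bool
    status: str                   # OK | NQ


def compute_spot_signal(m: SpotMeasurement) -> SpotSignal:
    """Stage (i): background subtraction, deviation pooling, D filter."""
    if m.spot_dev < 0 or m.bg_dev < 0:
        raise ValueError("pixel deviations must be >= 0")
    signal = m.spot_mean - m.bg_mean
    deviation = 0.5 * (m.spot_dev + m.bg_dev)
    d = separation_d(m.spot_mean, m.spot_dev, m.bg_mean, m.bg_dev)
    return SpotSignal(signal=signal, deviation=deviation, d_value=d,
                      passes_filter=d > 1.0)


def summarize_replicates(signals: Sequence[SpotSignal]):
    """Stage (ii): average D-passing replicate signals for one probe.

    Returns ``(mean, deviation, d_min, n)`` or ``None`` when no replicate
    survived the filter. Deviation is the sample SD (n-1 denominator); with
    a single surviving replicate it is reported as 0.0.
    """
    kept = [s for s in signals if s.passes_filter]
    if not kept:
        return None
    vals = np.array([s.signal for s in kept], dtype=float)
    mean = float(vals.mean())
    dev = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    d_min = min(s.d_value for s in kept)
    return mean, dev, d_min, len(kept)


def aggregate_gene(gene_id: str, strain: str, condition: str,
                   probe_summaries: Iterable[tuple]) -> GeneSignal:
    """Stage (iii): combine probe summaries of one gene.

    Each summary is a ``(mean, deviation, d_min, n)`` tuple from
    :func:`summarize_replicates`. Mean signal is the unweighted mean of
    probe means, deviation the unweighted mean of probe deviations and
    D_min the minimum over probes. An empty iterable yields an ``NF`` row.
    """
    summaries = [s for s in probe_summaries if s is not None]
    if not summaries:
        return GeneSignal(gene_id, strain, condition, math.nan, math.nan,
                          math.nan, 0, status="NF")
    means = [s[0] for s in summaries]
    devs = [s[1] for s in summaries]
    d_min = min(s[2] for s in summaries)
    n = sum(s[3] for s in summaries)
    return GeneSignal(gene_id, strain, condition,
                      float(np.mean(means)), float(np.mean(devs)),
                      float(d_min), int(n), status="OK")


def compare_signals(a: GeneSignal | None, b: GeneSignal | None,
                    comparison_id: str = "",
                    q_up: float = Q_UP_DEFAULT,
                    q_down: float = Q_DOWN_DEFAULT,
                    d_cut: float = D_CUT_DEFAULT) -> ComparisonResult:
    """Stage (iv): fold-change ratio Q and comparison D for one gene.

    Q = a.mean_signal / b.mean_signal (numerator first). Any missing, NF or
    non-positive operand makes the ratio meaningless -> status NQ with
    direction N; no epsilon flooring is applied, so no fold change can be
    manufactured from an absent signal.
    """
    gene = a.gene_id if a is not None else (b.gene_id if b is not None else "")
    ok = (a is not None and b is not None
          and a.status == "OK" and b.status == "OK"
          and a.mean_signal > 0 and b.mean_signal > 0)
    if not ok:
        return ComparisonResult(gene, comparison_id, math.nan, math.nan,
                                "N", False, status="NQ")
    q = a.mean_signal / b.mean_signal
    d = separation_d(a.mean_signal, a.deviation, b.mean_signal, b.deviation)
    if q >= q_up:
        direction = "U"
    elif q <= q_down:
        direction = "D"
    else:
        direction = "N"
    significant = direction != "N" and d > d_cut
    return ComparisonResult(gene, comparison_id, q, d, direction,
                            significant, status="OK")


# ---------------------------------------------------------------------------
# table-level pipeline (vectorised over a spot table)
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns: {', '.join(missing)}")


def spot_signal_table(spots: pd.DataFrame) -> pd.DataFrame:
    """Stage (i) over a whole spot table; appends signal/deviation/D columns."""
    _require_columns(spots, SPOT_COLUMNS, "spot table")
    if (spots["spot_dev"] < 0).any() or (spots["bg_dev"] < 0).any():
        raise ValueError("pixel deviations must be >= 0")
    out = spots.copy()
    num = (out["spot_mean"] - out["bg_mean"]).abs()
    den = out["spot_dev"] + out["bg_dev"]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))
    out["signal"] = out["spot_mean"] - out["bg_mean"]
    out["deviation"] = 0.5 * den
    out["d_value"] = d
    out["passes_filter"] = d > 1.0
    return out


def gene_signal_table(spot_signals: pd.DataFrame) -> pd.DataFrame:
    """Stages (ii)+(iii): per-(gene, strain, condition) signals with status.

    Every (gene, strain, condition) cell present in the input appears in
    the output; cells where no spot survived the D filter get status NF and
    NaN statistics.
    """
    _require_columns(spot_signals, ["gene_id", "probe_id", "replicate",
                                    "strain", "condition", "signal",
                                    "d_value", "passes_filter"],
                     "spot signal table")
    keys = ["gene_id", "strain", "condition"]
    universe = spot_signals[keys].drop_duplicates()

    kept = spot_signals[spot_signals["passes_filter"]]
    probe = (
        kept.groupby(keys + ["probe_id"], sort=False)
        .agg(mean=("signal", "mean"),
             dev=("signal", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
             d_min=("d_value", "min"),
             n=("signal", "size"))
        .reset_index()
    )
    gene = (
        probe.groupby(keys, sort=False)
        .agg(mean_signal=("mean", "mean"),
             deviation=("dev", "mean"),
             d_min=("d_min", "min"),
             n_spots_used=("n", "sum"))
        .reset_index()
    )
    out = universe.merge(gene, on=keys, how="left")
    out["status"] = np.where(out["mean_signal"].notna(), "OK", "NF")
    out["n_spots_used"] = out["n_spots_used"].fillna(0).astype(int)
    return out.sort_values(keys, kind="stable").reset_index(drop=True)


def compare_table(gene_signals: pd.DataFrame,
                  numerator: tuple[str, str],
                  denominator: tuple[str, str],
                  comparison_id: str | None = None,
                  q_up: float = Q_UP_DEFAULT,
                  q_down: float = Q_DOWN_DEFAULT,
                  d_cut: float = D_CUT_DEFAULT) -> pd.DataFrame:
    """Stage (iv) for every gene: numerator (strain, condition) over
    denominator (strain, condition)."""
    _require_columns(gene_signals, ["gene_id", "strain", "condition",
                                    "mean_signal", "deviation", "status"],
                     "gene signal table")
    if comparison_id is None:
        comparison_id = (f"{numerator[0]}:{numerator[1]}/"
                         f"{denominator[0]}:{denominator[1]}")

    def _side(sc: tuple[str, str], suffix: str) -> pd.DataFrame:
        strain, condition = sc
        side = gene_signals[(gene_signals["strain"] == strain)
                            & (gene_signals["condition"] == condition)]
        side = side[["gene_id", "mean_signal", "deviation", "status"]]
        return side.rename(columns={c: c + suffix
                                    for c in ("mean_signal", "deviation",
                                              "status")})

    merged = _side(numerator, "_a").merge(_side(denominator, "_b"),
                                          on="gene_id", how="outer")
    ok = ((merged["status_a"] == "OK") & (merged["status_b"] == "OK")
          & (merged["mean_signal_a"] > 0) & (merged["mean_signal_b"] > 0))

    with np.errstate(divide="ignore", invalid="ignore"):
        q = merged["mean_signal_a"] / merged["mean_signal_b"]
        num = (merged["mean_signal_a"] - merged["mean_signal_b"]).abs()
        den = merged["deviation_a"] + merged["deviation_b"]
        d = np.where(den > 0, num / den, np.where(num > 0, np.inf, 0.0))

    out = pd.DataFrame({"gene_id": merged["gene_id"]})
    out["comparison_id"] = comparison_id
    out["q_value"] = np.where(ok, q, np.nan)
    out["d_comparison"] = np.where(ok, d, np.nan)
    direction = np.where(ok & (q >= q_up), "U",
                         np.where(ok & (q <= q_down), "D", "N"))
    out["direction"] = direction
    out["significant"] = ok.to_numpy() & (direction != "N") & (np.asarray(d) > d_cut)
    out["status"] = np.where(ok, "OK", "NQ")
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)
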
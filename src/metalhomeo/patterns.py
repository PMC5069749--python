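"""Regulation-pattern classification across comparisons and cluster ratios.

A gene's behaviour over an ordered set of comparisons is summarised as a
string over {U, D, N} — up (Q >= 2), down (Q <= 0.5), or not regulated —
one letter per comparison. Genes are then tallied per realised pattern,
separating totals from the subcount whose calls all pass the D > 1
error-bar criterion. Unquantifiable comparisons (status NQ) classify as N
but are flagged so they remain auditable.

Operon-region clusters (e.g. "Op0317f": co-oriented adjacent genes, f/r
for strand) are summarised by the mean ± sample SD of their member genes'
Q ratios in a chosen comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_stats import ComparisonResult

__all__ = ["PatternKey", "ClusterRatio", "classify_gene", "classify_table",
           "count_patterns", "cluster_mean_ratio", "cluster_ratio_table"]


@dataclass(frozen=True)
class PatternKey:
    comparison_ids: tuple
    pattern: str                  # one of U/D/N per comparison
    has_nq: bool = False

    def __post_init__(self) -> None:
        if len(self.pattern) != len(self.comparison_ids):
            raise ValueError("pattern length must match comparison count")


@dataclass(frozen=True)
class ClusterRatio:
    cluster_id: str
    gene_ids: tuple
    mean_q: float
    deviation_q: float
    single_member: bool = False


def classify_gene(results: Mapping[str, ComparisonResult],
                  comparison_ids: Sequence[str]) -> PatternKey:
    """Assemble a gene's U/D/N pattern in the given comparison order.

    NQ results classify as N (the pattern alphabet has no fourth letter)
    with ``has_nq`` set. A missing comparison id is an input error.
    """
    letters = []
    has_nq = False
    for cid in comparison_ids:
        if cid not in results:
            raise KeyError(f"comparison {cid!r} missing for gene")
        r = results[cid]
        if r.status != "OK":
            letters.append("N")
            has_nq = True
        else:
            letters.append(r.direction)
    return PatternKey(tuple(comparison_ids), "".join(letters), has_nq)


def classify_table(comparisons: pd.DataFrame,
                   comparison_ids: Sequence[str]) -> pd.DataFrame:
    """Per-gene pattern table from a long comparison table.

    ``comparisons`` must hold one row per (gene_id, comparison_id) with
    columns direction, significant, status. Returns one row per gene with
    its pattern string, an any-NQ flag, and ``all_calls_significant`` —
    true iff the gene has at least one U/D call and every U/D call passed
    the D > 1 gate.
    """
    need = {"gene_id", "comparison_id", "direction", "significant", "status"}
    missing = need - set(comparisons.columns)
    if missing:
        raise ValueError(f"comparison table missing columns: {sorted(missing)}")
    present = set(comparisons["comparison_id"].unique())
    absent = [c for c in comparison_ids if c not in present]
    if absent:
        raise KeyError(f"comparisons absent from table: {absent}")

    sub = comparisons[comparisons["comparison_id"].isin(set(comparison_ids))]
    wide_dir = sub.pivot(index="gene_id", columns="comparison_id",
                         values="direction").reindex(columns=comparison_ids)
    if wide_dir.isna().any().any():
        bad = wide_dir.index[wide_dir.isna().any(axis=1)]
        raise KeyError(f"genes missing a requested comparison: {list(bad[:5])}")
    wide_sig = sub.pivot(index="gene_id", columns="comparison_id",
                         values="significant").reindex(columns=comparison_ids)
    wide_stat = sub.pivot(index="gene_id", columns="comparison_id",
                          values="status").reindex(columns=comparison_ids)

    dirs = wide_dir.to_numpy(dtype="U1")
    pattern = ["".join(row) for row in dirs]
    regulated = dirs != "N"
    sig = wide_sig.to_numpy(dtype=bool)
    all_sig = regulated.any(axis=1) & np.where(regulated, sig, True).all(axis=1)
    return pd.DataFrame({
        "gene_id": wide_dir.index,
        "pattern": pattern,
        "has_nq": (wide_stat.to_numpy() != "OK").any(axis=1),
        "all_calls_significant": all_sig,
    }).reset_index(drop=True)


def count_patterns(classified: pd.DataFrame) -> pd.DataFrame:
    """Tally genes per realised pattern.

    ``n_total`` counts every gene with the pattern (including those whose
    calls are nonsignificant, D < 1); ``n_significant`` counts the subset
    whose every U/D call passed the gate. Totals sum to the number of
    classified genes; output order is by descending n_total then pattern.
    """
    g = (classified.groupby("pattern", sort=False)
         .agg(n_total=("gene_id", "size"),
              n_significant=("all_calls_significant", "sum"))
         .reset_index())
    g["n_significant"] = g["n_significant"].astype(int)
    return (g.sort_values(["n_total", "pattern"], ascending=[False, True],
                          kind="stable")
            .reset_index(drop=True))


def cluster_mean_ratio(cluster_id: str, q_values: Mapping[str, float]) -> ClusterRatio:
    """Mean ± sample SD of a cluster's member Q ratios.

    ``q_values`` maps gene id -> Q; NaN entries (NQ genes) are excluded
    with a warning. A single surviving member reports deviation 0 with the
    ``single_member`` flag set.
    """
    kept = {g: q for g, q in q_values.items() if np.isfinite(q)}
    dropped = sorted(set(q_values) - set(kept))
    if dropped:
        warnings.warn(
            f"cluster {cluster_id}: excluding unquantifiable genes {dropped}",
            stacklevel=2)
    if not kept:
        raise ValueError(f"cluster {cluster_id} has no quantifiable member")
    vals = np.array(list(kept.values()), dtype=float)
    single = vals.size == 1
    dev = 0.0 if single else float(vals.std(ddof=1))
    return ClusterRatio(cluster_id, tuple(kept), float(vals.mean()), dev,
                        single_member=single)


def cluster_ratio_table(comparisons: pd.DataFrame,
                        gene_to_cluster: Mapping[str, str],
                        comparison_id: str) -> pd.DataFrame:
    """Cluster mean-ratio table for one comparison.

    ``gene_to_cluster`` maps gene id -> operon-region label. Clusters whose
    members are all NQ are omitted.
    """
    sub = comparisons[comparisons["comparison_id"] == comparison_id]
    qmap = dict(zip(sub["gene_id"], sub["q_value"]))
    rows = []
    clusters: dict[str, list[str]] = {}
    for gene, cl in gene_to_cluster.items():
        clusters.setdefault(cl, []).append(gene)
    for cl in sorted(clusters):
        q_values = {g: qmap.get(g, np.nan) for g in clusters[cl]}
        if not any(np.isfinite(q) for q in q_values.values()):
            warnings.warn(f"cluster {cl}: no quantifiable member; skipped",
                          stacklevel=2)
            continue
        r = cluster_mean_ratio(cl, q_values)
        rows.append((cl, len(r.gene_ids), r.mean_q, r.deviation_q))
    return pd.DataFrame(rows, columns=["cluster_id", "n_genes",
                                       "mean_q", "deviation_q"])
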
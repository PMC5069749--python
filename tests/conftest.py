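import numpy as np
import pandas as pd
import pytest

from metalhomeo import ArraySimConfig, simulate_spot_table

#: small enough that the noise-free limit holds to float precision while
#: honouring the generator's pixel_cv > 0 invariant
TINY_CV = 1e-12


@pytest.fixture
def small_array():
    """20-gene, 2-strain × 2-condition array with one 4-fold planted gene."""
    cfg = ArraySimConfig(
        n_genes=20, probes_per_gene=2, n_replicates=3,
        strains=["d7", "ref"], conditions=["EDTA", "Zn"],
        planted_effects={"g00003": {("d7", "EDTA"): 4.0}},
        pixel_cv=TINY_CV, rng_seed=7)
    return simulate_spot_table(cfg)


def naive_gene_table(spots: pd.DataFrame) -> list[dict]:
    """Straight-line reference for stages (i)-(iii): explicit loops, no
    grouping machinery. Returns one dict per (gene, strain, condition)."""
    rows = [dict(r) for _, r in spots.iterrows()]
    cells = sorted({(r["gene_id"], r["strain"], r["condition"]) for r in rows})
    out = []
    for gene, strain, cond in cells:
        probe_stats = []
        probes = sorted({r["probe_id"] for r in rows
                         if (r["gene_id"], r["strain"], r["condition"])
                         == (gene, strain, cond)})
        for probe in probes:
            sigs, ds = [], []
            for r in rows:
                if (r["gene_id"], r["probe_id"], r["strain"],
                        r["condition"]) != (gene, probe, strain, cond):
                    continue
                num = abs(r["spot_mean"] - r["bg_mean"])
                den = r["spot_dev"] + r["bg_dev"]
                d = (num / den) if den > 0 else (np.inf if num > 0 else 0.0)
                if d > 1.0:
                    sigs.append(r["spot_mean"] - r["bg_mean"])
                    ds.append(d)
            if not sigs:
                continue
            m = sum(sigs) / len(sigs)
            if len(sigs) > 1:
                sd = (sum((s - m) ** 2 for s in sigs) / (len(sigs) - 1)) ** 0.5
            else:
                sd = 0.0
            probe_stats.append((m, sd, min(ds), len(sigs)))
        if probe_stats:
            out.append({
                "gene_id": gene, "strain": strain, "condition": cond,
                "mean_signal": sum(p[0] for p in probe_stats) / len(probe_stats),
                "deviation": sum(p[1] for p in probe_stats) / len(probe_stats),
                "d_min": min(p[2] for p in probe_stats),
                "n_spots_used": sum(p[3] for p in probe_stats),
                "status": "OK"})
        else:
            out.append({"gene_id": gene, "strain": strain, "condition": cond,
                        "mean_signal": np.nan, "deviation": np.nan,
                        "d_min": np.nan, "n_spots_used": 0, "status": "NF"})
    return out


def naive_compare(gene_rows: list[dict], num: tuple, den: tuple,
                  q_up=2.0, q_down=0.5, d_cut=1.0) -> dict[str, dict]:
    """Straight-line reference for stage (iv); keyed by gene id."""
    def cell(gene, sc):
        for r in gene_rows:
            if (r["gene_id"], r["strain"], r["condition"]) == (gene, *sc):
                return r
        return None
    genes = sorted({r["gene_id"] for r in gene_rows})
    out = {}
    for gene in genes:
        a, b = cell(gene, num), cell(gene, den)
        ok = (a is not None and b is not None and a["status"] == "OK"
              and b["status"] == "OK" and a["mean_signal"] > 0
              and b["mean_signal"] > 0)
        if not ok:
            out[gene] = {"q_value": np.nan, "d_comparison": np.nan,
                         "direction": "N", "significant": False,
                         "status": "NQ"}
            continue
        q = a["mean_signal"] / b["mean_signal"]
        numd = abs(a["mean_signal"] - b["mean_signal"])
        dend = a["deviation"] + b["deviation"]
        d = (numd / dend) if dend > 0 else (np.inf if numd > 0 else 0.0)
        direction = "U" if q >= q_up else ("D" if q <= q_down else "N")
        out[gene] = {"q_value": q, "d_comparison": d, "direction": direction,
                     "significant": direction != "N" and d > d_cut,
                     "status": "OK"}
    return out
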
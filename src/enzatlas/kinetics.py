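"""Integration of enzyme abundance with kinetic and thermodynamic parameters.

Per-enzyme Michaelis constants (K_M) are cleaned — non-wild-type records
dropped, then per-enzyme outliers removed by a 1.5*IQR rule on the log10
scale (K_M scatter is multiplicative) — and aggregated by geometric mean.
Each enzyme is then joined with the standard Gibbs free energy (ΔG°) of its
primary reaction and its mean CPC; pairwise Pearson and Spearman
correlations are reported on (log10 CPC, log10 K_M, ΔG°). Finally the three
variables are min-max scaled to [0, 1] (log scale for CPC and K_M, linear
for ΔG°) and every enzyme is assigned to one of four groups by explicit
thresholds — a reproducible surrogate for visual grouping:

    group 3: extreme K_M (scaled_km >= 0.9) — needs substrate buildup;
    group 4: very low ΔG° (scaled_dg0 <= 0.1) — effectively irreversible;
    group 2: highly expressed remainder (scaled_cpc >= 0.9);
    group 1: everything else (moderate in all three variables).

The assignment is exhaustive and mutually exclusive in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import CPCMatrix, UndefinedInputError

PAIRS = (("log_cpc", "log_km"), ("log_cpc", "dg0"), ("log_km", "dg0"))


def filter_km(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop non-wild-type records, then per-enzyme log-scale IQR outliers.

    Outlier rule: within each enzyme, log10 values outside
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of that enzyme's log10 K_M distribution are
    removed. Returns (surviving records, report of enzymes left with zero
    records and why).
    """
    dropped = []
    wt = records[records["wildtype"] == 1].copy()
    for enz in records.loc[records["wildtype"] != 1, "enzyme_id"].unique():
        if enz not in set(wt["enzyme_id"]):
            dropped.append({"enzyme_id": enz, "reason": "no wild-type records"})
    keep_parts = []
    for enz, grp in wt.groupby("enzyme_id", sort=True):
        logv = np.log10(grp["km_value"].to_numpy())
        q1, q3 = np.percentile(logv, [25, 75])
        iqr = q3 - q1
        ok = (logv >= q1 - 1.5 * iqr) & (logv <= q3 + 1.5 * iqr)
        if not ok.any():
            dropped.append({"enzyme_id": enz, "reason": "all records outliers"})
            continue
        keep_parts.append(grp[ok])
    out = (pd.concat(keep_parts).sort_index() if keep_parts
           else records.iloc[0:0].copy())
    report = pd.DataFrame(dropped, columns=["enzyme_id", "reason"])
    return out, report


def aggregate_km(records: pd.DataFrame, method: str = "geometric") -> pd.DataFrame:
    """One K_M per enzyme: geometric mean (default) or arithmetic mean of the
    surviving records, with the contributing measurement count."""
    if method not in ("geometric", "arithmetic"):
        raise ValueError("method must be 'geometric' or 'arithmetic'")
    rows = []
    for enz, grp in records.groupby("enzyme_id", sort=True):
        v = grp["km_value"].to_numpy()
        agg = float(stats.gmean(v)) if method == "geometric" else float(v.mean())
        rows.append({"enzyme_id": enz, "km": agg, "n_measurements": len(v)})
    return pd.DataFrame(rows, columns=["enzyme_id", "km", "n_measurements"])


def join_kinetics(km_agg: pd.DataFrame, thermo: pd.DataFrame,
                  reaction_meta: pd.DataFrame, m: CPCMatrix,
                  expand_reactions: bool = False,
                  absent_as_zero: bool = True) -> pd.DataFrame:
    """Inner-join enzymes having all of mean CPC, K_M and ΔG°.

    ΔG° is per reaction; each enzyme takes the ΔG° of its primary reaction
    (first listed in the metadata), or one row per enzyme-reaction pair with
    ``expand_reactions=True`` (flagged in the ``n_reactions`` column).
    """
    dg = thermo.set_index("reaction_id")["dg0"]
    pairs = []
    for r in reaction_meta.itertuples(index=False):
        for enz in str(r.enzyme_id).split(";"):
            if enz:
                pairs.append((enz, r.reaction_id))
    enz_rxns: dict[str, list] = {}
    for enz, rid in pairs:
        enz_rxns.setdefault(enz, []).append(rid)

    mean_cpc = m.mean_cpc(absent_as_zero=absent_as_zero)
    km_by_enz = km_agg.set_index("enzyme_id")
    rows = []
    for enz in sorted(set(km_by_enz.index) & set(enz_rxns) & set(m.values.index)):
        rxns = [rid for rid in enz_rxns[enz] if rid in dg.index]
        if not rxns:
            continue
        chosen = rxns if expand_reactions else rxns[:1]
        for rid in chosen:
            cpc = float(mean_cpc[enz])
            km = float(km_by_enz.loc[enz, "km"])
            if cpc <= 0 or km <= 0:
                continue
            rows.append({
                "enzyme_id": enz, "reaction_id": rid,
                "mean_cpc": cpc, "km": km, "dg0": float(dg[rid]),
                "log_cpc": np.log10(cpc), "log_km": np.log10(km),
                "n_reactions": len(rxns),
            })
    return pd.DataFrame(rows, columns=[
        "enzyme_id", "reaction_id", "mean_cpc", "km", "dg0",
        "log_cpc", "log_km", "n_reactions"])


def correlate(joined: pd.DataFrame) -> pd.DataFrame:
    """Pearson and Spearman coefficients on the three variable pairs."""
    if len(joined) < 3:
        raise UndefinedInputError(
            f"need >= 3 joined enzymes for correlations, got {len(joined)}")
    rows = []
    for x, y in PAIRS:
        xv, yv = joined[x].to_numpy(), joined[y].to_numpy()
        pr, pp = stats.pearsonr(xv, yv)
        sr, sp = stats.spearmanr(xv, yv)
        rows.append({
            "pair": f"{x}~{y}", "pearson_r": float(pr), "pearson_p": float(pp),
            "spearman_r": float(sr), "spearman_p": float(sp), "n": len(joined),
        })
    return pd.DataFrame(rows)


def join_and_correlate(km_agg, thermo, reaction_meta, m: CPCMatrix,
                       **kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    joined = join_kinetics(km_agg, thermo, reaction_meta, m, **kwargs)
    return joined, correlate(joined)


def scale_unit(values) -> np.ndarray:
    """Min-max scale a variable to [0, 1]; strictly order-preserving."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise UndefinedInputError("need >= 2 values to scale")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise UndefinedInputError("constant variable cannot be scaled to [0, 1]")
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class GroupThresholds:
    t_km: float = 0.9    # scaled_km at or above -> group 3
    t_dg: float = 0.1    # scaled_dg0 at or below -> group 4
    t_cpc: float = 0.9   # scaled_cpc at or above -> group 2


def assign_groups(joined: pd.DataFrame,
                  thresholds: GroupThresholds = GroupThresholds()) -> pd.DataFrame:
    """Scale the three variables and assign each enzyme to one of 4 groups.

    Scaling: log10 for CPC and K_M, linear for ΔG°; min maps to 0, max to 1.
    Group rule documented in the module docstring; every row receives
    exactly one group.
    """
    out = joined.copy()
    out["scaled_cpc"] = scale_unit(out["log_cpc"])
    out["scaled_km"] = scale_unit(out["log_km"])
    out["scaled_dg0"] = scale_unit(out["dg0"])

    def rule(r) -> int:
        if r["scaled_km"] >= thresholds.t_km:
            return 3
        if r["scaled_dg0"] <= thresholds.t_dg:
            return 4
        if r["scaled_cpc"] >= thresholds.t_cpc:
            return 2
        return 1

    out["group"] = out.apply(rule, axis=1).astype(int)
    return out
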
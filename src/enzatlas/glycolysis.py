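"""Sequential profiling of a core pathway and branch-vs-core comparison.

The core glycolytic pathway is the ordered chain of steps converting glucose
to lactate; at several steps the substrate can instead be diverted by a
branch-point enzyme into a biosynthetic pathway (e.g. 3-phosphoglycerate to
serine synthesis via PHGDH, competing with PGAM along glycolysis). This
module orders enzyme abundance along the chain, compares each step's core
enzyme(s) to the branch enzymes acting on the same substrate, and exports
node/edge attribute tables for graph renderers.

A packaged, editable step list ships as ``data/core_glycolysis.tsv`` — a
best-effort reconstruction of the canonical eleven-step glucose-to-lactate
chain; users with a different isoenzyme convention should edit the TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CPCMatrix


@dataclass
class CoreStep:
    index: int
    substrate: str
    product: str
    core_enzymes: tuple
    branch_enzymes: tuple


@dataclass
class CorePathway:
    """Ordered chain of steps; product of step i is the substrate of i+1."""

    steps: list[CoreStep]

    def __post_init__(self) -> None:
        for a, b in zip(self.steps, self.steps[1:]):
            if a.product != b.substrate:
                raise ValueError(
                    f"step {a.index} product {a.product!r} != "
                    f"step {b.index} substrate {b.substrate!r}"
                )
        for s in self.steps:
            if not s.core_enzymes:
                raise ValueError(f"step {s.index} has no core enzyme")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CorePathway":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if "branch_enzymes" not in df.columns:
            df["branch_enzymes"] = ""
        df = df.fillna("")  # short rows (no branch column) read as NaN
        steps = [
            CoreStep(
                index=int(r.step_index),
                substrate=r.substrate,
                product=r.product,
                core_enzymes=tuple(e for e in r.core_enzymes.split(";") if e),
                branch_enzymes=tuple(
                    e for e in getattr(r, "branch_enzymes", "").split(";") if e
                ),
            )
            for r in df.itertuples(index=False)
        ]
        steps.sort(key=lambda s: s.index)
        return cls(steps)

    @classmethod
    def canonical_glycolysis(cls) -> "CorePathway":
        ref = resources.files("enzatlas").joinpath("data/core_glycolysis.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


def sequential_profile(cp: CorePathway, m: CPCMatrix,
                       isoenzyme_mode: str = "sum") -> pd.DataFrame:
    """Per-step abundance statistics in pathway order.

    One row per (step, enzyme) plus, when a step carries several isoenzymes,
    a step-level row whose CPC is their sum (default) or max per cell line.
    Enzymes absent from the matrix are reported as missing rows rather than
    dropped. Row order is a pure function of the pathway definition.
    """
    if isoenzyme_mode not in ("sum", "max"):
        raise ValueError("isoenzyme_mode must be 'sum' or 'max'")
    rows = []
    for s in cp.steps:
        per_enzyme = {}
        for e in s.core_enzymes:
            if e in m.values.index:
                v = m.values.loc[e].fillna(0.0)
                per_enzyme[e] = v
                rows.append({
                    "step_index": s.index, "substrate": s.substrate,
                    "product": s.product, "enzyme": e, "level": "enzyme",
                    "missing": False,
                    "mean_cpc": float(v.mean()), "min_cpc": float(v.min()),
                    "max_cpc": float(v.max()),
                })
            else:
                rows.append({
                    "step_index": s.index, "substrate": s.substrate,
                    "product": s.product, "enzyme": e, "level": "enzyme",
                    "missing": True,
                    "mean_cpc": np.nan, "min_cpc": np.nan, "max_cpc": np.nan,
                })
        if len(s.core_enzymes) > 1:
            if per_enzyme:
                stacked = pd.DataFrame(per_enzyme)
                agg = stacked.sum(axis=1) if isoenzyme_mode == "sum" else stacked.max(axis=1)
                rows.append({
                    "step_index": s.index, "substrate": s.substrate,
                    "product": s.product, "enzyme": ";".join(s.core_enzymes),
                    "level": "step", "missing": False,
                    "mean_cpc": float(agg.mean()), "min_cpc": float(agg.min()),
                    "max_cpc": float(agg.max()),
                })
            else:
                rows.append({
                    "step_index": s.index, "substrate": s.substrate,
                    "product": s.product, "enzyme": ";".join(s.core_enzymes),
                    "level": "step", "missing": True,
                    "mean_cpc": np.nan, "min_cpc": np.nan, "max_cpc": np.nan,
                })
    return pd.DataFrame(rows, columns=[
        "step_index", "substrate", "product", "enzyme", "level", "missing",
        "mean_cpc", "min_cpc", "max_cpc"])


def branch_vs_core_comparison(cp: CorePathway, m: CPCMatrix,
                              isoenzyme_mode: str = "sum") -> pd.DataFrame:
    """Compare branch-point enzymes against the core enzyme on each substrate.

    For every step with >= 1 branch enzyme: the core and branch per-cell-line
    CPC series (isoenzymes summed by default, absences as zero), their means,
    the branch/core mean ratio, and the exceedance count — the number of cell
    lines where the branch CPC is >= the core CPC. A zero core mean flags the
    ratio as undefined.
    """
    rows = []
    for s in cp.steps:
        if not s.branch_enzymes:
            continue
        core = _group_series(s.core_enzymes, m, isoenzyme_mode)
        for be in s.branch_enzymes:
            br = _group_series((be,), m, isoenzyme_mode)
            core_mean, br_mean = float(core.mean()), float(br.mean())
            rows.append({
                "step_index": s.index,
                "substrate": s.substrate,
                "core_enzymes": ";".join(s.core_enzymes),
                "branch_enzyme": be,
                "core_mean_cpc": core_mean,
                "branch_mean_cpc": br_mean,
                "ratio": (br_mean / core_mean) if core_mean > 0 else np.nan,
                "ratio_undefined": core_mean <= 0,
                "exceedance_count": int((br >= core).sum()) if core_mean > 0 or br_mean > 0 else 0,
                "n_cell_lines": int(m.values.shape[1]),
            })
    return pd.DataFrame(rows, columns=[
        "step_index", "substrate", "core_enzymes", "branch_enzyme",
        "core_mean_cpc", "branch_mean_cpc", "ratio", "ratio_undefined",
        "exceedance_count", "n_cell_lines"])


def _group_series(enzymes, m: CPCMatrix, isoenzyme_mode: str) -> pd.Series:
    present = [e for e in enzymes if e in m.values.index]
    if not present:
        return pd.Series(0.0, index=m.values.columns)
    sub = m.values.loc[present].fillna(0.0)
    return sub.sum(axis=0) if isoenzyme_mode == "sum" else sub.max(axis=0)


def node_size_table(cp: CorePathway, m: CPCMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge attribute tables for rendering the pathway diagram.

    Nodes: metabolites, core enzymes and branch enzymes with their mean CPC
    (absences as zero; the ``size`` column is mean CPC directly, so renderer
    scaling stays linear in abundance). Edges: substrate -> enzyme ->
    product for each step, plus substrate -> branch-enzyme edges.
    """
    mean_cpc = m.mean_cpc()
    nodes: dict[str, dict] = {}
    edges: list[dict] = []

    def add_node(nid: str, ntype: str) -> None:
        if nid not in nodes:
            cpc = float(mean_cpc.get(nid, 0.0)) if ntype != "metabolite" else np.nan
            nodes[nid] = {"id": nid, "type": ntype, "mean_cpc": cpc,
                          "size": cpc if ntype != "metabolite" else np.nan}

    for s in cp.steps:
        add_node(s.substrate, "metabolite")
        add_node(s.product, "metabolite")
        for e in s.core_enzymes:
            add_node(e, "enzyme")
            edges.append({"source": s.substrate, "target": e})
            edges.append({"source": e, "target": s.product})
        for e in s.branch_enzymes:
            add_node(e, "branch")
            edges.append({"source": s.substrate, "target": e})
    node_df = pd.DataFrame(nodes.values(), columns=["id", "type", "mean_cpc", "size"])
    edge_df = pd.DataFrame(edges, columns=["source", "target"]).drop_duplicates(
    ).reset_index(drop=True)
    return node_df, edge_df
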
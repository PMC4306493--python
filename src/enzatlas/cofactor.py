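"""Cofactor-usage classification and abundance ranking.

Oxidoreductases are defined structurally: any enzyme whose reaction carries
NAD+/NADH (NAD-linked) or NADP+/NADPH (NADP-linked) among its reactants or
products — both sides are considered so reversible reactions are not
missed. Aminotransferases are traced the same way through α-ketoglutarate,
the universal amino-group carrier in nitrogen assimilation. Classification
is a pure network property; enzymes are then ranked by mean CPC so the
dominant users of each cofactor pool stand out.

Metabolite ids are matched against a synonym list
(``data/cofactor_synonyms.tsv``); compartment tags (``nad_c``, ``nad[m]``,
``nad_m``) are stripped by default since cofactor pools are not resolved by
compartment here.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CPCMatrix, ReactionNetwork

_COMPARTMENT_RE = re.compile(r"(_[a-z]|\[[a-z]\])$")


def load_synonyms(path: str | Path | None = None) -> pd.DataFrame:
    """Synonym table mapping canonical metabolite ids to cofactor classes."""
    if path is None:
        ref = resources.files("enzatlas").joinpath("data/cofactor_synonyms.tsv")
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", dtype=str)
    return pd.read_csv(path, sep="\t", dtype=str)


def normalize_metabolite(met: str, collapse_compartments: bool = True) -> str:
    m = met.strip().lower()
    if collapse_compartments:
        m = _COMPARTMENT_RE.sub("", m)
    return m


@dataclass
class CofactorClassification:
    enzyme_id: str
    classes: set = field(default_factory=set)
    direction: str = ""        # reactant | product | both
    mean_cpc: float = float("nan")


def _classify(net: ReactionNetwork, m: CPCMatrix, wanted_classes: set,
              synonyms: pd.DataFrame,
              collapse_compartments: bool = True) -> list[CofactorClassification]:
    syn_class = {
        normalize_metabolite(cid, collapse_compartments): cls
        for cid, cls in synonyms[["canonical_id", "class"]].itertuples(
            index=False, name=None)
    }
    mean_cpc = m.mean_cpc()
    found_any = False
    by_enzyme: dict[str, CofactorClassification] = {}
    s = net.stoichiometry
    for rid, grp in s.groupby("reaction_id"):
        sides: dict[str, set] = {}
        for met, coef in grp[["metabolite_id", "coefficient"]].itertuples(
                index=False, name=None):
            cls = syn_class.get(normalize_metabolite(met, collapse_compartments))
            if cls is None or cls not in wanted_classes:
                continue
            found_any = True
            sides.setdefault(cls, set()).add("reactant" if coef < 0 else "product")
        if not sides:
            continue
        for enz in net.enzymes_of(rid):
            rec = by_enzyme.setdefault(
                enz, CofactorClassification(enzyme_id=enz,
                                            mean_cpc=float(mean_cpc.get(enz, np.nan)))
            )
            for cls, dirset in sides.items():
                rec.classes.add(cls)
                new = "both" if len(dirset) == 2 else next(iter(dirset))
                if rec.direction in ("", new):
                    rec.direction = new
                else:
                    rec.direction = "both"
    if not found_any:
        warnings.warn(
            "no cofactor metabolite ids found in the network; check the "
            "synonym list and metabolite naming", stacklevel=2,
        )
    out = list(by_enzyme.values())
    out.sort(key=lambda r: (-(r.mean_cpc if np.isfinite(r.mean_cpc) else -np.inf),
                            r.enzyme_id))
    return out


def classify_redox(net: ReactionNetwork, m: CPCMatrix,
                   synonyms: pd.DataFrame | None = None,
                   collapse_compartments: bool = True) -> list[CofactorClassification]:
    """NAD(H)- and NADP(H)-linked enzymes, ranked by mean CPC descending."""
    syn = synonyms if synonyms is not None else load_synonyms()
    return _classify(net, m, {"NAD_linked", "NADP_linked"}, syn,
                     collapse_compartments)


def classify_aminotransferases(net: ReactionNetwork, m: CPCMatrix,
                               synonyms: pd.DataFrame | None = None,
                               collapse_compartments: bool = True,
                               ) -> list[CofactorClassification]:
    """α-ketoglutarate-using enzymes (nitrogen assimilation), ranked by CPC."""
    syn = synonyms if synonyms is not None else load_synonyms()
    return _classify(net, m, {"aminotransferase"}, syn, collapse_compartments)


def cofactor_usage_table(classifications: list[CofactorClassification],
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node table (enzyme, class, direction, mean CPC) and bipartite
    enzyme-cofactor-class edge table for graph rendering."""
    node_rows, edge_rows = [], []
    for rec in classifications:
        node_rows.append({
            "enzyme_id": rec.enzyme_id,
            "classes": ";".join(sorted(rec.classes)),
            "direction": rec.direction,
            "mean_cpc": rec.mean_cpc,
        })
        for cls in sorted(rec.classes):
            edge_rows.append({"enzyme_id": rec.enzyme_id, "cofactor_class": cls})
    nodes = pd.DataFrame(node_rows,
                         columns=["enzyme_id", "classes", "direction", "mean_cpc"])
    edges = pd.DataFrame(edge_rows, columns=["enzyme_id", "cofactor_class"])
    return nodes, edges
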
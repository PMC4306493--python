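"""Readers and writers for the pipeline's flat-file interchange formats.

All tabular formats are plain TSV (CSV and XLSX are accepted for the CPC
table). Undetected abundance entries are written as *empty fields*, never as
zeros — readers preserve that distinction as ``NaN``.

A small SBML-subset reader is provided for reaction networks exported from
genome-scale reconstructions: it consumes ``listOfSpecies``,
``listOfReactions`` with ``listOfReactants``/``listOfProducts`` and the
``reversible`` attribute, which is all this pipeline needs.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .types import CPCMatrix, FormatError, PathwayMap, ReactionNetwork


# ---------------------------------------------------------------------------
# atomic writes
# ---------------------------------------------------------------------------

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename, so a crash mid-write
    never leaves a truncated output behind."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=index))


# ---------------------------------------------------------------------------
# CPC matrix + tissues
# ---------------------------------------------------------------------------

def read_cpc_table(path: str | Path, tissue_path: str | Path) -> CPCMatrix:
    """Read a protein × cell-line CPC table plus its tissue annotation.

    The table dialect is inferred from the suffix: ``.tsv`` (tab), ``.csv``
    (comma) or ``.xlsx``. The first column holds protein ids; the header row
    holds cell-line ids. Empty cells mean *not detected*.

    Raises
    ------
    FormatError
        On duplicate protein ids, negative values, or cell lines without a
        tissue label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        df = pd.read_excel(path, index_col=0)
    elif suffix == ".csv":
        df = pd.read_csv(path, index_col=0)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "protein_id"
    df.columns = [str(c) for c in df.columns]
    df = df.astype(float)

    tissues = read_tissues(tissue_path)
    return CPCMatrix(df, tissues)


def read_tissues(path: str | Path) -> pd.Series:
    t = pd.read_csv(path, sep="\t", dtype=str)
    if list(t.columns[:2]) != ["cell_line", "tissue"]:
        raise FormatError(f"tissue file must have columns cell_line, tissue: {path}")
    if t["cell_line"].duplicated().any():
        raise FormatError("duplicate cell line in tissue file")
    return pd.Series(t["tissue"].values, index=t["cell_line"].values, name="tissue")


def write_cpc_table(m: CPCMatrix, path: str | Path, tissue_path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "protein_id"
    # %.10g keeps round-trips lossless at the precision the generator emits
    atomic_write_text(path, df.to_csv(sep="\t", float_format="%.10g", na_rep=""))
    tdf = pd.DataFrame({"cell_line": m.tissues.index, "tissue": m.tissues.values})
    write_tsv(tdf, tissue_path)


# ---------------------------------------------------------------------------
# pathway map
# ---------------------------------------------------------------------------

def read_pathway_map(path: str | Path) -> PathwayMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and list(df.columns) != ["pathway_id", "protein_id"]:
        df = pd.DataFrame(columns=["pathway_id", "protein_id"])
    return PathwayMap(df)


def write_pathway_map(p: PathwayMap, path: str | Path) -> None:
    write_tsv(p.pairs, path)


# ---------------------------------------------------------------------------
# reaction network (TSV triples or SBML subset)
# ---------------------------------------------------------------------------

def read_network(stoich_path: str | Path, meta_path: str | Path) -> ReactionNetwork:
    """Read a network from a stoichiometry triple file and a metadata file.

    ``stoich_path``: reaction_id TAB metabolite_id TAB coefficient, with
    negative coefficients for consumed metabolites. ``meta_path``:
    reaction_id, reversible (0/1), enzyme_id (';'-separated, may be empty),
    pathway_id.
    """
    stoich = pd.read_csv(
        stoich_path, sep="\t",
        dtype={"reaction_id": str, "metabolite_id": str, "coefficient": float},
    )
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    meta["reversible"] = meta["reversible"].astype(int)
    return ReactionNetwork(stoich, meta)


def write_network(net: ReactionNetwork, stoich_path: str | Path, meta_path: str | Path) -> None:
    write_tsv(net.stoichiometry, stoich_path)
    write_tsv(net.reactions.reset_index(drop=True), meta_path)


_SBML_NS = "{http://www.sbml.org/sbml/level3/version1/core}"


def read_network_sbml(path: str | Path) -> ReactionNetwork:
    """Read an SBML-subset network file (level-agnostic tag matching).

    Enzyme and pathway annotation are taken from ``name`` attributes of the
    form ``enzyme=E1;E2|pathway=P`` when present, else left empty.
    """
    tree = etree.parse(str(path))
    root = tree.getroot()

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    rows = []
    meta_rows = []
    for rxn in root.iter():
        if local(rxn.tag) != "reaction":
            continue
        rid = rxn.get("id")
        reversible = 1 if str(rxn.get("reversible", "false")).lower() == "true" else 0
        enzyme, pathway = "", ""
        name = rxn.get("name", "")
        for part in name.split("|"):
            if part.startswith("enzyme="):
                enzyme = part[len("enzyme="):]
            elif part.startswith("pathway="):
                pathway = part[len("pathway="):]
        for child in rxn:
            kind = local(child.tag)
            if kind not in ("listOfReactants", "listOfProducts"):
                continue
            sign = -1.0 if kind == "listOfReactants" else 1.0
            for ref in child:
                if local(ref.tag) != "speciesReference":
                    continue
                coef = float(ref.get("stoichiometry", "1"))
                rows.append(
                    {"reaction_id": rid, "metabolite_id": ref.get("species"),
                     "coefficient": sign * coef}
                )
        meta_rows.append(
            {"reaction_id": rid, "reversible": reversible,
             "enzyme_id": enzyme, "pathway_id": pathway}
        )
    if not rows:
        raise FormatError(f"no reactions found in SBML file {path}")
    return ReactionNetwork(pd.DataFrame(rows), pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# kinetic tables
# ---------------------------------------------------------------------------

def read_km_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"enzyme_id": str, "km_value": float, "wildtype": int})
    if (df["km_value"] <= 0).any():
        raise FormatError("K_M values must be positive")
    return df


def read_thermo(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"reaction_id": str, "dg0": float})
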
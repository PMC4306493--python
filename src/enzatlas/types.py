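"""Core in-memory containers shared across the pipeline.

The central object is the :class:`CPCMatrix`, a protein-by-cell-line table of
cell protein copy numbers (CPC) — standardized estimates of absolute protein
copies per cell derived from label-free mass-spectrometry quantification.
Missing entries (``NaN``) mean *not detected*, which is distinct from a
measured zero; every detection-based filter in this package relies on that
distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input table violates its documented format contract."""


class UndefinedInputError(ValueError):
    """Raised when an operation is requested on an empty or degenerate input."""


@dataclass
class CPCMatrix:
    """Protein × cell-line absolute abundance table with tissue annotation.

    Parameters
    ----------
    values
        DataFrame indexed by protein id with one column per cell line.
        ``NaN`` marks an undetected entry; present values must be ≥ 0.
    tissues
        Series mapping each cell-line id to its tissue-of-origin label.
        Every column of ``values`` must be covered.
    """

    values: pd.DataFrame
    tissues: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate protein ids: {list(dups[:5])}")
        present = self.values.to_numpy(dtype=float)
        if np.nanmin(present, initial=0.0) < 0:
            raise FormatError("negative CPC value encountered")
        missing = set(self.values.columns) - set(self.tissues.index)
        if missing:
            raise FormatError(f"cell lines missing tissue annotation: {sorted(missing)[:5]}")
        self.tissues = self.tissues.reindex(self.values.columns)

    # -- basic accessors ---------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_line_ids(self) -> pd.Index:
        return self.values.columns

    def tissue_of(self, cell_line: str) -> str:
        return self.tissues[cell_line]

    def detected(self) -> pd.DataFrame:
        """Boolean mask of detected entries (present and strictly positive)."""
        return self.values.notna() & (self.values > 0)

    def mean_cpc(self, absent_as_zero: bool = True) -> pd.Series:
        """Per-protein arithmetic mean CPC across all cell lines.

        With ``absent_as_zero`` (default) undetected entries count as zero and
        the denominator is the full panel of cell lines, so low-prevalence
        proteins are not inflated. With ``absent_as_zero=False`` the mean runs
        over detecting cell lines only.
        """
        if absent_as_zero:
            return self.values.fillna(0.0).mean(axis=1)
        return self.values.mean(axis=1)

    def subset(self, proteins: Iterable[str]) -> "CPCMatrix":
        keep = self.values.index.intersection(pd.Index(proteins))
        return CPCMatrix(self.values.loc[keep].copy(), self.tissues.copy())


@dataclass
class PathwayMap:
    """Many-to-many pathway → protein membership (KEGG-style).

    A protein may belong to several pathways; proteins with at least one
    membership constitute the *metabolic* subset of the proteome.
    """

    pairs: pd.DataFrame  # columns: pathway_id, protein_id

    def __post_init__(self) -> None:
        expected = ["pathway_id", "protein_id"]
        if list(self.pairs.columns) != expected:
            self.pairs = self.pairs[expected]
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)

    @property
    def metabolic_proteins(self) -> set:
        return set(self.pairs["protein_id"])

    @property
    def pathway_ids(self) -> list:
        return sorted(self.pairs["pathway_id"].unique())

    def proteins_of(self, pathway_id: str) -> set:
        return set(self.pairs.loc[self.pairs["pathway_id"] == pathway_id, "protein_id"])

    def pathways_of(self, protein_id: str) -> set:
        return set(self.pairs.loc[self.pairs["protein_id"] == protein_id, "pathway_id"])

    def membership_counts(self) -> pd.Series:
        return self.pairs.groupby("protein_id").size()


@dataclass
class ReactionNetwork:
    """Stoichiometric reaction network with enzyme and pathway annotation.

    ``stoichiometry`` holds one row per (reaction, metabolite) pair with a
    signed coefficient — negative for consumed, positive for produced.
    ``reactions`` carries per-reaction metadata: a reversibility flag, the
    catalyzing enzyme id(s) (';'-separated for isoenzymes/complexes, empty if
    unmeasured) and the pathway the reaction is assigned to.
    """

    stoichiometry: pd.DataFrame  # reaction_id, metabolite_id, coefficient
    reactions: pd.DataFrame      # reaction_id, reversible, enzyme_id, pathway_id

    def __post_init__(self) -> None:
        self.reactions = self.reactions.set_index(
            self.reactions["reaction_id"]
        ) if self.reactions.index.name != "reaction_id" else self.reactions
        bad = []
        for rid, grp in self.stoichiometry.groupby("reaction_id"):
            coef = grp["coefficient"].to_numpy()
            if not ((coef < 0).any() and (coef > 0).any()):
                bad.append(rid)
        if bad:
            raise FormatError(f"reactions without both a reactant and a product: {bad[:5]}")

    @property
    def metabolite_ids(self) -> list:
        return sorted(self.stoichiometry["metabolite_id"].unique())

    @property
    def reaction_ids(self) -> list:
        return list(self.reactions["reaction_id"])

    def reactants_of(self, reaction_id: str) -> set:
        s = self.stoichiometry
        sel = (s["reaction_id"] == reaction_id) & (s["coefficient"] < 0)
        return set(s.loc[sel, "metabolite_id"])

    def products_of(self, reaction_id: str) -> set:
        s = self.stoichiometry
        sel = (s["reaction_id"] == reaction_id) & (s["coefficient"] > 0)
        return set(s.loc[sel, "metabolite_id"])

    def is_reversible(self, reaction_id: str) -> bool:
        return bool(self.reactions.loc[reaction_id, "reversible"])

    def enzymes_of(self, reaction_id: str) -> tuple:
        raw = self.reactions.loc[reaction_id, "enzyme_id"]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
            return ()
        return tuple(str(raw).split(";"))

    def pathway_of(self, reaction_id: str) -> str:
        return self.reactions.loc[reaction_id, "pathway_id"]

    def participants_of(self, reaction_id: str) -> set:
        s = self.stoichiometry
        return set(s.loc[s["reaction_id"] == reaction_id, "metabolite_id"])


@dataclass
class BranchRecord:
    """A branch point: one metabolite consumed by ≥ 2 distinct reactions.

    ``ranked`` lists the consuming reactions ranked by their (summed) enzyme
    mean CPC in descending order; ties broken by lexicographic enzyme id so
    ranking is deterministic. ``bd2``/``bd3`` are the top-2 / top-3 branch
    divergence scores; ``label`` is the class assigned by the 0.8 / 0.2 / 0
    thresholds.
    """

    metabolite: str
    reactions: tuple                      # consuming reaction ids (sorted)
    ranked: list = field(default_factory=list)  # [(reaction_id, enzymes, cpc)] desc
    bd2: float | None = None
    bd3: float | None = None
    label: str | None = None              # one_sided | equally_distributed | unclassified

    @property
    def n_routes(self) -> int:
        return len(self.reactions)

    def top_enzymes(self, k: int) -> list:
        out: list = []
        for _rid, enzymes, _cpc in self.ranked[:k]:
            out.extend(enzymes)
        return out


@dataclass
class BinnedPDF:
    """Log-binned relative-frequency histogram of CPC values.

    Bins are half-open intervals ``[10**(k*w), 10**((k+1)*w))`` anchored at
    ``10**0``; ``frequencies`` sum to one.
    """

    bin_edges: np.ndarray   # len = n_bins + 1, strictly increasing CPC values
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.frequencies < 0):
            raise ValueError("negative frequency")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin centers (midpoints on the log10 scale)."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "bin_center": self.bin_centers,
                "frequency": self.frequencies,
            }
        )
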
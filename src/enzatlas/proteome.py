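"""Proteome-level partitioning of absolute protein abundance.

Implements the detection filter (proteins seen in only one sample or one
tissue type are discarded), the metabolic-vs-non-metabolic split of total
CPC mass, per-pathway abundance percentages, and log-binned relative-
frequency distributions of CPC values.

Detection is defined as *present and strictly positive*; an absent (empty)
entry is never a detection. The per-protein "average CPC across all cell
lines" treats absent entries as zero by default — the mean runs over the
full cell-line panel — with the detecting-lines-only mean available via
``absent_as_zero=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import BinnedPDF, CPCMatrix, PathwayMap, UndefinedInputError


def filter_rare_proteins(m: CPCMatrix) -> tuple[CPCMatrix, list]:
    """Remove proteins detected in only one cell line or one tissue type.

    A protein is removed when its detected entries span fewer than two cell
    lines *or* fewer than two distinct tissues (proteins never detected are
    removed too). Returns the filtered matrix and the removed protein ids.
    The operation is idempotent.
    """
    det = m.detected()
    n_lines = det.sum(axis=1)
    tissue_arr = m.tissues.to_numpy()
    n_tissues = det.apply(lambda r: len(set(tissue_arr[r.to_numpy()])), axis=1)
    keep = (n_lines >= 2) & (n_tissues >= 2)
    removed = list(m.values.index[~keep])
    kept = CPCMatrix(m.values.loc[keep].copy(), m.tissues.copy())
    return kept, removed


def filter_statistics(m: CPCMatrix) -> pd.Series:
    """Mean CPC of the proteins the detection filter removes vs retains.

    Means are taken over detected entries only (a removed protein has at most
    a handful of measurements; averaging in its absences would mask the
    abundance contrast the filter is motivated by).
    """
    _kept, removed = filter_rare_proteins(m)
    removed_idx = pd.Index(removed)
    kept_idx = m.values.index.difference(removed_idx)

    def _mean_detected(idx: pd.Index) -> float:
        if len(idx) == 0:
            return float("nan")
        sub = m.values.loc[idx]
        vals = sub.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals) & (vals > 0)]
        return float(vals.mean()) if vals.size else float("nan")

    return pd.Series(
        {
            "removed_mean_cpc": _mean_detected(removed_idx),
            "retained_mean_cpc": _mean_detected(kept_idx),
            "n_removed": len(removed_idx),
            "n_retained": len(kept_idx),
        }
    )


def metabolic_fraction(m: CPCMatrix, p: PathwayMap,
                       absent_as_zero: bool = True) -> float:
    """Percentage of total mean-CPC mass carried by metabolic proteins.

    ``100 * sum(mean CPC of proteins with >= 1 pathway membership) /
    sum(mean CPC of all proteins)``. Apply :func:`filter_rare_proteins`
    first. The metabolic and non-metabolic percentages sum to 100 exactly.
    """
    if m.values.empty:
        raise UndefinedInputError("empty CPC matrix")
    mean_cpc = m.mean_cpc(absent_as_zero=absent_as_zero).fillna(0.0)
    total = mean_cpc.sum()
    if total <= 0:
        raise UndefinedInputError("total CPC mass is zero")
    metabolic = mean_cpc.index.isin(p.metabolic_proteins)
    return float(100.0 * mean_cpc[metabolic].sum() / total)


@dataclass
class PathwayFractions:
    """Per-cell-line pathway percentages with across-line summary stats."""

    per_cell_line: pd.DataFrame  # pathways x cell lines, percentages
    summary: pd.DataFrame        # median, mean, sd, min, max, n_proteins, detected

    def to_frame(self) -> pd.DataFrame:
        return self.summary.join(self.per_cell_line)


def pathway_fractions(m: CPCMatrix, p: PathwayMap,
                      denominator: str = "total") -> PathwayFractions:
    """Per-cell-line percentage of CPC mass in each pathway.

    For each cell line, a pathway's percentage is 100 x the summed CPC of its
    member proteins over the summed CPC of all proteins in that line
    (``denominator="total"``) or over the metabolic proteins only
    (``denominator="metabolic"``). A protein belonging to several pathways
    counts fully in each, so percentages need not sum to 100. Pathways with
    no detected member proteins are retained and flagged, never dropped.
    """
    if denominator not in ("total", "metabolic"):
        raise ValueError("denominator must be 'total' or 'metabolic'")
    vals = m.values.fillna(0.0)
    if denominator == "total":
        denom = vals.sum(axis=0)
    else:
        denom = vals.loc[vals.index.isin(p.metabolic_proteins)].sum(axis=0)
    denom = denom.replace(0.0, np.nan)

    det_any = m.detected().any(axis=1)
    rows, meta = {}, []
    for pw in p.pathway_ids:
        members = m.values.index.intersection(pd.Index(sorted(p.proteins_of(pw))))
        pct = 100.0 * vals.loc[members].sum(axis=0) / denom
        rows[pw] = pct
        meta.append({
            "pathway_id": pw,
            "n_proteins": len(members),
            "detected": bool(det_any.loc[members].any()) if len(members) else False,
        })
    per_line = pd.DataFrame(rows).T
    per_line.index.name = "pathway_id"
    meta_df = pd.DataFrame(meta).set_index("pathway_id")
    summary = pd.DataFrame({
        "median": per_line.median(axis=1),
        "mean": per_line.mean(axis=1),
        "sd": per_line.std(axis=1),
        "min": per_line.min(axis=1),
        "max": per_line.max(axis=1),
    }).join(meta_df)
    return PathwayFractions(per_line, summary)


def log_binned_pdf(values, width_exponent: float) -> BinnedPDF:
    """Relative-frequency histogram of CPC values on decade-fraction bins.

    Bins are half-open intervals ``[10**(k*w), 10**((k+1)*w))`` for integer
    ``k``, anchored at ``10**0``; with ``w = 0.3`` adjacent bin edges differ
    by a factor of 10^0.3. Zeros and absent values must be excluded before
    calling; frequencies sum to one.
    """
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise UndefinedInputError("no positive values to bin")
    if width_exponent <= 0:
        raise ValueError("width_exponent must be > 0")
    w = width_exponent
    k = np.floor(np.log10(v) / w).astype(int)
    # guard against float boundary error: value exactly at an edge belongs
    # to the bin whose lower edge it is
    lo = np.power(10.0, k * w)
    k = np.where(v < lo, k - 1, k)
    hi = np.power(10.0, (k + 1) * w)
    k = np.where(v >= hi, k + 1, k)
    kmin, kmax = int(k.min()), int(k.max())
    counts = np.bincount(k - kmin, minlength=kmax - kmin + 1).astype(float)
    freqs = counts / counts.sum()
    edges = np.power(10.0, np.arange(kmin, kmax + 2) * w)
    return BinnedPDF(edges, freqs)
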
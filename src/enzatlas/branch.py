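"""Branch-point extraction and branch-divergence scoring.

A *branch point* is a metabolite consumed as a reactant by two or more
distinct reactions: a place where competing enzymes divide a substrate
between routes. Because enzyme concentration bounds the flux each route can
carry, the distribution of abundance across a branch's enzymes measures how
strongly the network commits the substrate to one route.

The branch divergence (BD) scores, with C_n the mean CPC of the n-th most
abundant enzyme at the branch (rank by mean CPC, descending):

    BD_top2 = (C1 - C2) / C1              in [0, 1]
    BD_top3 = (C1 - C2 - C3) / C1         in [-1, 1], <= BD_top2

A branch is *one-sided* when BD_top2 > 0.8 (abundance concentrated on one
route) and *equally distributed* when BD_top2 < 0.2 or BD_top3 < 0. Between
classes, a Fisher's exact test per pathway asks which pathways are enriched
among one-sided versus equally distributed branch enzymes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import BranchRecord, CPCMatrix, ReactionNetwork


class UndefinedScoreError(ValueError):
    """BD score requested with a zero top-ranked concentration."""


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def extract_branch_points(net: ReactionNetwork,
                          exclude_metabolites: set | None = None,
                          reversible_both_sides: bool = False) -> list[BranchRecord]:
    """Enumerate metabolites consumed by >= 2 distinct reactions.

    Only the declared reactant side of each reaction counts by default;
    ``reversible_both_sides=True`` additionally treats the product side of
    reversible reactions as consumable. ``exclude_metabolites`` (e.g. a
    currency-metabolite list: ATP, H2O, cofactors) removes metabolites
    before enumeration.
    """
    excluded = exclude_metabolites or set()
    consumed: dict[str, set] = {}
    s = net.stoichiometry
    for rid, met, coef in s[["reaction_id", "metabolite_id", "coefficient"]].itertuples(
            index=False, name=None):
        if met in excluded:
            continue
        if coef < 0:
            consumed.setdefault(met, set()).add(rid)
        elif coef > 0 and reversible_both_sides and net.is_reversible(rid):
            consumed.setdefault(met, set()).add(rid)
    out = [
        BranchRecord(metabolite=met, reactions=tuple(sorted(rids)))
        for met, rids in sorted(consumed.items())
        if len(rids) >= 2
    ]
    return out


def dedupe_and_filter(branches: list[BranchRecord], m: CPCMatrix,
                      net: ReactionNetwork) -> list[BranchRecord]:
    """Collapse repeated branches and keep fully measured ones.

    Branches whose consuming-reaction sets are identical are repeats (one
    reaction pair may consume several shared substrates) and collapse to a
    single record — the lexicographically first metabolite is kept. A branch
    is retained only if every consuming reaction has at least one mapped
    enzyme and all of its mapped enzymes are present in the (filtered) CPC
    matrix.
    """
    seen: dict[tuple, BranchRecord] = {}
    for b in sorted(branches, key=lambda b: b.metabolite):
        seen.setdefault(b.reactions, b)
    out = []
    proteins = set(m.values.index)
    for b in seen.values():
        ok = True
        for rid in b.reactions:
            enz = net.enzymes_of(rid)
            if not enz or any(e not in proteins for e in enz):
                ok = False
                break
        if ok:
            out.append(b)
    return sorted(out, key=lambda b: b.metabolite)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def bd_top2(cpc_ranked) -> float:
    """(C1 - C2) / C1 over the two largest mean CPCs (descending order)."""
    c = list(cpc_ranked)
    if len(c) < 2:
        raise ValueError("bd_top2 needs >= 2 ranked concentrations")
    c1, c2 = float(c[0]), float(c[1])
    if c1 <= 0:
        raise UndefinedScoreError("top-ranked CPC must be > 0")
    return (c1 - c2) / c1


def bd_top3(cpc_ranked) -> float:
    """(C1 - C2 - C3) / C1 over the three largest mean CPCs; may be negative."""
    c = list(cpc_ranked)
    if len(c) < 3:
        raise ValueError("bd_top3 needs >= 3 ranked concentrations")
    c1, c2, c3 = float(c[0]), float(c[1]), float(c[2])
    if c1 <= 0:
        raise UndefinedScoreError("top-ranked CPC must be > 0")
    return (c1 - c2 - c3) / c1


def score_branches(branches: list[BranchRecord], m: CPCMatrix,
                   net: ReactionNetwork, isoenzyme_mode: str = "sum",
                   absent_as_zero: bool = True) -> list[BranchRecord]:
    """Rank each branch's routes by enzyme mean CPC and attach BD scores.

    A route's concentration is the sum (default) or max of its mapped
    enzymes' mean CPCs when a reaction carries several isoenzymes. Ties are
    broken by reaction id so the ranking is deterministic.
    """
    if isoenzyme_mode not in ("sum", "max"):
        raise ValueError("isoenzyme_mode must be 'sum' or 'max'")
    mean_cpc = m.mean_cpc(absent_as_zero=absent_as_zero)
    for b in branches:
        entries = []
        for rid in b.reactions:
            enz = net.enzymes_of(rid)
            vals = [float(mean_cpc.get(e, 0.0)) for e in enz]
            cpc = (sum(vals) if isoenzyme_mode == "sum" else max(vals)) if vals else 0.0
            entries.append((rid, enz, cpc))
        entries.sort(key=lambda t: (-t[2], t[1], t[0]))
        b.ranked = entries
        cpcs = [c for _r, _e, c in entries]
        b.bd2 = bd_top2(cpcs)
        b.bd3 = bd_top3(cpcs) if len(cpcs) >= 3 else None
    return branches


def classify_branch(b: BranchRecord, t_one_sided: float = 0.8,
                    t_equal: float = 0.2, t_equal_bd3: float = 0.0,
                    one_sided_on_bd3: bool = False) -> str:
    """Assign one_sided / equally_distributed / unclassified.

    one_sided: bd2 > 0.8 strictly (optionally also bd3 > 0.8);
    equally_distributed: bd2 < 0.2 strictly or bd3 < 0 strictly;
    otherwise unclassified. Thresholds are configurable; defaults as printed.
    """
    if b.bd2 is None:
        raise ValueError("score the branch before classifying it")
    if b.bd2 > t_one_sided or (one_sided_on_bd3 and b.bd3 is not None
                               and b.bd3 > t_one_sided):
        b.label = "one_sided"
    elif b.bd2 < t_equal or (b.bd3 is not None and b.bd3 < t_equal_bd3):
        b.label = "equally_distributed"
    else:
        b.label = "unclassified"
    return b.label


def classify_branches(branches: list[BranchRecord], **kwargs) -> list[BranchRecord]:
    for b in branches:
        classify_branch(b, **kwargs)
    return branches


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------

def bd_histogram(branches: list[BranchRecord], which: str = "top2") -> pd.DataFrame:
    """Bin BD scores at width 0.1, lower-end inclusive.

    top2 covers [0, 1] with the final bin upper-inclusive (a score of
    exactly 1 lands in [0.9, 1.0]); top3 covers [-1, 1] likewise.
    """
    if which == "top2":
        lo, hi = 0.0, 1.0
        scores = [b.bd2 for b in branches if b.bd2 is not None]
    elif which == "top3":
        lo, hi = -1.0, 1.0
        scores = [b.bd3 for b in branches if b.bd3 is not None]
    else:
        raise ValueError("which must be 'top2' or 'top3'")
    n_bins = int(round((hi - lo) / 0.1))
    edges = lo + 0.1 * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for s in scores:
        idx = int(np.floor((s - lo) / 0.1 + 1e-9))
        idx = min(max(idx, 0), n_bins - 1)  # top edge folds into last bin
        counts[idx] += 1
    return pd.DataFrame({
        "bin_low": np.round(edges[:-1], 10),
        "bin_high": np.round(edges[1:], 10),
        "count": counts,
    })


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def _contributing_enzymes(b: BranchRecord) -> list[tuple]:
    """(branch, enzyme) pairs that carried the classifying score.

    The top-2 ranked routes' enzymes contribute; where a top-3 score exists
    (>= 3 routes) the third route's enzymes contribute as well.
    """
    k = 3 if b.bd3 is not None else 2
    return [(b.metabolite, e) for e in b.top_enzymes(k)]


def exact_test_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, as used by
    :func:`pathway_enrichment`."""
    _odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def pathway_enrichment(one_sided: list[BranchRecord],
                       equal: list[BranchRecord],
                       net: ReactionNetwork,
                       bh_correction: bool = False) -> pd.DataFrame:
    """Per-pathway Fisher's exact test between branch classes.

    Contributing enzymes of each class (unique (branch, enzyme) pairs) are
    mapped to pathways through the reactions they catalyze; for each pathway
    a 2x2 table (in pathway vs not) x (one_sided vs equally_distributed)
    yields a two-sided exact p-value. ``ratio`` is the one-sided count over
    the equally-distributed count (NaN when the latter is zero, flagged).
    Raw p-values by default; Benjamini-Hochberg adjusted values are added
    with ``bh_correction=True``.
    """
    if not one_sided or not equal:
        raise ValueError("both branch classes must be non-empty")

    enz_pathways: dict[str, set] = {}
    for rid in net.reaction_ids:
        pw = net.pathway_of(rid)
        for e in net.enzymes_of(rid):
            if pw:
                enz_pathways.setdefault(e, set()).add(pw)

    def class_counts(branches: list[BranchRecord]) -> tuple[dict, int]:
        pairs = set()
        for b in branches:
            pairs.update(_contributing_enzymes(b))
        counts: dict[str, int] = {}
        for _met, e in pairs:
            for pw in enz_pathways.get(e, ()):
                counts[pw] = counts.get(pw, 0) + 1
        return counts, len(pairs)

    one_counts, n_one = class_counts(one_sided)
    eq_counts, n_eq = class_counts(equal)
    pathways = sorted(set(one_counts) | set(eq_counts))
    rows = []
    for pw in pathways:
        a, b_ = one_counts.get(pw, 0), eq_counts.get(pw, 0)
        table = [[a, b_], [n_one - a, n_eq - b_]]
        p = exact_test_p(table)
        rows.append({
            "pathway_id": pw,
            "one_sided_count": a,
            "equal_count": b_,
            "one_sided_total": n_one,
            "equal_total": n_eq,
            "p_value": float(p),
            "significant": bool(p < 0.05),
            "ratio": (a / b_) if b_ > 0 else float("nan"),
            "ratio_undefined": b_ == 0,
        })
    df = pd.DataFrame(rows, columns=[
        "pathway_id", "one_sided_count", "equal_count", "one_sided_total",
        "equal_total", "p_value", "significant", "ratio", "ratio_undefined",
    ])
    if bh_correction and not df.empty:
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
        out = np.empty_like(adj)
        out[order] = adj
        df["p_adj_bh"] = out
    return df


@dataclass
class BranchAnalysis:
    """Convenience wrapper: extract, dedupe, score and classify in one go."""

    branches: list[BranchRecord]

    @classmethod
    def run(cls, net: ReactionNetwork, m: CPCMatrix,
            exclude_metabolites: set | None = None,
            **classify_kwargs) -> "BranchAnalysis":
        raw = extract_branch_points(net, exclude_metabolites=exclude_metabolites)
        kept = dedupe_and_filter(raw, m, net)
        score_branches(kept, m, net)
        classify_branches(kept, **classify_kwargs)
        return cls(kept)

    def of_class(self, label: str) -> list[BranchRecord]:
        return [b for b in self.branches if b.label == label]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.branches:
            rows.append({
                "metabolite": b.metabolite,
                "reactions": ";".join(b.reactions),
                "enzymes": ";".join(e for _r, enz, _c in b.ranked for e in enz),
                "bd2": b.bd2,
                "bd3": b.bd3 if b.bd3 is not None else "",
                "class": b.label,
            })
        return pd.DataFrame(rows, columns=[
            "metabolite", "reactions", "enzymes", "bd2", "bd3", "class"])
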
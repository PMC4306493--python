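"""End-to-end pipeline: simulate -> profile -> glycolysis -> branch ->
cofactor -> kinetics, with a machine-readable run summary.

Each stage reads the flat files of the input directory, writes its TSV
outputs into the output directory and contributes a section to
``summary.json``. Outputs are written atomically, so re-running a stage
overwrites cleanly and never leaves partial files. Logging goes to stderr;
files and stdout carry results only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import branch as br
from . import cofactor as cf
from . import glycolysis as gly
from . import io as eio
from . import kinetics as kin
from . import proteome as prot
from .simulate import SimConfig, generate
from .types import CPCMatrix, PathwayMap, ReactionNetwork

log = logging.getLogger("enzatlas")

SUMMARY_SCHEMA_VERSION = 1
ALL_STAGES = ("simulate", "profile", "glycolysis", "branch", "cofactor", "kinetics")


class DependencyError(RuntimeError):
    """A requested stage's upstream inputs are missing."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with the documented defaults."""

    outdir: str = "enzatlas_out"
    indir: str | None = None       # defaults to outdir (where simulate wrote)
    stages: tuple = ALL_STAGES
    seed: int = 0
    sim: SimConfig | None = None   # None -> SimConfig(seed=seed)
    # analysis flags (the documented switchable choices)
    absent_as_zero: bool = True
    pathway_denominator: str = "total"
    pdf_width_exponent: float = 0.3
    glycolysis_pdf_width: float = 0.2
    currency_metabolites: tuple = ()
    reversible_both_sides: bool = False
    isoenzyme_mode: str = "sum"
    bd_one_sided: float = 0.8
    bd_equal: float = 0.2
    bd_equal_bd3: float = 0.0
    one_sided_on_bd3: bool = False
    bh_correction: bool = False
    km_aggregator: str = "geometric"
    t_km: float = 0.9
    t_dg: float = 0.1
    t_cpc: float = 0.9
    core_pathway_path: str | None = None
    verbose: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.pathway_denominator not in ("total", "metabolic"):
            raise ValueError("pathway_denominator must be 'total' or 'metabolic'")
        for name in ("t_km", "t_dg", "t_cpc"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.bd_equal <= self.bd_one_sided <= 1.0:
            raise ValueError("BD thresholds must satisfy 0 <= equal <= one_sided <= 1")


def _load_inputs(indir: Path) -> tuple[CPCMatrix, PathwayMap, ReactionNetwork,
                                       pd.DataFrame, pd.DataFrame]:
    needed = ["cpc_matrix.tsv", "tissues.tsv", "pathway_map.tsv",
              "network_stoichiometry.tsv", "reaction_meta.tsv",
              "km_table.tsv", "thermo.tsv"]
    missing = [n for n in needed if not (indir / n).exists()]
    if missing:
        raise DependencyError(
            f"missing inputs in {indir}: {missing}; run the simulate stage "
            "or point --indir at a directory with these files"
        )
    cpc = eio.read_cpc_table(indir / "cpc_matrix.tsv", indir / "tissues.tsv")
    pmap = eio.read_pathway_map(indir / "pathway_map.tsv")
    net = eio.read_network(indir / "network_stoichiometry.tsv",
                           indir / "reaction_meta.tsv")
    km = eio.read_km_table(indir / "km_table.tsv")
    thermo = eio.read_thermo(indir / "thermo.tsv")
    return cpc, pmap, net, km, thermo


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the summary."""
    config.validate()
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(config.indir) if config.indir else outdir

    summary: dict = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "software_version": __version__,
        "parameters": _param_dict(config),
        "stages": {},
    }

    if "simulate" in config.stages:
        log.info("stage simulate: generating synthetic inputs")
        sim = config.sim or SimConfig(seed=config.seed)
        ds = generate(sim)
        ds.write(indir)
        summary["stages"]["simulate"] = {
            "n_proteins": int(ds.cpc.values.shape[0]),
            "n_cell_lines": int(ds.cpc.values.shape[1]),
            "n_reactions": len(ds.network.reaction_ids),
            "manifest": str(indir / "manifest.json"),
        }

    analysis_stages = [s for s in config.stages if s != "simulate"]
    if not analysis_stages:
        _write_summary(summary, outdir)
        return summary

    cpc, pmap, net, km, thermo = _load_inputs(indir)
    filtered, removed = prot.filter_rare_proteins(cpc)
    fstats = prot.filter_statistics(cpc)
    eio.write_tsv(
        pd.DataFrame({"protein_id": removed, "removed": True}),
        outdir / "filter_report.tsv",
    )

    if "profile" in analysis_stages:
        log.info("stage profile: proteome partitioning")
        frac = prot.metabolic_fraction(filtered, pmap,
                                       absent_as_zero=config.absent_as_zero)
        pf = prot.pathway_fractions(filtered, pmap,
                                    denominator=config.pathway_denominator)
        eio.write_tsv(pf.to_frame().reset_index(), outdir / "pathway_fractions.tsv")
        all_vals = filtered.values.to_numpy().ravel()
        pdf_all = prot.log_binned_pdf(all_vals[np.isfinite(all_vals)],
                                      config.pdf_width_exponent)
        metab_idx = filtered.values.index.isin(pmap.metabolic_proteins)
        met_vals = filtered.values.loc[metab_idx].to_numpy().ravel()
        sections = {"all": pdf_all}
        if np.isfinite(met_vals).sum() and (met_vals[np.isfinite(met_vals)] > 0).any():
            sections["metabolic"] = prot.log_binned_pdf(
                met_vals[np.isfinite(met_vals)], config.pdf_width_exponent)
        for name, pdf in sections.items():
            eio.write_tsv(pdf.to_frame(), outdir / f"pdf_{name}.tsv")
        top = pf.summary["median"].sort_values(ascending=False)
        summary["stages"]["profile"] = {
            "metabolic_fraction_pct": frac,
            "non_metabolic_fraction_pct": 100.0 - frac,
            "n_removed_by_filter": len(removed),
            "removed_mean_cpc": float(fstats["removed_mean_cpc"]),
            "retained_mean_cpc": float(fstats["retained_mean_cpc"]),
            "n_pathways": len(pf.summary),
            "n_pathways_without_detected_proteins": int((~pf.summary["detected"]).sum()),
            "top_pathway_by_median_pct": (str(top.index[0]) if len(top) else None),
            "top_pathway_median_pct": (float(top.iloc[0]) if len(top) else None),
        }

    if "glycolysis" in analysis_stages:
        log.info("stage glycolysis: core-pathway profiling")
        cp = (gly.CorePathway.from_tsv(config.core_pathway_path)
              if config.core_pathway_path else gly.CorePathway.canonical_glycolysis())
        profile = gly.sequential_profile(cp, filtered, isoenzyme_mode=config.isoenzyme_mode)
        bvc = gly.branch_vs_core_comparison(cp, filtered,
                                            isoenzyme_mode=config.isoenzyme_mode)
        nodes, edges = gly.node_size_table(cp, filtered)
        eio.write_tsv(profile, outdir / "sequential_profile.tsv")
        eio.write_tsv(bvc, outdir / "branch_vs_core.tsv")
        eio.write_tsv(nodes, outdir / "nodes.tsv")
        eio.write_tsv(edges, outdir / "edges.tsv")
        measured = profile[(profile["level"] == "enzyme") & (~profile["missing"])]
        summary["stages"]["glycolysis"] = {
            "n_steps": len(cp.steps),
            "n_missing_enzymes": int(profile["missing"].sum()),
            "peak_step": (int(measured.loc[measured["mean_cpc"].idxmax(),
                                           "step_index"])
                          if len(measured) else None),
            "branch_comparisons": len(bvc),
        }

    if "branch" in analysis_stages:
        log.info("stage branch: branch-point analysis")
        analysis = br.BranchAnalysis.run(
            net, filtered,
            exclude_metabolites=set(config.currency_metabolites) or None,
            t_one_sided=config.bd_one_sided, t_equal=config.bd_equal,
            t_equal_bd3=config.bd_equal_bd3,
            one_sided_on_bd3=config.one_sided_on_bd3,
        )
        eio.write_tsv(analysis.to_frame(), outdir / "branches.tsv")
        for which in ("top2", "top3"):
            eio.write_tsv(br.bd_histogram(analysis.branches, which),
                          outdir / f"bd_hist_{which}.tsv")
        one, eq = analysis.of_class("one_sided"), analysis.of_class("equally_distributed")
        tallies = {
            "n_branches": len(analysis.branches),
            "n_with_three_routes": sum(1 for b in analysis.branches if b.bd3 is not None),
            "one_sided": len(one),
            "equally_distributed": len(eq),
            "unclassified": len(analysis.of_class("unclassified")),
        }
        if one and eq:
            enr = br.pathway_enrichment(one, eq, net,
                                        bh_correction=config.bh_correction)
            eio.write_tsv(enr, outdir / "enrichment.tsv")
            tallies["n_significant_pathways"] = int(enr["significant"].sum())
        summary["stages"]["branch"] = tallies

    if "cofactor" in analysis_stages:
        log.info("stage cofactor: usage classification")
        redox = cf.classify_redox(net, filtered)
        amino = cf.classify_aminotransferases(net, filtered)
        for recs, stem in ((redox, "redox_ranking"), (amino, "aminotransferase_ranking")):
            nodes, edges = cf.cofactor_usage_table(recs)
            eio.write_tsv(nodes, outdir / f"{stem}.tsv")
            eio.write_tsv(edges, outdir / f"{stem.split('_')[0]}_edges.tsv")
        summary["stages"]["cofactor"] = {
            "n_redox_enzymes": len(redox),
            "n_aminotransferases": len(amino),
            "top_redox_enzyme": redox[0].enzyme_id if redox else None,
            "top_aminotransferase": amino[0].enzyme_id if amino else None,
        }

    if "kinetics" in analysis_stages:
        log.info("stage kinetics: K_M / ΔG° / CPC integration")
        surviving, drop_report = kin.filter_km(km)
        agg = kin.aggregate_km(surviving, method=config.km_aggregator)
        joined = kin.join_kinetics(agg, thermo, net.reactions.reset_index(drop=True),
                                   filtered, absent_as_zero=config.absent_as_zero)
        section: dict = {"n_joined": len(joined),
                         "n_enzymes_dropped": len(drop_report)}
        if len(joined) >= 3:
            corr = kin.correlate(joined)
            grouped = kin.assign_groups(
                joined, kin.GroupThresholds(config.t_km, config.t_dg, config.t_cpc))
            eio.write_tsv(grouped, outdir / "kinetics_joined.tsv")
            eio.write_tsv(corr, outdir / "correlations.tsv")
            section["correlations"] = {
                r["pair"]: {"pearson_r": r["pearson_r"], "spearman_r": r["spearman_r"]}
                for _i, r in corr.iterrows()
            }
            section["group_counts"] = {
                str(g): int(n) for g, n in
                grouped["group"].value_counts().sort_index().items()
            }
        summary["stages"]["kinetics"] = section

    _write_summary(summary, outdir)
    return summary


def _param_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["stages"] = list(d["stages"])
    d["currency_metabolites"] = list(d["currency_metabolites"])
    return d


def _write_summary(summary: dict, outdir: Path) -> None:
    _validate_summary(summary)
    eio.atomic_write_text(outdir / "summary.json",
                          json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _validate_summary(summary: dict) -> None:
    for key in ("schema_version", "software_version", "parameters", "stages"):
        if key not in summary:
            raise ValueError(f"summary missing required key {key!r}")
    if summary["schema_version"] != SUMMARY_SCHEMA_VERSION:
        raise ValueError("summary schema version mismatch")
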
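"""Synthetic proteome / network / kinetics generator with known ground truth.

Emulates the structure of an NCI-60-style absolute proteome study: a
protein-by-cell-line table of cell protein copy numbers (CPC) with roughly
log-normal abundance, a tissue label per cell line, sparse detection, a
KEGG-style pathway membership map, a Recon-style stoichiometric network
containing branch points with planted divergence patterns, and BRENDA-style
kinetic tables with injected mutant records and outliers.

Every emitted quantity is recorded in a manifest that is recomputable from
the emitted files, so parameter-recovery tests downstream are sharp. The
whole dataset is a pure function of :class:`SimConfig`; identical configs
produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .types import CPCMatrix, PathwayMap, ReactionNetwork


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class GenerationError(RuntimeError):
    """Configuration is structurally valid but unreachable in generation."""


# The canonical glycolysis block planted when ``include_glycolysis`` is on:
# eleven core steps (glucose -> lactate) plus branch enzymes acting on the
# same substrates. Step means (log10 CPC) are non-monotonic with the primary
# peak at GAPDH and a secondary peak at enolase.
_GLYC_CORE = [
    # (step substrate, product, core enzyme, planted log10 mean CPC)
    ("glc", "g6p", "HK2", 4.6),
    ("g6p", "f6p", "GPI", 4.8),
    ("f6p", "fbp", "PFKP", 4.9),
    ("fbp", "dhap", "ALDOA", 5.1),
    ("dhap", "gap", "TPI1", 5.3),
    ("gap", "bpg13", "GAPDH", 5.9),
    ("bpg13", "pg3", "PGK1", 5.2),
    ("pg3", "pg2", "PGAM1", 5.0),
    ("pg2", "pep", "ENO1", 5.6),
    ("pep", "pyr", "PKM", 5.4),
    ("pyr", "lac", "LDHA", 5.5),
]
_GLYC_BRANCH = {
    # substrate -> [(branch enzyme, planted log10 mean CPC)]
    "g6p": [("G6PD", 4.3), ("PGM1", 4.1)],
    "f6p": [("GFPT1", 4.2)],
    "dhap": [("GPD1", 4.0)],
    "pg3": [("PHGDH", 4.7)],   # values rewritten by the exceedance planting
    "pyr": [("GPT", 3.9), ("PDHA1", 4.4)],
}
GLYCOLYSIS_PATHWAY_ID = "Glycolysis"


@dataclass(frozen=True)
class KineticsNoise:
    """Replicate scatter and contamination rates for the K_M table.

    ``scatter`` is the standard deviation of log10 replicate noise;
    ``outlier_rate`` / ``mutant_rate`` are per-record probabilities that a
    replicate is displaced by ~4 decades (wild-type flagged) or flagged as a
    mutant experiment, respectively.
    """

    n_replicates: int = 4
    scatter: float = 0.15
    outlier_rate: float = 0.05
    mutant_rate: float = 0.1


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Abundance scale defaults emulate an NCI-60-like proteome: log10 CPC is
    normal with mean 4.2 and SD 0.8 across proteins, with per-cell-line
    scatter of 0.2 decades and a 90% detection rate. K_M values are in mM,
    ΔG° in kJ/mol.
    """

    n_proteins: int = 400
    n_cell_lines: int = 20
    tissues: Sequence[str] = ("breast", "lung", "renal", "melanoma")
    lognormal_mu: float = 4.2        # mean of log10 CPC across proteins
    lognormal_sigma: float = 0.8     # SD of log10 CPC across proteins
    cell_line_sigma: float = 0.2     # per-cell-line log10 scatter
    metabolic_fraction: float = 0.15  # fraction of proteins with >=1 pathway
    planted_pathways: Sequence[tuple] = (("PW_DOM", 12, 6.0),)
    pathway_overlap_fraction: float = 0.15  # proteins given a 2nd membership
    rare_fraction: float = 0.05      # proteins detected in 1 line or 1 tissue
    rare_log10_shift: float = -1.4   # abundance penalty for rare proteins
    n_metabolites: int = 60
    n_reactions: int = 40
    planted_branches: Sequence[tuple] = (("B_one", 2, 0.9), ("B_eq", 3, 0.1))
    n_nad_reactions: int = 4
    n_nadp_reactions: int = 3
    n_akg_reactions: int = 3
    detection_rate: float = 0.9
    include_glycolysis: bool = True
    phgdh_exceedance_lines: int = 7  # lines where PHGDH >= PGAM1
    kinetics_noise: KineticsNoise = field(default_factory=KineticsNoise)
    km_log10_mu: float = -0.5        # geometric-mean K_M ~ 0.3 mM
    km_log10_sigma: float = 1.0
    dg0_mu: float = -10.0
    dg0_sigma: float = 15.0
    corr_cpc_km: float = 0.0         # planted Pearson r on the log10 scale
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_proteins", "n_cell_lines", "n_metabolites", "n_reactions"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("lognormal_mu", "lognormal_sigma", "cell_line_sigma"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")
        if self.lognormal_sigma < 0 or self.cell_line_sigma < 0:
            raise ConfigError("sigmas must be >= 0")
        for name in ("metabolic_fraction", "detection_rate", "rare_fraction",
                     "pathway_overlap_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for mid, n_out, bd2 in self.planted_branches:
            if n_out < 2:
                raise ConfigError(f"branch {mid}: n_out_reactions must be >= 2")
            if not 0.0 <= bd2 <= 1.0:
                raise ConfigError(f"branch {mid}: target_bd2 must lie in [0, 1]")
        mids = [b[0] for b in self.planted_branches]
        if len(mids) != len(set(mids)):
            raise ConfigError("planted branch metabolite ids must be unique")
        kn = self.kinetics_noise
        if kn.n_replicates < 1 or kn.scatter < 0:
            raise ConfigError("invalid kinetics noise spec")
        if not (0 <= kn.outlier_rate <= 1 and 0 <= kn.mutant_rate <= 1):
            raise ConfigError("kinetics rates must lie in [0, 1]")
        if not np.isfinite(self.km_log10_mu) or self.km_log10_sigma < 0:
            raise ConfigError("invalid K_M distribution parameters")
        if not -1.0 <= self.corr_cpc_km <= 1.0:
            raise ConfigError("corr_cpc_km must lie in [-1, 1]")
        if self.include_glycolysis and self.metabolic_fraction * self.n_proteins < 24:
            raise ConfigError(
                "include_glycolysis needs >= 24 metabolic proteins; "
                "enlarge the proteome or disable it"
            )


@dataclass
class SyntheticDataset:
    """All pipeline inputs plus the ground-truth manifest."""

    cpc: CPCMatrix
    pathways: PathwayMap
    network: ReactionNetwork
    km_table: pd.DataFrame
    thermo: pd.DataFrame
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        eio.write_cpc_table(self.cpc, outdir / "cpc_matrix.tsv", outdir / "tissues.tsv")
        eio.write_pathway_map(self.pathways, outdir / "pathway_map.tsv")
        eio.write_network(self.network, outdir / "network_stoichiometry.tsv",
                          outdir / "reaction_meta.tsv")
        eio.write_tsv(self.km_table, outdir / "km_table.tsv")
        eio.write_tsv(self.thermo, outdir / "thermo.tsv")
        eio.atomic_write_text(
            outdir / "manifest.json",
            json.dumps(self.manifest, indent=2, sort_keys=True) + "\n",
        )


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate(config: SimConfig) -> SyntheticDataset:
    """Build the full synthetic dataset for one configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    cell_lines = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]
    tissues = pd.Series(
        [config.tissues[i % len(config.tissues)] for i in range(config.n_cell_lines)],
        index=cell_lines, name="tissue",
    )

    # ----- protein roster -------------------------------------------------
    n_metabolic = int(round(config.metabolic_fraction * config.n_proteins))
    glyc_proteins: list[str] = []
    if config.include_glycolysis:
        glyc_proteins = [enz for _s, _p, enz, _m in _GLYC_CORE]
        glyc_proteins += [enz for subs in _GLYC_BRANCH.values() for enz, _m in subs]

    n_generic_ids = config.n_proteins - len(glyc_proteins)
    if n_generic_ids < 0:
        raise ConfigError("n_proteins too small for the glycolysis block")
    generic_ids = [f"P{i + 1:04d}" for i in range(n_generic_ids)]
    protein_ids = glyc_proteins + generic_ids

    # planted pathways claim generic metabolic proteins first
    planted_assign: dict[str, list[str]] = {}
    cursor = 0
    for pw_id, n_pw, _mult in config.planted_pathways:
        if n_metabolic == 0:
            raise GenerationError(f"pathway {pw_id} planted with metabolic_fraction=0")
        take = generic_ids[cursor:cursor + n_pw]
        if len(take) < n_pw:
            raise GenerationError(f"pathway {pw_id} requests more proteins than available")
        planted_assign[pw_id] = take
        cursor += n_pw
    n_left = n_metabolic - len(glyc_proteins) - cursor
    if n_left < 0:
        raise GenerationError("planted pathways exceed the metabolic protein budget")
    generic_metabolic = generic_ids[cursor:cursor + n_left]
    metabolic_set = set(glyc_proteins) | set(
        pid for ids in planted_assign.values() for pid in ids
    ) | set(generic_metabolic)
    non_metabolic = [p for p in generic_ids if p not in metabolic_set]

    # generic pathways soak up the unplanted metabolic proteins, ~8 each
    pairs: list[tuple[str, str]] = []
    if config.include_glycolysis:
        pairs += [(GLYCOLYSIS_PATHWAY_ID, p) for p in glyc_proteins]
    for pw_id, ids in planted_assign.items():
        pairs += [(pw_id, p) for p in ids]
    n_generic_pw = max(1, int(np.ceil(len(generic_metabolic) / 8))) if generic_metabolic else 0
    generic_pw_ids = [f"PW{i + 1:02d}" for i in range(n_generic_pw)]
    for i, pid in enumerate(generic_metabolic):
        pairs.append((generic_pw_ids[i % n_generic_pw], pid))

    # overlap: give a slice of metabolic proteins a second membership
    all_pw = sorted({pw for pw, _ in pairs})
    if config.pathway_overlap_fraction > 0 and len(all_pw) >= 2 and metabolic_set:
        members = sorted(metabolic_set)
        n_overlap = max(1, int(round(config.pathway_overlap_fraction * len(members))))
        first_pw = {p: pw for pw, p in reversed(pairs)}
        chosen = rng.choice(len(members), size=min(n_overlap, len(members)), replace=False)
        for ci in sorted(chosen):
            pid = members[ci]
            others = [pw for pw in all_pw if pw != first_pw[pid]]
            pairs.append((others[int(rng.integers(len(others)))], pid))
    pathway_map = PathwayMap(pd.DataFrame(pairs, columns=["pathway_id", "protein_id"])
                             if pairs else
                             pd.DataFrame(columns=["pathway_id", "protein_id"]))

    # ----- abundance draws ------------------------------------------------
    base_log10 = pd.Series(
        rng.normal(config.lognormal_mu, config.lognormal_sigma, size=config.n_proteins),
        index=protein_ids,
    )
    if config.include_glycolysis:
        for s, p, enz, mu in _GLYC_CORE:
            base_log10[enz] = mu
        for subs in _GLYC_BRANCH.values():
            for enz, mu in subs:
                base_log10[enz] = mu
    for (pw_id, _n, mult), ids in zip(config.planted_pathways, planted_assign.values()):
        base_log10[ids] = base_log10[ids] + np.log10(mult)

    # rare proteins: low-abundance, detected in one line or one tissue only
    candidates = [p for p in non_metabolic] or [p for p in generic_ids]
    n_rare = int(round(config.rare_fraction * config.n_proteins))
    n_rare = min(n_rare, len(candidates))
    rare_proteins = sorted(
        np.array(candidates)[rng.choice(len(candidates), size=n_rare, replace=False)]
    ) if n_rare else []
    base_log10[rare_proteins] = (
        base_log10[rare_proteins] + config.rare_log10_shift
    )

    noise = rng.normal(0.0, config.cell_line_sigma,
                       size=(config.n_proteins, config.n_cell_lines))
    values = pd.DataFrame(
        np.power(10.0, base_log10.to_numpy()[:, None] + noise),
        index=pd.Index(protein_ids, name="protein_id"), columns=cell_lines,
    )

    # detection mask
    detected = rng.random(values.shape) < config.detection_rate
    forced_rows = []            # planted rows stay fully detected
    if config.include_glycolysis:
        forced_rows += glyc_proteins
    tissue_lines: dict[str, list[str]] = {}
    for cl, t in tissues.items():
        tissue_lines.setdefault(t, []).append(cl)
    row_pos = {p: i for i, p in enumerate(protein_ids)}
    col_pos = {c: j for j, c in enumerate(cell_lines)}
    for p in rare_proteins:
        detected[row_pos[p], :] = False
        if rng.random() < 0.5 or config.n_cell_lines < 2:
            detected[row_pos[p], int(rng.integers(config.n_cell_lines))] = True
        else:
            t = config.tissues[int(rng.integers(len(config.tissues)))]
            lines = tissue_lines.get(t, cell_lines[:1])
            for cl in lines[: max(1, min(2, len(lines)))]:
                detected[row_pos[p], col_pos[cl]] = True

    # ----- reaction network ----------------------------------------------
    branch_rows, incidental, net, branch_truth = _build_network(
        config, metabolic_set, pathway_map, protein_ids,
    )
    forced_rows += branch_rows

    for p in forced_rows:
        detected[row_pos[p], :] = True
    values = values.where(pd.DataFrame(detected, index=values.index,
                                       columns=values.columns))

    # planted branch enzymes: rescale so the absent-as-zero mean hits the
    # analytic target exactly -> realized BD2 == target_bd2
    for enz, target_mean in branch_truth["enzyme_target_means"].items():
        row = values.loc[enz]
        realized = row.fillna(0.0).mean()
        values.loc[enz] = row * (target_mean / realized)

    # PHGDH / PGAM1 exceedance planting
    if config.include_glycolysis and config.phgdh_exceedance_lines >= 0:
        k = min(config.phgdh_exceedance_lines, config.n_cell_lines)
        over = rng.choice(config.n_cell_lines, size=k, replace=False)
        mult = np.where(
            np.isin(np.arange(config.n_cell_lines), over),
            rng.uniform(1.05, 1.6, size=config.n_cell_lines),
            rng.uniform(0.15, 0.85, size=config.n_cell_lines),
        )
        values.loc["PHGDH"] = values.loc["PGAM1"].to_numpy() * mult

    cpc = CPCMatrix(values, tissues)

    # ----- kinetic tables -------------------------------------------------
    km_table, thermo, kin_truth = _build_kinetics(config, rng, cpc, net)

    # ----- manifest (recomputable ground truth) ---------------------------
    mean_cpc = cpc.mean_cpc(absent_as_zero=True)
    det = cpc.detected()
    n_lines_det = det.sum(axis=1)
    tissue_arr = tissues.to_numpy()
    n_tissues_det = det.apply(lambda r: len(set(tissue_arr[r.to_numpy()])), axis=1)
    keep = (n_lines_det >= 2) & (n_tissues_det >= 2)
    metab = mean_cpc.index.isin(metabolic_set)
    kept_mass = mean_cpc[keep].sum()
    true_fraction = (
        100.0 * mean_cpc[keep & pd.Series(metab, index=mean_cpc.index)].sum() / kept_mass
        if kept_mass > 0 else float("nan")
    )

    manifest = {
        "config": _config_dict(config),
        "proteins": {
            "metabolic": sorted(metabolic_set),
            "rare": list(map(str, rare_proteins)),
            "n_removed_by_filter": int((~keep).sum()),
        },
        "metabolic_fraction_pct": float(true_fraction),
        "planted_pathways": {
            pw: ids for pw, ids in planted_assign.items()
        },
        "glycolysis": (
            {
                "core_enzymes": [e for _s, _p, e, _m in _GLYC_CORE],
                "argmax_step": int(np.argmax([m for *_x, m in _GLYC_CORE])) + 1,
                "phgdh_exceedance_lines": int(
                    (values.loc["PHGDH"] >= values.loc["PGAM1"]).sum()
                ),
            }
            if config.include_glycolysis else None
        ),
        "branches": branch_truth["branches"],
        "incidental_branches": incidental,
        "cofactors": _cofactor_truth(net, cpc),
        "kinetics": kin_truth,
    }
    return SyntheticDataset(cpc, pathway_map, net, km_table, thermo, manifest)


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["tissues"] = list(d["tissues"])
    d["planted_pathways"] = [list(t) for t in d["planted_pathways"]]
    d["planted_branches"] = [list(t) for t in d["planted_branches"]]
    return d


def _build_network(config, metabolic_set, pathway_map, protein_ids):
    """Assemble stoichiometry: planted branches + linear chains + cofactors."""
    n_branch_rxn = sum(n_out for _m, n_out, _b in config.planted_branches)
    n_chain = config.n_reactions - n_branch_rxn
    if n_chain < 0:
        raise GenerationError("planted branches require more reactions than n_reactions")

    branch_mets = [b[0] for b in config.planted_branches]
    pool = [f"M{i + 1:03d}" for i in range(config.n_metabolites - len(branch_mets))]
    if n_chain + 1 > len(pool):
        raise GenerationError("n_metabolites too small for the requested chain length")

    # enzymes available for wiring: metabolic generics not already planted
    planted_prot = set()
    if config.include_glycolysis:
        planted_prot |= {e for _s, _p, e, _m in _GLYC_CORE}
        planted_prot |= {e for subs in _GLYC_BRANCH.values() for e, _m in subs}
    enzyme_pool = sorted(metabolic_set - planted_prot) or sorted(
        set(protein_ids) - planted_prot
    )
    need = config.n_reactions
    if len(enzyme_pool) < need:
        # reuse is allowed for chains but planted branches need distinct enzymes
        if len(enzyme_pool) < n_branch_rxn:
            raise GenerationError("not enough proteins to catalyze planted branches")
    pw_of_protein = {p: pw for pw, p in reversed(list(
        pathway_map.pairs.itertuples(index=False, name=None)))}
    all_pw = pathway_map.pathway_ids or ["PW_NA"]

    stoich_rows: list[dict] = []
    meta_rows: list[dict] = []
    branch_truth: dict = {"branches": {}, "enzyme_target_means": {}}
    e_cursor = 0
    prod_cursor = 0

    for mid, n_out, bd2 in config.planted_branches:
        c1 = 10.0 ** (config.lognormal_mu + 0.5)
        c2 = c1 * (1.0 - bd2)
        if c2 <= 0:  # target_bd2 == 1: epsilon-floored second route
            c2 = c1 * 1e-6
        means = [c1, c2] + [c2 * (0.6 ** k) for k in range(1, n_out - 1)]
        enzymes, rxns = [], []
        for k in range(n_out):
            rid = f"R_{mid}_{k + 1}"
            enz = enzyme_pool[e_cursor % len(enzyme_pool)]
            e_cursor += 1
            product = pool[prod_cursor % len(pool)]
            prod_cursor += 1
            stoich_rows.append({"reaction_id": rid, "metabolite_id": mid,
                                "coefficient": -1.0})
            stoich_rows.append({"reaction_id": rid, "metabolite_id": product,
                                "coefficient": 1.0})
            meta_rows.append({
                "reaction_id": rid, "reversible": 0, "enzyme_id": enz,
                "pathway_id": pw_of_protein.get(enz, all_pw[k % len(all_pw)]),
            })
            branch_truth["enzyme_target_means"][enz] = means[k]
            enzymes.append(enz)
            rxns.append(rid)
        eps_floored = bd2 >= 1.0
        realized_bd2 = (means[0] - means[1]) / means[0]
        realized_bd3 = ((means[0] - means[1] - means[2]) / means[0]
                        if n_out >= 3 else None)
        if realized_bd2 > 0.8:
            label = "one_sided"
        elif realized_bd2 < 0.2 or (realized_bd3 is not None and realized_bd3 < 0):
            label = "equally_distributed"
        else:
            label = "unclassified"
        branch_truth["branches"][mid] = {
            "reactions": rxns, "enzymes": enzymes,
            "target_bd2": float(bd2), "realized_bd2": float(realized_bd2),
            "realized_bd3": None if realized_bd3 is None else float(realized_bd3),
            "expected_class": label, "epsilon_floored": bool(eps_floored),
        }

    # linear chains over fresh pool metabolites; each consumed exactly once
    chain_start = prod_cursor  # keep chain reactants disjoint from branch wiring
    chain_mets = pool[chain_start:chain_start + n_chain + 1]
    if len(chain_mets) < n_chain + 1:
        chain_mets = pool[: n_chain + 1]
    cof_counts = [("nad", config.n_nad_reactions),
                  ("nadp", config.n_nadp_reactions),
                  ("akg", config.n_akg_reactions)]
    cof_plan: list[str] = []
    for kind, n in cof_counts:
        cof_plan += [kind] * max(0, n)
    for t in range(n_chain):
        rid = f"RC{t + 1:03d}"
        enz = enzyme_pool[e_cursor % len(enzyme_pool)] if enzyme_pool else ""
        e_cursor += 1
        stoich_rows.append({"reaction_id": rid, "metabolite_id": chain_mets[t],
                            "coefficient": -1.0})
        stoich_rows.append({"reaction_id": rid, "metabolite_id": chain_mets[t + 1],
                            "coefficient": 1.0})
        if t < len(cof_plan):
            kind = cof_plan[t]
            flip = t % 2 == 1  # alternate which side carries the reduced form
            if kind == "nad":
                a, b = ("nad_c", "nadh_c") if not flip else ("nadh_c", "nad_c")
            elif kind == "nadp":
                a, b = ("nadp_c", "nadph_c") if not flip else ("nadph_c", "nadp_c")
            else:
                a, b = ("akg_c", "glu_c") if not flip else ("glu_c", "akg_c")
            stoich_rows.append({"reaction_id": rid, "metabolite_id": a,
                                "coefficient": -1.0})
            stoich_rows.append({"reaction_id": rid, "metabolite_id": b,
                                "coefficient": 1.0})
        meta_rows.append({
            "reaction_id": rid, "reversible": int(t % 5 == 4), "enzyme_id": enz,
            "pathway_id": pw_of_protein.get(enz, all_pw[t % len(all_pw)]),
        })

    net = ReactionNetwork(pd.DataFrame(stoich_rows), pd.DataFrame(meta_rows))

    # incidental branch points: brute-force scan of the emitted stoichiometry
    consumed: dict[str, set] = {}
    for row in stoich_rows:
        if row["coefficient"] < 0:
            consumed.setdefault(row["metabolite_id"], set()).add(row["reaction_id"])
    incidental = sorted(
        m for m, rs in consumed.items()
        if len(rs) >= 2 and m not in set(branch_mets)
    )
    return list(branch_truth["enzyme_target_means"]), incidental, net, branch_truth


def _cofactor_truth(net: ReactionNetwork, cpc: CPCMatrix) -> dict:
    """Realized per-class enzyme rankings, recomputable from the files."""
    classes = {"NAD_linked": {"nad_c", "nadh_c"},
               "NADP_linked": {"nadp_c", "nadph_c"},
               "aminotransferase": {"akg_c"}}
    mean_cpc = cpc.mean_cpc()
    out = {}
    for cname, mets in classes.items():
        enz: set = set()
        for rid in net.reaction_ids:
            if net.participants_of(rid) & mets:
                enz |= set(net.enzymes_of(rid))
        ranked = sorted(
            ((e, float(mean_cpc.get(e, np.nan))) for e in enz if e),
            key=lambda t: (-(t[1] if np.isfinite(t[1]) else -np.inf), t[0]),
        )
        out[cname] = [[e, v] for e, v in ranked]
    return out


def _build_kinetics(config: SimConfig, rng, cpc: CPCMatrix, net: ReactionNetwork):
    """Per-enzyme K_M replicates and per-reaction ΔG° with planted structure."""
    kn = config.kinetics_noise
    enzymes = sorted({e for rid in net.reaction_ids for e in net.enzymes_of(rid)})
    primary_rxn = {}
    for rid in net.reaction_ids:           # first reaction listed = primary
        for e in net.enzymes_of(rid):
            primary_rxn.setdefault(e, rid)
    mean_cpc = cpc.mean_cpc()
    log_cpc = np.log10(mean_cpc.reindex(enzymes).clip(lower=1e-12).to_numpy())
    if len(enzymes) > 1 and np.std(log_cpc) > 0:
        z = (log_cpc - log_cpc.mean()) / log_cpc.std()
    else:
        z = np.zeros(len(enzymes))
    r = config.corr_cpc_km
    eps = rng.normal(size=len(enzymes))
    log_km = config.km_log10_mu + config.km_log10_sigma * (
        r * z + np.sqrt(max(0.0, 1.0 - r * r)) * eps
    )

    rows = []
    for i, enz in enumerate(enzymes):
        for _rep in range(kn.n_replicates):
            mutant = rng.random() < kn.mutant_rate
            outlier = rng.random() < kn.outlier_rate
            lv = log_km[i] + (rng.normal(0.0, kn.scatter) if kn.scatter > 0 else 0.0)
            if mutant:
                lv += rng.normal(0.0, 1.0) + 1.0
            elif outlier:
                lv += 4.0 * (1 if rng.random() < 0.5 else -1)
            rows.append({"enzyme_id": enz, "km_value": 10.0 ** lv,
                         "wildtype": 0 if mutant else 1})
    km_table = pd.DataFrame(rows, columns=["enzyme_id", "km_value", "wildtype"])

    dg0 = rng.normal(config.dg0_mu, config.dg0_sigma, size=len(net.reaction_ids))
    thermo = pd.DataFrame({"reaction_id": net.reaction_ids, "dg0": dg0})

    truth = {
        "true_km": {e: float(10.0 ** log_km[i]) for i, e in enumerate(enzymes)},
        "primary_reaction": primary_rxn,
        "planted_corr": {"log_cpc_log_km": float(r),
                         "log_cpc_dg0": 0.0, "log_km_dg0": 0.0},
    }
    return km_table, thermo, truth


# ---------------------------------------------------------------------------
# single-output convenience wrappers
# ---------------------------------------------------------------------------

def generate_cpc_matrix(config: SimConfig) -> CPCMatrix:
    return generate(config).cpc


def generate_pathway_map(config: SimConfig) -> PathwayMap:
    return generate(config).pathways


def generate_reaction_network(config: SimConfig) -> ReactionNetwork:
    return generate(config).network


def generate_kinetic_tables(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    ds = generate(config)
    return ds.km_table, ds.thermo
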
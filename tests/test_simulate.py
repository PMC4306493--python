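"""Generator contracts: determinism, planted structure, manifest consistency."""

import json

import numpy as np
import pandas as pd
import pytest

from enzatlas.simulate import ConfigError, GenerationError, KineticsNoise, SimConfig, generate


def _flat_config(**kw):
    """A degenerate-noise configuration used by several exactness tests."""
    base = dict(
        n_proteins=20, n_cell_lines=6, metabolic_fraction=0.5,
        planted_pathways=(), planted_branches=(),
        n_metabolites=12, n_reactions=8,
        lognormal_sigma=0.0, cell_line_sigma=0.0, detection_rate=1.0,
        rare_fraction=0.0, pathway_overlap_fraction=0.0,
        include_glycolysis=False,
        n_nad_reactions=1, n_nadp_reactions=1, n_akg_reactions=1,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestCPCMatrix:
    def test_degenerate_distribution_yields_constant_matrix(self):
        ds = generate(_flat_config(lognormal_mu=3.0))
        assert np.allclose(ds.cpc.values.to_numpy(), 1000.0)

    def test_same_seed_gives_byte_identical_files(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate(small_config).write(d1)
        generate(small_config).write(d2)
        for f in sorted(p.name for p in d1.iterdir()):
            assert (d1 / f).read_bytes() == (d2 / f).read_bytes(), f

    def test_sample_mean_of_log10_cpc_near_mu(self):
        cfg = _flat_config(n_proteins=10_000, n_metabolites=12, n_reactions=8,
                           lognormal_mu=4.0, lognormal_sigma=0.5)
        ds = generate(cfg)
        log10 = np.log10(ds.cpc.values.to_numpy()[:, 0])
        se = 0.5 / np.sqrt(10_000)
        assert abs(log10.mean() - 4.0) < 3 * se

    def test_tissue_labels_cover_every_cell_line(self, small_dataset):
        assert not small_dataset.cpc.tissues.isna().any()

    def test_nonfinite_distribution_parameters_rejected(self):
        with pytest.raises(ConfigError):
            generate(_flat_config(lognormal_mu=float("nan")))

    def test_detection_rate_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(detection_rate=1.5).validate()


class TestPathwayMap:
    def test_zero_metabolic_fraction_gives_empty_map(self):
        ds = generate(_flat_config(metabolic_fraction=0.0))
        assert ds.pathways.pairs.empty

    def test_single_planted_pathway_of_five_gives_five_pairs(self):
        cfg = _flat_config(metabolic_fraction=0.25,  # exactly the 5 planted
                           planted_pathways=(("PWX", 5, 1.0),))
        ds = generate(cfg)
        assert len(ds.pathways.pairs) == 5
        assert set(ds.pathways.pairs["pathway_id"]) == {"PWX"}

    def test_overlap_config_yields_multi_membership(self, small_dataset):
        counts = small_dataset.pathways.membership_counts()
        assert (counts >= 2).any()

    def test_nonmetabolic_proteins_have_no_membership(self, small_dataset):
        metab = small_dataset.pathways.metabolic_proteins
        truth = set(small_dataset.manifest["proteins"]["metabolic"])
        assert metab == truth

    def test_planted_pathway_larger_than_budget_fails(self):
        with pytest.raises(GenerationError):
            generate(_flat_config(metabolic_fraction=0.1,
                                  planted_pathways=(("PWX", 50, 1.0),)))


class TestReactionNetwork:
    def test_planted_branch_has_requested_out_degree(self, small_dataset):
        net = small_dataset.network
        for mid, truth in small_dataset.manifest["branches"].items():
            consuming = [
                rid for rid in net.reaction_ids if mid in net.reactants_of(rid)
            ]
            assert sorted(consuming) == sorted(truth["reactions"])

    def test_target_bd2_zero_gives_equal_top_means(self):
        cfg = _flat_config(planted_branches=(("BZ", 2, 0.0),), n_reactions=6)
        ds = generate(cfg)
        e1, e2 = ds.manifest["branches"]["BZ"]["enzymes"]
        means = ds.cpc.mean_cpc()
        assert means[e1] == pytest.approx(means[e2])

    def test_target_bd2_one_is_epsilon_floored(self):
        ds = generate(_flat_config(planted_branches=(("BX", 2, 1.0),), n_reactions=6))
        truth = ds.manifest["branches"]["BX"]
        assert truth["epsilon_floored"]
        assert truth["realized_bd2"] > 0.999

    def test_realized_bd2_matches_target_exactly(self, small_dataset):
        means = small_dataset.cpc.mean_cpc()
        for mid, truth in small_dataset.manifest["branches"].items():
            ranked = sorted(
                (means[e] for e in truth["enzymes"]), reverse=True)
            realized = (ranked[0] - ranked[1]) / ranked[0]
            assert realized == pytest.approx(truth["target_bd2"], abs=0.02)

    def test_branch_enumeration_equals_manifest(self, small_dataset):
        # brute force over the emitted stoichiometry triples
        s = small_dataset.network.stoichiometry
        consumed = s[s["coefficient"] < 0].groupby("metabolite_id")["reaction_id"].nunique()
        found = set(consumed[consumed >= 2].index)
        planted = set(small_dataset.manifest["branches"])
        incidental = set(small_dataset.manifest["incidental_branches"])
        assert found == planted | incidental

    def test_every_reaction_enzyme_is_in_the_matrix(self, small_dataset):
        proteins = set(small_dataset.cpc.values.index)
        for rid in small_dataset.network.reaction_ids:
            for e in small_dataset.network.enzymes_of(rid):
                assert e in proteins


class TestKineticTables:
    def test_zero_noise_recovers_true_km_exactly(self):
        cfg = _flat_config(kinetics_noise=KineticsNoise(
            n_replicates=3, scatter=0.0, outlier_rate=0.0, mutant_rate=0.0))
        ds = generate(cfg)
        for enz, grp in ds.km_table.groupby("enzyme_id"):
            assert np.allclose(grp["km_value"], ds.manifest["kinetics"]["true_km"][enz])

    def test_mutant_rate_one_flags_every_record(self):
        cfg = _flat_config(kinetics_noise=KineticsNoise(mutant_rate=1.0))
        ds = generate(cfg)
        assert (ds.km_table["wildtype"] == 0).all()

    def test_scatter_gmean_of_clean_records_near_truth(self):
        cfg = _flat_config(kinetics_noise=KineticsNoise(
            n_replicates=8, scatter=0.1, outlier_rate=0.0, mutant_rate=0.0))
        ds = generate(cfg)
        for enz, grp in ds.km_table.groupby("enzyme_id"):
            logs = np.log10(grp.loc[grp["wildtype"] == 1, "km_value"])
            truth = np.log10(ds.manifest["kinetics"]["true_km"][enz])
            assert abs(logs.mean() - truth) < 0.2  # ~5 SE at scatter 0.1, n 8

    def test_thermo_covers_every_reaction(self, small_dataset):
        assert set(small_dataset.thermo["reaction_id"]) == set(
            small_dataset.network.reaction_ids)


class TestManifest:
    def test_manifest_is_json_serializable(self, small_dataset):
        json.dumps(small_dataset.manifest)

    def test_metabolic_fraction_recomputable_from_files(self, tmp_path, small_dataset):
        small_dataset.write(tmp_path)
        cpc = pd.read_csv(tmp_path / "cpc_matrix.tsv", sep="\t", index_col=0)
        tissues = pd.read_csv(tmp_path / "tissues.tsv", sep="\t")
        pmap = pd.read_csv(tmp_path / "pathway_map.tsv", sep="\t")
        tissue_of = dict(zip(tissues["cell_line"], tissues["tissue"]))
        det = cpc.notna() & (cpc > 0)
        keep = []
        for p in cpc.index:
            lines = [c for c in cpc.columns if det.loc[p, c]]
            if len(lines) >= 2 and len({tissue_of[c] for c in lines}) >= 2:
                keep.append(p)
        mean_cpc = cpc.loc[keep].fillna(0.0).mean(axis=1)
        metab = mean_cpc.index.isin(set(pmap["protein_id"]))
        frac = 100.0 * mean_cpc[metab].sum() / mean_cpc.sum()
        assert frac == pytest.approx(small_dataset.manifest["metabolic_fraction_pct"],
                                     abs=1e-9)
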
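"""Two-allele demethylation simulator: truth layer, bulk, clones, noise, UMIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epiclone as ec
from epiclone import ParameterError, SimParams
from epiclone.simulate import InputError


def two_allele_probs(p):
    """Exact enumeration of the four allele outcomes of one cell-locus."""
    return {1.0: p * p, 0.5: 2 * p * (1 - p), 0.0: (1 - p) ** 2}


class TestSimulatePopulation:
    @pytest.mark.parametrize("p, expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_degenerate_probabilities(self, small_params, p, expected):
        pop = ec.simulate_population(small_params.with_(p_demeth=p))
        silenced = pop.fractions[pop.silenced_loci].to_numpy()
        assert np.all(silenced == expected)

    def test_entries_only_from_allele_fractions(self, small_params):
        pop = ec.simulate_population(small_params)
        assert set(np.unique(pop.fractions.to_numpy())) <= {0.0, 0.5, 1.0}

    def test_background_loci_fully_demethylated(self, small_params):
        pop = ec.simulate_population(small_params)
        assert np.all(pop.fractions[pop.background_loci].to_numpy() == 1.0)

    def test_mock_population_untouched(self, small_params):
        pop = ec.simulate_population(small_params, kind="mock")
        assert np.all(pop.fractions[pop.silenced_loci].to_numpy() == 0.0)

    def test_two_allele_fractions_match_enumeration(self):
        # frozen oracle: p=0.3 -> P(complete)=0.09, P(half)=0.42, P(none)=0.49
        p = 0.3
        params = SimParams(n_loci=50, n_background_loci=1, n_cells=10_000,
                           n_clones=1, p_demeth=p, seed=11)
        pop = ec.simulate_population(params)
        vals = pop.fractions[pop.silenced_loci].to_numpy()
        n = vals.size
        for frac, prob in two_allele_probs(p).items():
            observed = np.mean(vals == frac)
            se = np.sqrt(prob * (1 - prob) / n)
            assert abs(observed - prob) < 3 * se

    def test_reproducible_under_seed(self, small_params):
        a = ec.simulate_population(small_params)
        b = ec.simulate_population(small_params)
        pd.testing.assert_frame_equal(a.fractions, b.fractions)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterError):
            SimParams(p_demeth=1.5)

    @settings(max_examples=20, deadline=None)
    @given(p=st.floats(0.0, 1.0), seed=st.integers(0, 2**20))
    def test_entries_always_valid_fractions(self, p, seed):
        params = SimParams(n_loci=5, n_background_loci=2, n_cells=8, n_clones=2,
                           p_demeth=p, seed=seed)
        pop = ec.simulate_population(params)
        assert set(np.unique(pop.fractions.to_numpy())) <= {0.0, 0.5, 1.0}


class TestDeriveBulkAndClones:
    def test_single_cell_bulk_inverts_fraction(self, small_params):
        pop = ec.simulate_population(small_params.with_(n_cells=1, n_clones=1, p_demeth=1.0))
        bulk = ec.derive_bulk(pop)
        assert np.all(bulk.betas[pop.silenced_loci] == 0.0)

    def test_two_cell_average(self):
        frame = pd.DataFrame({"L": [0.0, 1.0]}, index=["c1", "c2"])
        pop = ec.CellMethylome(frame, ["L"], [])
        assert ec.derive_bulk(pop).betas["L"] == 0.5

    def test_bulk_beta_near_one_minus_p(self):
        # E[beta] = 1 - p; binomial SE of the per-locus mean over n cells
        p, n = 0.3, 10_000
        params = SimParams(n_loci=30, n_background_loci=1, n_cells=n,
                           n_clones=1, p_demeth=p, seed=3)
        bulk = ec.derive_bulk(ec.simulate_population(params))
        silenced = bulk.betas[[l for l in bulk.betas.index if not l.startswith("BG")]]
        assert ((silenced > 0.6) & (silenced < 0.8)).all()

    def test_empty_population_rejected(self):
        pop = ec.CellMethylome(pd.DataFrame(), [], [])
        with pytest.raises(InputError):
            ec.derive_bulk(pop)

    def test_clone_inherits_founder(self, small_params):
        pop = ec.simulate_population(small_params)
        clones = ec.derive_clones(pop, small_params)
        assert len(clones) == small_params.n_clones
        founders = [c.founder for c in clones]
        assert len(set(founders)) == len(founders)  # without replacement
        for clone in clones:
            expected = 1.0 - pop.fractions.loc[clone.founder]
            pd.testing.assert_series_equal(clone.betas, expected, check_names=False)

    def test_clone_complete_count_matches_binomial(self):
        # E[# fully demethylated loci per clone] = n_loci * p^2
        p, n_loci = 0.3, 1000
        params = SimParams(n_loci=n_loci, n_background_loci=1, n_cells=100,
                           n_clones=9, p_demeth=p, seed=5)
        pop = ec.simulate_population(params)
        clones = ec.derive_clones(pop, params)
        counts = [(c.betas[pop.silenced_loci] == 0.0).sum() for c in clones]
        expect = n_loci * p**2
        sd = np.sqrt(n_loci * p**2 * (1 - p**2))
        assert abs(np.mean(counts) - expect) < 3 * sd / np.sqrt(len(counts))

    def test_too_many_clones_rejected(self, small_params):
        pop = ec.simulate_population(small_params)
        truncated = ec.CellMethylome(
            pop.fractions.iloc[:3], pop.silenced_loci, pop.background_loci)
        with pytest.raises(InputError):
            ec.derive_clones(truncated, small_params)


class TestProbeTable:
    def test_high_concentration_recovers_truth(self, small_params):
        pop = ec.simulate_population(small_params)
        bulk = ec.derive_bulk(pop)
        table, manifest = ec.emit_probe_table(
            [bulk], small_params.with_(beta_noise_concentration=1e6)
        )
        probe_truth = np.repeat(bulk.betas.to_numpy(), small_params.probes_per_block)
        assert np.allclose(table["bulk"].to_numpy(), probe_truth, atol=5e-3)

    def test_noise_bounded_and_centered(self):
        params = SimParams(n_loci=1, n_background_loci=1, n_cells=1, n_clones=1,
                           probes_per_block=2000, beta_noise_concentration=100, seed=2)
        profile = ec.SampleBetaProfile(
            betas=pd.Series({"CDKN2A": 0.0, "BG0001": 1.0}), label="s", kind="clone")
        table, _ = ec.emit_probe_table([profile], params)
        vals = table["s"].to_numpy()
        assert np.all((vals >= 0) & (vals <= 1))
        low = table.loc[[i for i in table.index if i.startswith("CDKN2A")], "s"]
        assert abs(low.mean() - 0.0) < 0.02

    def test_manifest_classes(self, small_params):
        pop = ec.simulate_population(small_params)
        _, manifest = ec.emit_probe_table([ec.derive_bulk(pop)], small_params)
        silenced = manifest[manifest["gene"].isin(pop.silenced_loci)]
        background = manifest[manifest["gene"].isin(pop.background_loci)]
        assert (background["cgi_class"] == "open_sea").all()
        island = silenced[silenced["gene"] != "CDKN2A"]
        assert (island["region_class"] == "TSS200").all()
        assert (island["cgi_class"] == "island").all()

    def test_roundtrip_through_block_aggregation(self, small_params):
        # oracle: the truth matrix itself
        pop = ec.simulate_population(small_params)
        profiles = [ec.derive_bulk(pop)] + ec.derive_clones(pop, small_params)
        table, manifest = ec.emit_probe_table(
            profiles, small_params.with_(beta_noise_concentration=5e5))
        defs = ec.assemble_blocks(manifest)
        betas = ec.aggregate_block_beta(table, defs)
        gene_of = {b.block_id: b.gene for b in defs}
        for profile in profiles:
            truth = profile.betas
            for block_id in betas.index:
                assert betas.loc[block_id, profile.label] == pytest.approx(
                    truth[gene_of[block_id]], abs=0.01)


class TestUMISimulation:
    def _roles(self, pop):
        roles = {g: "TSG" for g in pop.silenced_loci[:3]}
        roles[pop.silenced_loci[3]] = "ERV"
        roles["IFIX"] = "ISG"
        roles["HK1"] = "background"
        return roles

    def test_zero_fraction_gives_zero_counts(self, small_params):
        pop = ec.simulate_population(small_params.with_(p_demeth=0.0))
        umis = ec.simulate_umi_matrix(pop, small_params, self._roles(pop))
        tsg_erv = [g for g, r in self._roles(pop).items() if r in ("TSG", "ERV")]
        assert (umis.counts.loc[tsg_erv].to_numpy() == 0).all()

    def test_zero_coupling_decouples_isg(self, small_params):
        pop = ec.simulate_population(small_params.with_(p_demeth=1.0))
        params0 = small_params.with_(p_demeth=1.0, isg_coupling=0.0, expr_mean=20.0)
        umis = ec.simulate_umi_matrix(pop, params0, self._roles(pop))
        isg_mean = umis.counts.loc["IFIX"].mean()
        # every cell has the ERV active; with gamma=0 the ISG mean stays expr_mean
        assert isg_mean == pytest.approx(20.0, rel=0.2)

    def test_isg_scales_with_erv_activity(self, small_params):
        roles = None
        means = {}
        for p in (0.0, 1.0):
            params = small_params.with_(p_demeth=p, isg_coupling=2.0, expr_mean=10.0,
                                        n_cells=500)
            pop = ec.simulate_population(params)
            roles = self._roles(pop)
            means[p] = ec.simulate_umi_matrix(pop, params, roles).counts.loc["IFIX"].mean()
        assert means[1.0] > 2 * means[0.0]

    def test_upregulated_fraction_increases_with_expression(self):
        # Monte-Carlo oracle at two parameter settings
        fracs = {}
        for mean in (2.0, 20.0):
            params = SimParams(n_loci=4, n_background_loci=1, n_cells=2000,
                               n_clones=1, p_demeth=0.3, expr_mean=mean, seed=13)
            pop = ec.simulate_population(params)
            umis = ec.simulate_umi_matrix(pop, params, {pop.silenced_loci[0]: "TSG"})
            frac, _ = ec.upregulated_cell_fraction(umis, pop.silenced_loci[0], 3)
            fracs[mean] = frac
        assert 0.0 < fracs[2.0] < fracs[20.0] < 1.0

    def test_unknown_role_rejected(self, small_params):
        pop = ec.simulate_population(small_params)
        with pytest.raises(InputError):
            ec.simulate_umi_matrix(pop, small_params, {pop.silenced_loci[0]: "oncogene"})


class TestParams:
    def test_yaml_roundtrip(self, tmp_path, small_params):
        path = tmp_path / "params.yaml"
        small_params.to_yaml(path)
        assert SimParams.from_yaml(path) == small_params

    @pytest.mark.parametrize("kwargs", [
        {"n_cells": 0}, {"beta_noise_concentration": -1.0},
        {"isg_coupling": -0.1}, {"n_clones": 100, "n_cells": 10},
        {"dead_multiplier": -1.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimParams(**kwargs)
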
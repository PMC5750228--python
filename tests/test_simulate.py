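"""Synthetic wet-up generator: dynamics, observation model, determinism."""

import numpy as np
import pandas as pd
import pytest

from crustlink.scenario import (MetaboliteSpec, TaxonSpec, WetupScenario,
                                default_scenario)
from crustlink.simulate import (isolate_fold_change, observe_peak_areas,
                                simulate_abundance, simulate_dataset,
                                simulate_exoprofiles, simulate_marker_reads,
                                simulate_markers, simulate_metabolites)

from conftest import flat_taxon, tiny_scenario


class TestAbundance:
    def test_flat_taxon_is_constant(self):
        scn = tiny_scenario(taxa=[flat_taxon(baseline=2.0)])
        ab = simulate_abundance(scn)
        assert (ab.loc["bug"] == 2.0).all()

    def test_early_responder_peaks_at_first_sample(self, scenario):
        ab = simulate_abundance(scenario)
        early = ab.loc["cyano_early", "A"]
        assert early[0.05] >= early[49.5]
        assert early.idxmax() == 0.05

    def test_responder_peak_order_early_mid_late(self, scenario):
        """Trajectory argmax times are ordered early < mid < late."""
        ab = simulate_abundance(scenario)
        peaks = {t: ab.loc[t, "A"].idxmax()
                 for t in ("cyano_early", "firmicute_mid", "firmicute_late")}
        assert (peaks["cyano_early"] < peaks["firmicute_mid"]
                < peaks["firmicute_late"])

    def test_succession_scaling(self, scenario):
        ab = simulate_abundance(scenario)
        spec = {t.taxon_id: t for t in scenario.taxa}["actino_flat"]
        ratio = ab.loc["actino_flat", "D"] / ab.loc["actino_flat", "A"]
        expected = spec.succession_scale["D"] / spec.succession_scale["A"]
        assert np.allclose(ratio, expected)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            tiny_scenario(time_points=(0.0, 1.0))


class TestMetabolites:
    def test_no_dynamics_when_all_rates_zero(self):
        scn = tiny_scenario(
            metabolites=[MetaboliteSpec("met", initial_pool=10.0)])
        active = simulate_metabolites(scn, killed=False)
        killed = simulate_metabolites(scn, killed=True)
        assert (active.loc["met"] == 10.0).all()
        pd.testing.assert_frame_equal(active, killed)

    def test_killed_dominates_consumption_only(self, scenario):
        """Uptake only removes mass: killed pool >= active pool."""
        active = simulate_metabolites(scenario, killed=False)
        killed = simulate_metabolites(scenario, killed=True)
        consumption_only = [
            m.metabolite_id for m in scenario.metabolites
            if m.uptake_rate and not m.release_rate
        ]
        assert consumption_only
        diff = killed.loc[consumption_only] - active.loc[consumption_only]
        assert (diff >= -1e-12).all().all()

    def test_pools_nonnegative(self, scenario):
        assert (simulate_metabolites(scenario) >= 0).all().all()

    def test_negative_step_rejected(self, scenario):
        with pytest.raises(ValueError):
            simulate_metabolites(scenario, step=-0.1)

    def test_single_consumer_matches_fine_step_oracle(self):
        """Terminal pool of a constant-biomass Monod consumer agrees
        with an independently coded dt=0.001 integration within 1%."""
        u, K, B, M0, T = 0.08, 1.0, 2.5, 5.0, 8.0
        scn = tiny_scenario(
            taxa=[flat_taxon(baseline=B)],
            metabolites=[MetaboliteSpec("met", initial_pool=M0,
                                        uptake_rate={"bug": u},
                                        half_saturation=K)],
            time_points=(1.0, T),
        )
        got = simulate_metabolites(scn).loc["met", ("A", T)]
        # independent brute-force Euler at dt = 0.001
        dt, m, t = 0.001, M0, 0.0
        while t < T - 1e-9:
            m = max(m + dt * (-u * B * m / (K + m)), 0.0)
            t += dt
        assert got == pytest.approx(m, rel=0.01)

    def test_default_step_converges_to_fine_step(self, scenario):
        """Euler at the default step tracks a 50x finer step within 1%
        relative error (1% of the initial pool as absolute floor for
        pools that decay to ~0)."""
        coarse = simulate_metabolites(scenario)
        fine = simulate_metabolites(scenario, step=scenario.euler_step / 50)
        atol = {m.metabolite_id: 0.01 * max(m.initial_pool, 1.0)
                for m in scenario.metabolites}
        for met in coarse.index:
            a = coarse.loc[met].to_numpy()
            b = fine.loc[met].to_numpy()
            assert np.allclose(a, b, rtol=0.01, atol=atol[met]), met


class TestObservation:
    def test_noise_free_areas_equal_pools(self):
        scn = tiny_scenario(noise_sigma=0.0, gain=1.0)
        pools = simulate_metabolites(scn)
        table = observe_peak_areas(pools, scn)
        for (stage, t) in pools.columns:
            cols = table.meta[(table.meta["stage"] == stage)
                              & (table.meta["time"] == t)].index
            for c in cols:
                assert np.allclose(table.areas[c], pools[(stage, t)])

    def test_detection_limit_blanks_everything(self):
        scn = tiny_scenario(detection_limit=1e9)
        table = observe_peak_areas(simulate_metabolites(scn), scn)
        assert table.areas.isna().all().all()

    def test_observation_determinism(self, scenario):
        pools = simulate_metabolites(scenario)
        t1 = observe_peak_areas(pools, scenario)
        t2 = observe_peak_areas(pools, scenario)
        pd.testing.assert_frame_equal(t1.areas, t2.areas)

    def test_dataset_determinism(self, scenario, dataset):
        again = simulate_dataset(default_scenario(seed=scenario.seed))
        pd.testing.assert_frame_equal(dataset.active.areas, again.active.areas)
        pd.testing.assert_frame_equal(dataset.marker_counts,
                                      again.marker_counts)
        assert dataset.env_markers == again.env_markers

    def test_areas_nonnegative(self, dataset):
        assert (dataset.active.areas.fillna(0) >= 0).all().all()


class TestMarkerReads:
    def test_counts_sum_to_depth(self, scenario, dataset):
        assert (dataset.marker_counts.sum(axis=0)
                == scenario.read_depth).all()

    def test_single_taxon_takes_all_reads(self):
        scn = tiny_scenario(background_abundance=0.0, read_depth=500)
        reads = simulate_marker_reads(simulate_abundance(scn), scn)
        assert (reads.loc["bug"] == 500).all()

    def test_proportions_within_three_se(self):
        taxa = [flat_taxon("t1", 1.0), flat_taxon("t2", 3.0),
                flat_taxon("t3", 6.0)]
        scn = tiny_scenario(taxa=taxa, background_abundance=0.0,
                            read_depth=100_000, time_points=(1.0,))
        reads = simulate_marker_reads(simulate_abundance(scn), scn)
        depth = scn.read_depth
        for taxon, p in zip(("t1", "t2", "t3"), (0.1, 0.3, 0.6)):
            phat = reads.loc[taxon].iloc[0] / depth
            se = np.sqrt(p * (1 - p) / depth)
            assert abs(phat - p) <= 3 * se

    def test_all_zero_abundance_rejected(self):
        scn = tiny_scenario(taxa=[flat_taxon(baseline=0.0)],
                            background_abundance=0.0)
        with pytest.raises(ValueError, match="all-zero"):
            simulate_marker_reads(simulate_abundance(scn), scn)


class TestExoprofiles:
    def test_inert_pair_has_unit_fold_change(self):
        scn = tiny_scenario()
        spent = simulate_exoprofiles(scn, noise=False)
        assert spent["fold_change"].iloc[0] == pytest.approx(1.0)
        assert spent["true_class"].iloc[0] == "unchanged"

    def test_fold_change_closed_form(self):
        """fc = exp(-u c_b T) (1 + r c_b T / M0), evaluated by hand."""
        scn = tiny_scenario(
            metabolites=[MetaboliteSpec("met", initial_pool=2.0,
                                        uptake_rate={"bug": 0.05},
                                        release_rate={"bug": 0.1})],
            culture_biomass=3.0, culture_hours=24.0,
        )
        got = isolate_fold_change(0.05, 0.1, 2.0, scn)
        hand = np.exp(-0.05 * 72) * (1 + 0.1 * 72 / 2.0)
        assert got == pytest.approx(hand)
        spent = simulate_exoprofiles(scn, noise=False)
        assert spent["fold_change"].iloc[0] == pytest.approx(hand)

    def test_release_into_empty_pool_rejected(self):
        scn = tiny_scenario()
        with pytest.raises(ValueError):
            isolate_fold_change(0.0, 0.5, 0.0, scn)

    def test_zero_divergence_keeps_marker_identical(self):
        scn = tiny_scenario(isolate_divergence=0.0)
        env, iso = simulate_markers(scn)
        assert iso["iso-bug"] == env["bug"]

    def test_divergence_changes_expected_fraction_of_sites(self, scenario):
        env, iso = simulate_markers(scenario)
        for tid, seq in env.items():
            diff = sum(a != b for a, b in zip(seq, iso[f"iso-{tid}"]))
            frac = diff / len(seq)
            # binomial(450, 0.10): +-4 SD
            assert abs(frac - 0.10) < 4 * np.sqrt(0.1 * 0.9 / len(seq))


class TestScenarioValidation:
    def test_flat_taxon_needs_zero_amplitude(self):
        with pytest.raises(ValueError, match="amplitude 0"):
            TaxonSpec("x", "flat", 1.0, 1.0, 1.0, 2.0, {"A": 1})

    def test_time_points_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            tiny_scenario(time_points=(2.0, 1.0))

    def test_rate_must_reference_known_taxon(self):
        with pytest.raises(ValueError, match="unknown taxon"):
            tiny_scenario(metabolites=[
                MetaboliteSpec("met", 1.0, uptake_rate={"ghost": 0.1})])

    def test_default_design_has_100_active_samples(self, dataset):
        assert dataset.active.n_samples == 100
        assert dataset.killed.n_samples == 15  # 5 time points x 3 reps

    def test_yaml_round_trip(self, scenario, tmp_path):
        path = tmp_path / "scn.yaml"
        scenario.to_yaml(path)
        back = type(scenario).from_yaml(path)
        assert back.to_dict() == scenario.to_dict()
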
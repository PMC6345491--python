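import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

import wetlandbirds as wb
from wetlandbirds.io_data import ModelSpec
from wetlandbirds.synthetic_data import (
    CATEGORY_PROPORTIONS, SIZE_RANGE, SURVEY_RANGES, SimulationScenario,
    simulate_covariates, simulate_richness, simulate_species, simulate_study,
    true_coefficient_vectors,
)

from conftest import make_intercept_only_study


class TestSimulateCovariates:
    def test_default_design_envelope(self, small_study):
        w = small_study.wetlands
        assert len(w) == 33
        assert (w["type"] == "ACEP").sum() == 20
        assert w["size"].between(*SIZE_RANGE).all()
        assert w["n_points"].between(1, 9).all()
        sc = small_study.site_covariates.data
        assert set(sc["year"]) == {"1", "2"}
        vc = small_study.survey_covariates.data
        for name, (a, b) in SURVEY_RANGES.items():
            assert vc[name].between(a, b).all()

    def test_reproducible_given_seed(self):
        s = SimulationScenario(seed=5)
        a = simulate_covariates(s)
        b = simulate_covariates(s)
        pd.testing.assert_frame_equal(a[0].data, b[0].data)
        pd.testing.assert_frame_equal(a[1].data, b[1].data)

    def test_category_proportions_at_large_n(self):
        # ~9600 point-years: binomial SE of a proportion is under 0.005
        scenario = SimulationScenario(n_acep=600, n_reference=600, seed=8)
        sc, vc, _ = simulate_covariates(scenario)
        shrub1 = sc.data["shrub1"].value_counts(normalize=True)
        assert shrub1["0-50"] == pytest.approx(0.77, abs=0.02)
        assert shrub1["51-100"] == pytest.approx(0.23, abs=0.02)
        herb = sc.data["herb"].value_counts(normalize=True)
        for level, prop in zip(("0-25", "26-75", "76-100"),
                               CATEGORY_PROPORTIONS["herb"]):
            assert herb[level] == pytest.approx(prop, abs=0.02)
        sky = vc.data["sky"].value_counts(normalize=True)
        assert sky["0-1"] == pytest.approx(0.56, abs=0.02)

    def test_mean_points_per_wetland(self):
        scenario = SimulationScenario(n_acep=500, n_reference=500, seed=9)
        _, _, w = simulate_covariates(scenario)
        assert w["n_points"].mean() == pytest.approx(4.0, abs=0.15)


class TestSimulateDetections:
    def test_saturation_all_ones_and_all_zeros(self):
        scenario = SimulationScenario(n_acep=3, n_reference=3, seed=1)
        sc, vc, _ = simulate_covariates(scenario)
        spec = ModelSpec([], [], species="sosp")
        det, z, _ = wb.simulate_detections(sc, vc, [40.0], [40.0], seed=2,
                                           spec=spec)
        assert (det.y == 1).all() and (z == 1).all()
        det, z, _ = wb.simulate_detections(sc, vc, [-40.0], [40.0], seed=2,
                                           spec=spec)
        assert (det.y == 0).all() and (z == 0).all()

    def test_unoccupied_sites_have_empty_histories(self, small_study):
        for sp, det in small_study.detections.items():
            z = small_study.latent_z[sp]
            assert det.y[z == 0].sum() == 0

    def test_naive_occupancy_matches_closed_form(self):
        # E[naive] = psi * (1 - (1 - p)^J) = 0.6 * 0.91 = 0.546 at J = 2
        det, _, _, _, _ = make_intercept_only_study(10_000, 0.6, 0.7, seed=13)
        n = det.n_sites
        expected = 0.6 * (1 - 0.3 ** 2)
        se = np.sqrt(expected * (1 - expected) / n)
        assert det.naive_occupancy() == pytest.approx(expected, abs=3 * se)

    def test_effect_expansion(self, small_study):
        det = small_study.detections["sosp"]
        sc, vc = small_study.site_covariates, small_study.survey_covariates
        design = wb.build_design(det, sc, vc, wb.global_spec("sosp"))
        truth = small_study.scenario.species_truth["deju"]
        alpha, beta = true_coefficient_vectors(truth, design)
        assert alpha[0] == truth.occ_intercept
        assert alpha[design.x_blocks["size"][0]] == -1.6
        assert beta[design.w_blocks["time"][0]] == 0.8
        assert alpha[design.x_blocks["herb"]].tolist() == [0.0, 0.0]


class TestSimulateRichness:
    def _wetlands(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "wetland_id": [f"W{i}" for i in range(n)],
            "type": rng.choice(["ACEP", "reference"], n),
            "size": np.exp(rng.uniform(np.log(0.28), np.log(32.4), n)),
        })

    def test_intercept_only_mean(self):
        coef = {"intercept": np.log(10.0), "type": 0.0, "size": 0.0,
                "year": 0.0}
        rt = simulate_richness(self._wetlands(1000), coef, seed=3)
        assert rt.data["richness"].mean() == pytest.approx(10.0, abs=0.4)

    def test_poisson_dispersion_near_one(self):
        coef = {"intercept": np.log(10.0), "type": 0.0, "size": 0.0,
                "year": 0.0}
        rt = simulate_richness(self._wetlands(5000), coef, seed=4)
        counts = rt.data["richness"].to_numpy(float)
        dispersion = counts.var(ddof=1) / counts.mean()
        assert 0.9 <= dispersion <= 1.1

    def test_reproducible(self):
        w = self._wetlands(20)
        coef = {"intercept": 2.0, "type": -0.05, "size": 0.2, "year": -0.08}
        a = simulate_richness(w, coef, seed=5)
        b = simulate_richness(w, coef, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestFullLoopRecovery:
    def test_reduction_recovers_true_covariate_structure(self):
        """simulate -> global fit -> reduce: strong true effects (|1.5|) are
        retained in >= 80% of replicates; null covariates are dropped at a
        rate consistent with the 50%-interval rule (about half the time)."""
        from wetlandbirds.mcmc_inference import MCMCConfig
        from wetlandbirds.synthetic_data import SpeciesTruth

        spec = ModelSpec(["size", "type", "water"], ["wind", "sky"],
                         species="sosp")
        truth = SpeciesTruth(0.3, {"size": 1.5, "water": 1.5}, 0.4,
                             {"wind": -1.5})
        n_rep = 8
        kept_signal, dropped_null = [], []
        for rep in range(n_rep):
            scenario = SimulationScenario(n_acep=25, n_reference=25,
                                          seed=100 + rep)
            sc, vc, _ = simulate_covariates(scenario)
            det, z, design = simulate_species(sc, vc, truth, seed=200 + rep,
                                              spec=spec)
            cfg = MCMCConfig(n_chains=2, n_iterations=1500, n_burnin=500,
                             thin=5, seed=300 + rep)
            fit = wb.fit_occupancy(det, sc, vc, spec, cfg)
            reduced = wb.reduce_model(fit)
            kept = set(reduced.occupancy_covariates) | \
                {f"det:{c}" for c in reduced.detection_covariates}
            kept_signal.append({"size", "water", "det:wind"} <= kept)
            dropped_null.append("type" not in kept)
            dropped_null.append("det:sky" not in kept)
        assert np.mean(kept_signal) >= 0.8
        assert np.mean(dropped_null) >= 0.3


def test_study_reproducible_end_to_end():
    a = simulate_study(SimulationScenario(seed=77))
    b = simulate_study(SimulationScenario(seed=77))
    for sp in a.detections:
        np.testing.assert_array_equal(a.detections[sp].y, b.detections[sp].y)
    pd.testing.assert_frame_equal(a.richness.data, b.richness.data)
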
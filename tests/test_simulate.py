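"""Synthetic-trial generator: determinism, calibration, and couplings."""

import numpy as np
import pytest

from hempkite.growth import fit_growth
from hempkite.quantgen import HalfSibFamilyModel
from hempkite.regression import fit_loglog
from hempkite.simulate import (
    TrialConfig,
    grid_layout,
    simulate_growth,
    simulate_scene,
    simulate_trial,
)


class TestConfig:
    def test_roundtrip(self):
        cfg = TrialConfig(master_seed=9, h2={"DIA": 0.5})
        back = TrialConfig.from_dict(cfg.to_dict())
        assert back == cfg

    @pytest.mark.parametrize("kw", [
        dict(n_families=0),
        dict(allometry_r2=0.0),
        dict(h2={"DIA": 1.5}),
        dict(chemotype_probs={"CBD-dominant": 0.5}),
    ])
    def test_invalid_rejected_before_sampling(self, kw):
        with pytest.raises(ValueError):
            simulate_trial(TrialConfig(**kw))


class TestTrial:
    def test_deterministic_under_seed(self):
        d1, _ = simulate_trial(seed=4)
        d2, _ = simulate_trial(seed=4)
        assert d1.equals(d2)
        d3, _ = simulate_trial(seed=5)
        assert not d1.equals(d3)

    def test_shape_and_columns(self, trial_df):
        assert len(trial_df) == 23 * 15
        assert trial_df["family"].nunique() == 23
        for col in ("HT", "MCD", "MCDH", "TRKL", "DIA", "WBM", "DSBM",
                    "PTFD", "SPA", "LI", "CB_yield"):
            assert col in trial_df.columns

    def test_population_means_near_study_values(self):
        """Sanity envelope: generated means land within ±15% of the trial's
        reported population means for the key size traits."""
        means = {"HT": [], "MCD": [], "DIA": [], "WBM": []}
        for s in range(5):
            df, _ = simulate_trial(seed=100 + s)
            for k in means:
                means[k].append(df[k].mean())
        for k, want in {"HT": 157.7, "MCD": 125.9, "DIA": 4.44,
                        "WBM": 6.31}.items():
            assert np.mean(means[k]) == pytest.approx(want, rel=0.15)

    def test_kite_preconditions_hold(self, trial_df):
        assert (trial_df["TRKL"] < trial_df["MCDH"]).all()
        assert (trial_df["MCDH"] < trial_df["HT"]).all()

    def test_flowering_segregation_patterns(self, trial_df, trial):
        _, truth = trial
        early_frac = (
            trial_df.assign(e=trial_df["genotype"] == "ee")
            .groupby("family")["e"].mean()
        )
        crosses = dict(zip(sorted(trial_df["family"].unique()),
                           truth.family_crosses))
        for fam, frac in early_frac.items():
            s, p = crosses[fam]
            if (s, p) == ("ee", "ee"):
                assert frac == 1.0
            elif (s, p) == ("EE", "Ee"):
                assert frac == 0.0

    def test_leaflet_number_tracks_flowering_class(self, trial_df):
        g = trial_df.groupby("flowering_class")["LFLTN"].mean()
        assert g["early"] < g["mid"] < g["late"]
        assert g["early"] == pytest.approx(3.9, abs=0.7)
        assert g["late"] == pytest.approx(6.3, abs=0.7)

    def test_allometry_recovery_height(self):
        slopes = [fit_loglog(*simulate_trial(seed=300 + s)[0][["DIA", "HT"]]
                             .to_numpy().T).slope for s in range(25)]
        assert np.mean(slopes) == pytest.approx(0.65, abs=0.05)

    def test_foliar_allometry_recovery(self):
        slopes = []
        for s in range(25):
            df, _ = simulate_trial(seed=400 + s)
            slopes.append(fit_loglog(df["LI"], df["LFDW"]).slope)
        assert np.mean(slopes) == pytest.approx(-0.71, abs=0.06)

    def test_h2_recovery_at_configured_value(self):
        cfg = TrialConfig(h2={"DIA": 0.5})
        est = []
        for s in range(60):
            df, _ = simulate_trial(cfg, seed=600 + s)
            est.append(HalfSibFamilyModel(
                np.log10(df["DIA"]), df["family"]).fit().h2_uncapped)
        assert np.mean(est) == pytest.approx(0.5, abs=0.08)

    def test_disease_coupled_to_flowering(self):
        rs = []
        for s in range(5):
            df, _ = simulate_trial(seed=700 + s)
            aud = (df["PM71"] + df["PM86"]) / 2 * 15 + (df["PM86"] + df["PM97"]) / 2 * 11
            rs.append(np.corrcoef(aud, df["PTFD"])[0, 1])
        assert np.mean(rs) == pytest.approx(-0.54, abs=0.15)

    def test_totals_consistent_with_acid_neutral_split(self, trial_df):
        recomputed = (trial_df["CBD_neutral"]
                      + 0.877 * trial_df["CBDA_acid"])
        np.testing.assert_allclose(recomputed, trial_df["CBD_total"], rtol=1e-9)


class TestGrowth:
    def test_noise_free_logistic_recovery(self, trial):
        df, truth = trial
        series = simulate_growth(df.head(8), truth, noise_sd=0.0, seed=0)
        for pid, s in series.items():
            fit = fit_growth(s, restrict_loglinear=False)
            K = df.set_index("plant").loc[pid, "HT"]
            # analytic logistic maximum is rK/4 with r near 0.10
            assert fit.max_rate == pytest.approx(0.10 * K / 4, rel=0.25)

    def test_day_of_max_growth_correlates_with_flowering(self):
        rs = []
        for s in range(3):
            df, truth = simulate_trial(seed=800 + s)
            series = simulate_growth(df, truth, seed=s)
            dmg = [fit_growth(series[p], restrict_loglinear=False).day_of_max
                   for p in df["plant"]]
            rs.append(np.corrcoef(dmg, df["PTFD"])[0, 1])
        assert np.mean(rs) > 0.2

    def test_late_flowering_plants_taller(self, trial_df):
        late = trial_df[trial_df["flowering_class"] == "late"]["HT"].mean()
        early = trial_df[trial_df["flowering_class"] == "early"]["HT"].mean()
        assert late > early


class TestScene:
    def test_empty_layout_bare_ground(self):
        scene, truth = simulate_scene(np.empty((0, 2)), np.empty(0), seed=0)
        assert scene.rgb.shape[2] == 3 and scene.msp.shape[2] == 5
        assert truth["centers"].size == 0

    def test_grid_layout_spacing(self):
        g = grid_layout(3, 4)
        assert g.shape == (12, 2)
        assert g[:, 0].max() == pytest.approx(2 * 1.83)
        assert g[:, 1].max() == pytest.approx(3 * 1.22)

    def test_truth_matches_inputs(self):
        centers = grid_layout(2, 3)
        heights = np.full(6, 1.2)
        scene, truth = simulate_scene(centers, heights, seed=1)
        np.testing.assert_allclose(truth["centers"], centers)
        np.testing.assert_allclose(truth["heights"], heights)
        assert scene.cloud.shape[1] == 6
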
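import numpy as np
import pandas as pd
import pytest

import bequiv as bq
from bequiv.simulate import replicate_abe_cmax, simulate_profiles


@pytest.fixture
def params():
    return bq.PKModelParams(ka_per_h=1.0, t_half_h=30.0, V_L=25.0, dose_mg=200.0)


def noiseless(gmr=1.0, seed=0, n=4, period_effect=1.0):
    params = bq.PKModelParams(ka_per_h=1.0, t_half_h=30.0, V_L=25.0, dose_mg=200.0,
                              gmr_true=gmr)
    var = bq.VariabilitySpec(bsv_cv={}, wsv_cv={}, period_effect=period_effect, seed=seed)
    design = bq.DesignSpec(n_subjects=n, lloq_ng_ml=1.0)
    return params, var, design


class TestConcentrationCurve:
    def test_zero_at_dosing_and_nonnegative(self, params):
        t = np.linspace(0, 72, 500)
        c = bq.concentration_curve(params, t)
        assert c[0] == 0.0
        assert (c >= 0).all()

    def test_peak_time_matches_closed_form(self, params):
        t = np.linspace(0, 24, 200001)
        c = bq.concentration_curve(params, t)
        t_star = np.log(params.ka_per_h / params.ke_per_h) / (params.ka_per_h - params.ke_per_h)
        assert t[np.argmax(c)] == pytest.approx(t_star, abs=1e-3)
        assert params.tmax_h == pytest.approx(t_star)

    def test_linear_in_bioavailability(self, params):
        t = np.array([0.5, 2.0, 8.0, 48.0])
        half = bq.PKModelParams(ka_per_h=1.0, t_half_h=30.0, V_L=25.0, dose_mg=200.0,
                                F_ref=0.5)
        np.testing.assert_allclose(bq.concentration_curve(params, t),
                                   2 * bq.concentration_curve(half, t))

    def test_equal_rates_refused(self):
        with pytest.raises(bq.ParameterError):
            bq.PKModelParams(ka_per_h=np.log(2) / 30.0, t_half_h=30.0, V_L=25.0, dose_mg=200.0)

    def test_negative_time_refused(self, params):
        with pytest.raises(bq.ParameterError):
            bq.concentration_curve(params, [-1.0])


class TestSimulateStudy:
    def test_no_noise_no_effect_gives_identical_profiles_and_gmr_100(self):
        study = bq.simulate_study(*noiseless())
        wide = study.records.pivot_table(index=["subject", "period"], columns="time_h",
                                         values="conc_ng_ml")
        assert (wide.nunique(axis=0) <= 1).all()
        result = bq.run_abe(bq.run_nca(study), "cmax")
        assert result.gmr_pct == pytest.approx(100.0, abs=1e-9)
        assert result.mse == pytest.approx(0.0, abs=1e-12)

    def test_no_noise_gmr_scales_test_concentrations(self):
        study = bq.simulate_study(*noiseless(gmr=1.05))
        rec = study.records.dropna(subset=["conc_ng_ml"])
        wide = rec.pivot_table(index="time_h", columns="formulation", values="conc_ng_ml")
        wide = wide.dropna()
        np.testing.assert_allclose(wide["Test"], 1.05 * wide["Reference"], rtol=1e-12)

    def test_concentrations_below_lloq_are_flagged_blq(self):
        params, var, _ = noiseless()
        design = bq.DesignSpec(n_subjects=4, lloq_ng_ml=50.0)
        study = bq.simulate_study(params, var, design)
        # raw (uncensored) curve lets us find which samples must be censored
        raw = bq.concentration_curve(params, np.array(design.nominal_times_h))
        low = raw < 50.0
        assert low.any()
        for t, is_low in zip(design.nominal_times_h, low):
            rows = study.records[study.records["time_h"] == t]
            assert (rows["blq"] == is_low).all()
            if is_low:
                assert rows["conc_ng_ml"].isna().all()

    def test_seed_reproducibility(self):
        params, var, design = bq.preset("pazopanib_200", seed=99)
        a = bq.simulate_study(params, var, design)
        b = bq.simulate_study(params, var, design)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_odd_subject_count_rejected(self):
        with pytest.raises(bq.DesignError):
            bq.DesignSpec(n_subjects=23)

    def test_sequences_balanced(self, pilot_study):
        per_seq = pilot_study.records.groupby("sequence")["subject"].nunique()
        assert per_seq["TR"] == per_seq["RT"] == 12

    def test_period_effect_multiplies_period_two(self):
        base = bq.simulate_study(*noiseless())
        shifted = bq.simulate_study(*noiseless(period_effect=1.1))
        for study in (base, shifted):
            study.records["conc_ng_ml"] = study.records["conc_ng_ml"].fillna(0)
        b = base.records.set_index(["subject", "period", "time_h"])["conc_ng_ml"]
        s = shifted.records.set_index(["subject", "period", "time_h"])["conc_ng_ml"]
        ratio = (s / b).dropna()
        p2 = ratio.index.get_level_values("period") == 2
        assert np.allclose(ratio[p2], 1.1) and np.allclose(ratio[~p2], 1.0)


class TestPresets:
    def test_validation_preset_matches_short_half_life_regime(self):
        params, _, _ = bq.preset("validation")
        assert params.ke_per_h == pytest.approx(np.log(2) / 4.6)
        assert params.V_L == 60.0

    def test_pazopanib_400_pilot_design(self):
        params, _, design = bq.preset("pazopanib_400")
        assert design.n_subjects == 24
        assert len(design.nominal_times_h) == 20
        assert params.dose_mg == 400.0
        assert design.lloq_ng_ml == 100.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            bq.preset("nope")

    def test_pazopanib_median_tmax_in_plausible_window(self):
        params, var, design = bq.preset("pazopanib_200", n_subjects=1000, seed=11)
        rng = np.random.default_rng(11)
        _, conc = simulate_profiles(params, var, design, rng)
        t = np.asarray(design.nominal_times_h)
        tmax = t[conc.argmax(axis=2)]
        assert 2.0 <= np.median(tmax) <= 8.0


class TestStatisticalStructure:
    def test_geometric_mean_ratio_converges_to_true_gmr(self, rng):
        params, var, design = bq.preset("pazopanib_200", n_subjects=1000, iscv=0.5,
                                        gmr_true=1.05)
        seqs, conc = simulate_profiles(params, var, design, rng)
        cmax = conc.max(axis=2)
        test = np.where(seqs == "TR", cmax[:, 0], cmax[:, 1])
        ref = np.where(seqs == "TR", cmax[:, 1], cmax[:, 0])
        gm = np.exp(np.mean(np.log(test / ref)))
        # MC error ~ sqrt(2*ln(1.25)/1000) ~ 2% on the ln scale
        assert gm == pytest.approx(1.05, rel=0.05)

    def test_replicate_driver_cmax_matches_nca(self):
        params, var, design = bq.preset("pazopanib_200", seed=5)
        study = bq.simulate_study(params, var, design)
        nca = bq.run_nca(study).sort_values(["subject_id", "period"])
        rng = np.random.default_rng(var.seed)
        _, conc = simulate_profiles(params, var, design, rng)
        fast = np.sort(conc.max(axis=2).ravel())
        slow = np.sort(nca["cmax_ng_ml"].to_numpy())
        np.testing.assert_allclose(fast, slow, rtol=1e-12)
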
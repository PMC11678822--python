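import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bequiv as bq
from bequiv.abe import fit_crossover


def crossover_oracle(values, sequence, subject, period, alpha=0.05):
    """Closed-form 2x2 crossover estimator, independent of the design-matrix fit.

    With within-subject ln-differences D_i = ln y_{i,P1} - ln y_{i,P2}, the
    formulation effect is (Dbar_TR - Dbar_RT)/2, its variance
    s_D^2/4*(1/n1+1/n2) with s_D^2 the pooled variance of D (equal to twice
    the ANOVA residual mean square).
    """
    df = pd.DataFrame({"y": np.log(values), "seq": sequence, "subj": subject, "per": period})
    wide = df.pivot_table(index=["subj", "seq"], columns="per", values="y").reset_index("seq")
    d = wide[1] - wide[2]
    d_tr, d_rt = d[wide["seq"] == "TR"], d[wide["seq"] == "RT"]
    n1, n2 = len(d_tr), len(d_rt)
    est = (d_tr.mean() - d_rt.mean()) / 2
    pooled = ((d_tr - d_tr.mean()) ** 2).sum() + ((d_rt - d_rt.mean()) ** 2).sum()
    df_resid = n1 + n2 - 2
    s2_d = pooled / df_resid
    mse = s2_d / 2
    se = np.sqrt(s2_d / 4 * (1 / n1 + 1 / n2))
    tcrit = stats.t.ppf(1 - alpha, df_resid)
    # grand marginal mean: sequences weighted equally
    mu = (wide[wide["seq"] == "TR"][[1, 2]].to_numpy().mean()
          + wide[wide["seq"] == "RT"][[1, 2]].to_numpy().mean()) / 2
    return {"est": est, "mse": mse, "se": se, "df": df_resid, "mu": mu,
            "ci": (est - tcrit * se, est + tcrit * se)}


def random_crossover(rng, n_tr=5, n_rt=4):
    subj, seq, per, form, vals = [], [], [], [], []
    for i in range(n_tr + n_rt):
        s = "TR" if i < n_tr else "RT"
        for p in (1, 2):
            subj.append(f"S{i}")
            seq.append(s)
            per.append(p)
            form.append(bq.io.formulation_for(s, p))
            vals.append(float(np.exp(rng.normal(7, 0.5))))
    return np.array(vals), np.array(seq), np.array(subj), np.array(per), np.array(form)


class TestFitAgainstOracle:
    def test_matches_closed_form_on_random_datasets(self, rng):
        for _ in range(25):
            vals, seq, subj, per, form = random_crossover(
                rng, n_tr=int(rng.integers(3, 8)), n_rt=int(rng.integers(3, 8)))
            fit = fit_crossover(vals, seq, subj, per, form)
            ora = crossover_oracle(vals, seq, subj, per)
            assert fit["estimate_ln"] == pytest.approx(ora["est"], rel=1e-9, abs=1e-12)
            assert fit["mse"] == pytest.approx(ora["mse"], rel=1e-9, abs=1e-12)
            assert fit["se_ln"] == pytest.approx(ora["se"], rel=1e-9, abs=1e-12)
            assert fit["df_resid"] == ora["df"]
            assert fit["mu_ln"] == pytest.approx(ora["mu"], rel=1e-9)
            assert fit["ci_ln"][0] == pytest.approx(ora["ci"][0], rel=1e-9, abs=1e-12)
            assert fit["ci_ln"][1] == pytest.approx(ora["ci"][1], rel=1e-9, abs=1e-12)

    def test_matches_statsmodels_ols_on_same_design(self, rng):
        import statsmodels.api as sm

        from bequiv.abe import _design_matrix

        vals, seq, subj, per, form = random_crossover(rng)
        X, groups = _design_matrix(seq, subj, per, form)
        res = sm.OLS(np.log(vals), X).fit()
        fit = fit_crossover(vals, seq, subj, per, form)
        i = groups["Formulation"][0]
        assert fit["estimate_ln"] == pytest.approx(res.params[i], rel=1e-10)
        assert fit["se_ln"] == pytest.approx(res.bse[i], rel=1e-8)
        assert fit["mse"] == pytest.approx(res.mse_resid, rel=1e-10)
        assert fit["df_resid"] == int(res.df_resid)


class TestRunABE:
    def test_balanced_df_is_n_minus_2(self, pilot_study):
        result = bq.run_abe(bq.run_nca(pilot_study), "cmax")
        assert result.n_subjects == 24
        assert result.df_resid == 22

    def test_gmr_equals_lsm_ratio_and_ci_contains_gmr(self, pilot_study):
        r = bq.run_abe(bq.run_nca(pilot_study), "cmax")
        assert r.gmr_pct == pytest.approx(100 * r.lsm_test / r.lsm_ref, rel=1e-12)
        assert r.ci90_pct[0] < r.gmr_pct < r.ci90_pct[1]
        assert r.iscv_pct == pytest.approx(bq.iscv_from_mse(r.mse))

    def test_identical_test_and_reference_values_degenerate(self, toy_study):
        nca = bq.run_nca(toy_study)
        # force Test == Reference per subject
        ref = nca[nca["formulation"] == "Reference"].set_index("subject_id")["cmax_ng_ml"]
        nca.loc[nca["formulation"] == "Test", "cmax_ng_ml"] = (
            nca.loc[nca["formulation"] == "Test", "subject_id"].map(ref).to_numpy())
        r = bq.run_abe(nca, "cmax")
        assert r.gmr_pct == pytest.approx(100.0, abs=1e-9)
        assert r.mse == pytest.approx(0.0, abs=1e-15)
        assert r.ci90_pct[0] == pytest.approx(r.ci90_pct[1], abs=1e-9)

    def test_period_relabeling_leaves_gmr_unchanged(self, pilot_study):
        nca = bq.run_nca(pilot_study)
        a = bq.run_abe(nca, "cmax")
        flipped = nca.copy()
        flipped["period"] = 3 - flipped["period"]
        flipped["sequence"] = flipped["sequence"].map({"TR": "RT", "RT": "TR"})
        b = bq.run_abe(flipped, "cmax")
        assert b.gmr_pct == pytest.approx(a.gmr_pct, rel=1e-9)
        assert b.iscv_pct == pytest.approx(a.iscv_pct, rel=1e-9)

    def test_nonpositive_metric_rejected(self, toy_study):
        nca = bq.run_nca(toy_study)
        nca.loc[0, "cmax_ng_ml"] = 0.0
        with pytest.raises((bq.DataError, ValueError)):
            fit_crossover(nca["cmax_ng_ml"], nca["sequence"], nca["subject_id"],
                          nca["period"], nca["formulation"])

    def test_empty_sequence_is_design_error(self):
        vals = np.array([1.0, 2.0, 1.1, 2.1])
        seq = np.array(["TR"] * 4)
        subj = np.array(["A", "A", "B", "B"])
        per = np.array([1, 2, 1, 2])
        form = np.array(["Test", "Reference", "Test", "Reference"])
        with pytest.raises(bq.DataError):
            fit_crossover(vals, seq, subj, per, form)

    def test_anova_table_terms_and_dfs(self, pilot_study):
        r = bq.run_abe(bq.run_nca(pilot_study), "cmax")
        tbl = r.anova_table
        assert list(tbl.index) == ["Sequence", "Subject(Sequence)", "Period",
                                   "Formulation", "Residual"]
        assert tbl.loc["Subject(Sequence)", "df"] == 22
        assert tbl.loc["Sequence", "df"] == 1
        assert tbl.loc["Residual", "df"] == 22
        # total SS partitions (balanced complete data)
        y = np.log(bq.run_nca(pilot_study)["cmax_ng_ml"])
        total = ((y - y.mean()) ** 2).sum()
        assert tbl["ss"].sum() == pytest.approx(total, rel=1e-9)


class TestISCV:
    @pytest.mark.parametrize("mse,expected", [
        (0.0, 0.0),
        (np.log(1.25), 50.0),
        (0.25, 53.294),
    ])
    def test_iscv_from_mse(self, mse, expected):
        assert bq.iscv_from_mse(mse) == pytest.approx(expected, abs=5e-4)

    def test_negative_mse_rejected(self):
        with pytest.raises(ValueError):
            bq.iscv_from_mse(-0.1)

    def test_inverse_map_round_trips(self):
        assert bq.iscv_from_mse(bq.mse_from_iscv(50.0)) == pytest.approx(50.0)


class TestDecision:
    @pytest.mark.parametrize("ci,expected", [
        ((89.04, 114.60), True),     # pivotal-style CI inside the limits
        ((81.76, 132.21), False),    # pilot-style CI breaching the upper limit
        ((80.00, 125.00), True),     # closed interval at the boundaries
        ((79.99, 120.0), False),
    ])
    def test_interval_inclusion_rule(self, ci, expected):
        r = bq.ABEResult(metric_name="cmax", n_subjects=23, lsm_test=1.0, lsm_ref=1.0,
                         gmr_pct=float(np.sqrt(ci[0] * ci[1])), ci90_pct=ci, mse=0.1,
                         df_resid=21, iscv_pct=33.0)
        assert bq.be_decision(r).bioequivalent is expected

    def test_published_lsm_ratios_reproduce_gmr(self):
        assert round(bq.gmr_from_lsms(10398.64, 10001.77), 2) == 103.97
        assert round(bq.gmr_from_lsms(14667.79, 12509.20), 2) == 117.26
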
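"""Mixed models, stepwise AIC, LRT, Tukey HSD and RMSE."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from sorglt import stats_report as sr


@pytest.fixture(scope="module")
def trait_table():
    """Balanced table with a known +0.3 trait effect and Eq-1 random parts."""
    return sr.simulate_factorial_table(
        n_sites=4, n_years=6,
        effects={("trait",): {("LT0.9",): 0.3}},
        sd_site=0.2, sd_year=0.1, sd_resid=0.3, seed=7)


@pytest.fixture(scope="module")
def trait_fit(trait_table):
    return sr.fit_mixed(sr.spec("yield_mg_ha", "eq1"), trait_table, reml=True)


class TestRmse:
    @pytest.mark.parametrize("obs,sim,expected", [
        ([52], [53], 1.0),
        ([1.0, 2.0], [1.0, 2.0], 0.0),
        ([0.0, 0.0], [3.0, 4.0], 3.5355339),
    ])
    def test_values(self, obs, sim, expected):
        assert sr.rmse(obs, sim) == pytest.approx(expected, abs=1e-6)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        obs, sim = rng.random(137), rng.random(137)
        total = 0.0
        for o, s in zip(obs, sim):
            total += (o - s) ** 2
        assert sr.rmse(obs, sim) == pytest.approx(
            (total / len(obs)) ** 0.5, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sr.rmse([1, 2], [1])


class TestFitMixed:
    def test_recovers_trait_effect_within_two_se(self, trait_fit):
        pairs = sr.tukey_hsd(trait_fit, "GT").pairs
        row = pairs.iloc[0]
        diff = row["estimate"] if row.level_a == "LT0.9" else -row["estimate"]
        assert abs(diff - 0.3) <= 2 * row.se

    def test_zero_between_year_variance_estimated_near_zero(self):
        t = sr.simulate_factorial_table(n_sites=3, n_years=4, sd_year=0.0,
                                        sd_site=0.2, sd_resid=0.3, seed=1)
        fit = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), t, reml=True)
        assert float(fit.result.vcomp[0]) < 0.01

    def test_row_order_invariance(self, trait_table):
        fit1 = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), trait_table)
        shuffled = trait_table.sample(frac=1.0, random_state=3)
        fit2 = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), shuffled)
        pd.testing.assert_series_equal(fit1.fe_params, fit2.fe_params,
                                       atol=1e-6, rtol=1e-5)

    def test_single_location_rejected(self, trait_table):
        with pytest.raises(ValueError, match="locations"):
            sr.fit_mixed(sr.spec("yield_mg_ha", "eq1"),
                         trait_table[trait_table.site == 0])

    def test_matches_lme4_fixed_effects(self, trait_table):
        """Independent oracle: the same model fitted by lme4 through Rscript."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        sub = trait_table
        fit = sr.fit_mixed(
            sr.ModelSpec("yield_mg_ha", (("GT",), ("EW",))), sub, reml=True)
        csv = "scratch_lme4.csv"
        import tempfile, os
        with tempfile.TemporaryDirectory() as td:
            path = os.path.join(td, csv)
            sub.to_csv(path, index=False)
            rcode = f"""
            suppressMessages(library(lme4))
            d <- read.csv("{path}")
            m <- lmer(yield_mg_ha ~ trait + env + (1|site) + (1|site:year), d, REML=TRUE)
            cat(fixef(m), sep="\\n")
            """
            out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                                 text=True, timeout=300)
            assert out.returncode == 0, out.stderr
            r_fixef = np.array([float(x) for x in out.stdout.split()])
        np.testing.assert_allclose(np.asarray(fit.fe_params), r_fixef, atol=2e-3)


class TestLikelihoodRatio:
    def test_identical_models(self, trait_table):
        f = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), trait_table)
        stat, dof, p = sr.likelihood_ratio(f, f)
        assert stat == 0.0 and dof == 0 and p == 1.0

    def test_statistic_matches_brute_force(self, trait_table):
        reduced = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), trait_table)
        full = sr.fit_mixed(sr.spec("yield_mg_ha", "full"), trait_table)
        stat, dof, p = sr.likelihood_ratio(reduced, full)
        assert stat == pytest.approx(
            max(0.0, 2 * (full.llf - reduced.llf)), abs=1e-9)
        assert stat >= 0.0
        assert dof == full.n_params - reduced.n_params

    def test_non_nested_rejected(self, trait_table):
        a = sr.fit_mixed(sr.ModelSpec("yield_mg_ha", (("GT",),)), trait_table)
        b = sr.fit_mixed(sr.ModelSpec("yield_mg_ha", (("GM",),)), trait_table)
        with pytest.raises(ValueError, match="nested"):
            sr.likelihood_ratio(a, b)

    def test_reml_fits_rejected(self, trait_table):
        a = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), trait_table, reml=True)
        b = sr.fit_mixed(sr.spec("yield_mg_ha", "full"), trait_table, reml=True)
        with pytest.raises(ValueError, match="ML"):
            sr.likelihood_ratio(a, b)


class TestStepwise:
    def test_drops_absent_interactions_keeps_real_effects(self):
        t = sr.simulate_factorial_table(
            n_sites=3, n_years=5,
            effects={("trait",): {("LT0.9",): 0.5},
                     ("env",): {("ED",): -0.8, ("MD",): -0.5, ("LD",): -0.2}},
            sd_resid=0.25, seed=11)
        # search from the two-way family to keep the scan quick
        start = sr.ModelSpec("yield_mg_ha", tuple(
            term for term in sr.MODEL_PRESETS["full"] if len(term) <= 2))
        final = sr.stepwise_backward_aic(start, t)
        assert ("GT",) in final.fixed_terms
        assert ("EW",) in final.fixed_terms
        assert ("GM", "MP") not in final.fixed_terms

    def test_marginality_never_violated(self):
        t = sr.simulate_factorial_table(n_sites=2, n_years=4, seed=3)
        start = sr.ModelSpec("yield_mg_ha", tuple(
            term for term in sr.MODEL_PRESETS["full"] if len(term) <= 2))
        trace: list = []
        final = sr.stepwise_backward_aic(start, t, trace=trace)
        for term in final.fixed_terms:
            for other in final.fixed_terms:
                if set(term) < set(other):
                    break
            else:
                continue
        # every retained interaction keeps its main effects
        for term in final.fixed_terms:
            if len(term) > 1:
                for sym in term:
                    assert (sym,) in final.fixed_terms

    def test_final_aic_not_above_start(self):
        t = sr.simulate_factorial_table(n_sites=2, n_years=4, seed=5)
        start = sr.ModelSpec("yield_mg_ha", tuple(
            term for term in sr.MODEL_PRESETS["full"] if len(term) <= 2))
        final = sr.stepwise_backward_aic(start, t)
        aic_start = sr.fit_mixed(start, t).aic
        aic_final = sr.fit_mixed(final, t).aic
        assert aic_final <= aic_start + 1e-9


class TestTukey:
    def test_equal_means_share_a_letter(self):
        t = sr.simulate_factorial_table(n_sites=3, n_years=5, seed=2)
        fit = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), t, reml=True)
        tk = sr.tukey_hsd(fit, "GM")
        assert not tk.gate_passed
        assert len(set(tk.letters.values())) == 1

    def test_shifted_group_gets_own_letter(self):
        t = sr.simulate_factorial_table(
            n_sites=3, n_years=5,
            effects={("maturity",): {("full",): 3.0}},  # 10 sd shift
            sd_resid=0.3, seed=4)
        fit = sr.fit_mixed(sr.spec("yield_mg_ha", "eq4"), t, reml=True)
        tk = sr.tukey_hsd(fit, "GM")
        assert tk.gate_passed
        assert tk.letters["full"] != tk.letters["short"]
        assert tk.letters["short"] == tk.letters["medium"]

    def test_number_of_pairs(self, trait_fit):
        assert len(sr.tukey_hsd(trait_fit, "EW").pairs) == 6  # C(4,2)
        assert len(sr.tukey_hsd(trait_fit, "GM").pairs) == 3  # C(3,2)


class TestReport:
    def _tables(self):
        runs = sr.simulate_factorial_table(n_sites=2, n_years=3, seed=0)
        runs["failed"] = False
        rel = pd.DataFrame({
            "trait": ["LT0.9"] * 4, "env": ["WW", "LD", "MD", "ED"],
            "pct_change": [1.0, 4.0, 8.0, 9.0]})
        return {"runs": runs, "relative": rel}

    def test_regeneration_is_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        sr.report(self._tables(), a)
        sr.report(self._tables(), b)
        assert (a / "report.txt").read_bytes() == (b / "report.txt").read_bytes()
        assert (a / "runs.csv").read_bytes() == (b / "runs.csv").read_bytes()

    def test_missing_sections_marked_absent(self, tmp_path):
        path = sr.report({}, tmp_path / "r")
        text = path.read_text()
        assert "absent" in text

    def test_relative_rows_per_env(self, tmp_path):
        sr.report(self._tables(), tmp_path / "r")
        rel = pd.read_csv(tmp_path / "r" / "relative_change_by_env.csv")
        assert len(rel) == 4
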
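"""Mixed-model fits: recovery, null calibration, invariances, lme4 oracle."""

import copy
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from gaitprop import (compute_diagnostics, fit_control_propulsion_model,
                      fit_leg_model, fit_per_leg_posthoc, fit_symmetry_model,
                      generate_cohort, load_params, process_cohort)
from gaitprop.errors import GaitPropError
from gaitprop.synthetic_gait import GeneratorParams


def _null_params(params):
    """Exchangeable-leg stroke parameters: no speed, leg or interaction effects."""
    raw = copy.deepcopy({"stroke": params.stroke, "control": params.control,
                         "gait": params.gait, "waveform": params.waveform})
    for metric in ("peak", "impulse"):
        mp = raw["stroke"][metric]
        mp["sym_speed_beta"] = 0.0
        mp["sym_interaction_beta"] = 0.0
        mp["share_at_cws"] = dict(mp["share_at_cws"], mean=0.5, sd=0.03,
                                  min=0.3, max=0.7)
    return GeneratorParams.from_dict(raw)


class TestSymmetryModel:
    def test_stroke_impulse_estimates_recover_generative_values(self, params,
                                                                stroke_table):
        fit = fit_symmetry_model(stroke_table, "impulse", "stroke")
        gen = params.stroke["impulse"]
        assert fit.converged
        assert fit.estimate("speed") == pytest.approx(
            gen["sym_speed_beta"], abs=2 * fit.params.loc["speed", "se"])
        assert fit.estimate("speed:s0") == pytest.approx(
            gen["sym_interaction_beta"], abs=2 * fit.params.loc["speed:s0", "se"])
        assert "s0" in fit.not_reported

    def test_control_intercept_near_half(self, control_table):
        fit = fit_symmetry_model(control_table, "peak", "control")
        assert abs(fit.estimate("Intercept") - 0.5) <= \
            2 * fit.params.loc["Intercept", "se"]

    def test_single_participant_rejected(self, stroke_table):
        one = stroke_table[stroke_table.participant_id == "st000"]
        with pytest.raises(GaitPropError):
            fit_symmetry_model(one, "impulse", "stroke")

    def test_null_speed_effect_ci_covers_zero(self, params):
        """With zero injected effects the 95% CI covers 0 in >=90% of reps."""
        p0 = _null_params(params)
        hits = 0
        n_rep = 20
        for rep in range(n_rep):
            cohort = generate_cohort(p0, "stroke", 3000 + rep)
            table, _ = process_cohort(cohort)
            fit = fit_symmetry_model(table, "impulse", "stroke",
                                     df_method="between_within")
            est = fit.estimate("speed")
            se = fit.params.loc["speed", "se"]
            if abs(est) <= 1.96 * se:
                hits += 1
        assert hits >= int(0.9 * n_rep) - 1


class TestLegModel:
    def test_injected_interaction_recovered(self, params, stroke_table):
        fit = fit_leg_model(stroke_table, "peak")
        # generative per-leg slopes: non-paretic ~1.6, paretic ~1.2 N/kg per m/s
        assert fit.estimate("speed:leg_p") == pytest.approx(
            -0.4, abs=2 * fit.params.loc["speed:leg_p", "se"])
        assert fit.estimate("leg_p") < 0  # paretic reduction

    def test_exchangeable_legs_give_null_leg_effects(self, params):
        p0 = _null_params(params)
        cohort = generate_cohort(p0, "stroke", 77)
        table, _ = process_cohort(cohort)
        fit = fit_leg_model(table, "impulse")
        for term in ("leg_p", "speed:leg_p"):
            assert abs(fit.estimate(term)) <= 2 * fit.params.loc[term, "se"]

    def test_missing_leg_rejected(self, stroke_table):
        only_paretic = stroke_table[stroke_table.leg != "non_paretic"]
        with pytest.raises(GaitPropError):
            fit_leg_model(only_paretic, "peak")

    def test_beta_invariant_to_row_order_and_df_method(self, stroke_table, rng):
        fit_a = fit_leg_model(stroke_table, "impulse", df_method="between_within")
        shuffled = stroke_table.sample(frac=1.0, random_state=7)
        fit_b = fit_leg_model(shuffled, "impulse", df_method="satterthwaite")
        np.testing.assert_allclose(fit_a.params["estimate"], fit_b.params["estimate"],
                                   rtol=1e-6)
        np.testing.assert_allclose(fit_a.params["se"], fit_b.params["se"], rtol=1e-6)
        # df/p may differ between methods; estimates may not
        assert not np.allclose(fit_a.params["df"], fit_b.params["df"])


class TestPosthocAndControl:
    def test_posthoc_slopes_bracket_the_leg_model(self, stroke_table):
        fit_np = fit_per_leg_posthoc(stroke_table, "peak", "non_paretic")
        fit_p = fit_per_leg_posthoc(stroke_table, "peak", "paretic")
        assert fit_np.estimate("speed") > fit_p.estimate("speed")

    def test_control_speed_slope_recovers_generative_value(self, params,
                                                           control_table):
        fit = fit_control_propulsion_model(control_table, "peak")
        assert fit.estimate("speed") == pytest.approx(
            1.73, abs=2 * fit.params.loc["speed", "se"])

    def test_too_few_participants_rejected(self, stroke_table):
        sub = stroke_table[stroke_table.participant_id == "st001"]
        with pytest.raises(GaitPropError):
            fit_per_leg_posthoc(sub, "peak", "paretic")


class TestDiagnostics:
    def test_bundle_lengths_and_residual_mean(self, stroke_table):
        fit = fit_symmetry_model(stroke_table, "impulse", "stroke")
        bundle = compute_diagnostics(fit)
        assert bundle.residuals.size == fit.n_obs
        assert bundle.fitted.size == fit.n_obs
        assert bundle.qq_sample.size == fit.n_obs
        # intercept model: conditional residuals centred near zero
        assert abs(bundle.residuals.mean()) < 0.3 * bundle.residuals.std()

    def test_gaussian_generation_passes_shapiro_mostly(self, params):
        passes = 0
        n_rep = 10
        for rep in range(n_rep):
            cohort = generate_cohort(params, "stroke", 500 + rep)
            table, _ = process_cohort(cohort)
            fit = fit_symmetry_model(table, "impulse", "stroke",
                                     df_method="between_within")
            if compute_diagnostics(fit).shapiro_p > 0.05:
                passes += 1
        assert passes >= int(0.9 * n_rep) - 1

    def test_render_writes_png(self, stroke_table, tmp_path):
        from gaitprop.lmm_models import render_diagnostics
        fit = fit_symmetry_model(stroke_table, "peak", "stroke")
        out = tmp_path / "diag.png"
        render_diagnostics(compute_diagnostics(fit), out)
        assert out.stat().st_size > 0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="R unavailable for the cross-check oracle")
class TestLme4Oracle:
    def test_fixed_effects_match_lme4(self, stroke_table, tmp_path):
        """Independent REML implementation (lme4) agrees on the fixed effects."""
        df = stroke_table.drop_duplicates(["participant_id", "condition_id"])
        work = pd.DataFrame({
            "pid": df["participant_id"], "speed": df["speed"],
            "sym": df["impulse_symmetry"], "s0": df["impulse_symmetry_at_cws"],
        }).dropna()
        csv = tmp_path / "d.csv"
        work.to_csv(csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'm <- lmer(sym ~ speed + s0 + speed:s0 + (1 + speed | pid), data = d,'
            ' REML = TRUE)\n'
            'cat(sprintf("%.10f\\n", fixef(m)))\n')
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        lme4 = np.array([float(x) for x in out.stdout.split()])
        fit = fit_symmetry_model(stroke_table, "impulse", "stroke",
                                 df_method="between_within")
        ours = fit.params["estimate"].to_numpy()  # Intercept, speed, s0, speed:s0
        np.testing.assert_allclose(ours, lme4, rtol=1e-3, atol=1e-5)
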
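{
  "version": 1,
  "description": "Headline values reported in the original allethrin-biodegradation optimization study, with the comparison tolerances used by the reproduce-reference report.",
  "fixture_sha256": "9561ddd36576cfa05ad05196797b1072b8c2cb864e40e0a39163b855d9df32bf",
  "values": {
    "intercept": {"value": 94.23, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, constant term"},
    "coef_pH": {"value": -0.1231, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, linear pH term (A)"},
    "coef_temperature": {"value": -0.2929, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, linear temperature term (B)"},
    "coef_time": {"value": 4.04, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, linear time term (C)"},
    "coef_pH_temperature": {"value": -1.25, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, AB interaction"},
    "coef_pH_time_magnitude": {"value": 2.00, "tol_abs": 0.02, "tol_rel": 0.0, "where": "coded quadratic equation, AC interaction (magnitude only)", "note": "the equation as printed carries +2.00; refitting the published design table gives -2.00, so only the magnitude is compared and the sign discrepancy is annotated"},
    "coef_temperature_time": {"value": -4.5, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, BC interaction"},
    "coef_pH_sq": {"value": -6.74, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, A^2 term"},
    "coef_temperature_sq": {"value": -6.91, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, B^2 term"},
    "coef_time_sq": {"value": -5.11, "tol_abs": 0.005, "tol_rel": 0.005, "where": "coded quadratic equation, C^2 term"},
    "adj_r2": {"value": 0.9823, "tol_abs": 0.002, "tol_rel": 0.0, "where": "model summary; reported simply as the R-squared of the model", "note": "the reported 0.9823 matches the adjusted R-squared of the run-means fit; the raw R-squared of that fit is about 0.989 -- both are always reported, clearly labelled"},
    "pred_r2": {"value": 0.9412, "tol_abs": 0.01, "tol_rel": 0.0, "where": "model summary, predicted R-squared"},
    "f_value": {"value": 143.23, "tol_abs": 0.0, "tol_rel": 0.02, "where": "ANOVA, whole-model F"},
    "cv_percent": {"value": 1.64, "tol_abs": 0.05, "tol_rel": 0.0, "where": "model summary, coefficient of variation (%)"},
    "axial_alpha_2dp": {"value": 1.68, "tol_abs": 0.005, "tol_rel": 0.0, "where": "design description: five coded levels (-1.68, -1, 0, +1, +1.68)"},
    "n_runs": {"value": 24, "tol_abs": 0.0, "tol_rel": 0.0, "where": "design description: 24 experiments"},
    "boxcox_best_lambda": {"value": 1.72, "tol_abs": 0.15, "tol_rel": 0.0, "soft": true, "where": "Box-Cox plot, best lambda"},
    "boxcox_ci_low": {"value": -0.45, "tol_abs": 0.5, "tol_rel": 0.0, "soft": true, "where": "Box-Cox plot, lambda interval lower bound"},
    "boxcox_ci_high": {"value": 4.24, "tol_abs": 0.5, "tol_rel": 0.0, "soft": true, "where": "Box-Cox plot, lambda interval upper bound"},
    "stationary_max": {"value": 95.6, "tol_abs": 0.5, "tol_rel": 0.0, "soft": true, "where": "reported maximum degradation at the stationary point", "note": "95.6% is the best observed run (run 10), not the value of the printed equation at the stated coded optimum (0,0,0), which is its intercept 94.23; the report shows the model stationary value and the best observed run side by side"},
    "control_k": {"value": 0.0013, "tol_abs": 0.0001, "tol_rel": 0.0, "where": "kinetics results, control rate constant (1/h)"},
    "control_t_half": {"value": 533.19, "tol_abs": 0.01, "tol_rel": 0.0, "where": "kinetics results, control half-life (h)"},
    "treatment_k": {"value": 0.0193, "tol_abs": 0.0001, "tol_rel": 0.0, "where": "kinetics results, treatment rate constant (1/h)"},
    "treatment_t_half": {"value": 26.05, "tol_abs": 0.01, "tol_rel": 0.0, "soft": true, "where": "kinetics results, treatment half-life (h)", "note": "internally inconsistent with the reported treatment k: ln2/0.0193 = 35.91 h, not 26.05 h (the control pair is exactly consistent); the report prints both and flags the discrepancy"},
    "t_half_reduction": {"value": 507.1, "tol_abs": 0.1, "tol_rel": 0.0, "where": "reported half-life reduction, control minus treatment (h)", "note": "507.1 = 533.19 - 26.05, i.e. computed from the two reported half-lives"},
    "control_dissipation_percent": {"value": 18.0, "tol_abs": 0.0, "tol_rel": 0.0, "soft": true, "where": "reported abiotic control dissipation at 144 h (%)", "note": "a pure exponential with the reported control k predicts about 17.1% at 144 h"}
  }
}
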
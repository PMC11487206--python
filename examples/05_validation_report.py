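"""Full screening study: simulate, analyze, score, validate.

Runs the whole pipeline on a synthetic cohort and prints the
Table-style validation report: one row per screener x reference pair
with Youden-optimal cutoff, sensitivity/specificity, PPV/NPV and
trapezoidal AUC.
"""

import frailscreen as fs

config = fs.CohortConfig(n_participants=22, duration_days=0.25,
                         accel_rate_hz=25.0, seed=7)
result = fs.run_study(config)

cols = ["screener", "reference", "optimal_cutoff", "sensitivity",
        "specificity", "ppv", "npv", "auc"]
print(result.formatted_report[cols].to_string(index=False))

# AUC > 0.8 indicates good screener validity against that reference.
# "NaN" rows are the structural exclusions: the gait analyzer is not
# validated against non-movement (nonfunctional) FRAIL items, nor the
# heart-rate analyzer against the functional items.
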
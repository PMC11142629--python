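"""Reference estimates for the observed women's unit the simulator emulates.

The synthetic-data generator is parameterised to emulate a real 16-bed,
gender-segregated therapeutic-community unit observed for 611 days, over
which 6,108 peer affirmations and 1,945 peer corrections were exchanged.
The fitted tie-model coefficients estimated on that unit (posterior mean
and equal-tailed 95% interval, probit scale) are embedded here and serve
two roles:

* default ``true_beta`` / variance components of the simulator, so that
  synthetic units reproduce the magnitude and sign structure of a real
  unit; and
* ground truth for parameter-recovery experiments, in which data are
  simulated with these coefficients and the fitted posterior is compared
  against them.

The underlying clinical records are archival and not distributable; only
these summary estimates travel with the package.
"""

from __future__ import annotations

import pandas as pd

from .event_data import AFFIRMATION, CORRECTION

#: Observed event volumes over the 611-day reference window.
REFERENCE_VOLUMES = {AFFIRMATION: 6108, CORRECTION: 1945}
REFERENCE_HORIZON = 611
REFERENCE_BEDS = 16

# variable, affirmations (mean, lower, upper), corrections (mean, lower, upper)
_ROWS = [
    ("intercept", -1.83, -1.95, -1.71, -2.39, -2.49, -2.28),
    ("aff_reciprocity", 0.14, 0.10, 0.18, -0.09, -0.15, -0.04),
    ("aff_transitive_closure", 0.00, -0.03, 0.02, 0.00, -0.03, 0.02),
    ("aff_three_cycle", 0.00, -0.01, 0.01, 0.02, 0.00, 0.03),
    ("aff_indegree_activity", 0.10, 0.06, 0.15, 0.17, 0.10, 0.23),
    ("aff_indegree_popularity", 0.04, -0.01, 0.09, 0.14, 0.05, 0.22),
    ("aff_outdegree_activity", -0.07, -0.10, -0.05, 0.12, 0.09, 0.16),
    ("aff_out_isolation_activity", -0.34, -0.43, -0.24, -0.09, -0.38, 0.18),
    ("aff_same_peer", -0.15, -0.20, -0.10, -0.13, -0.20, -0.06),
    ("cor_reciprocity", -0.05, -0.11, 0.00, 0.20, 0.13, 0.25),
    ("cor_transitive_closure", 0.02, -0.01, 0.06, -0.04, -0.07, 0.00),
    ("cor_three_cycle", 0.03, 0.00, 0.07, -0.01, -0.04, 0.03),
    ("cor_indegree_activity", 0.03, 0.00, 0.07, 0.13, 0.07, 0.19),
    ("cor_indegree_popularity", 0.02, -0.01, 0.06, 0.24, 0.18, 0.30),
    ("cor_outdegree_activity", 0.05, 0.02, 0.08, 0.06, 0.01, 0.10),
    ("cor_out_isolation_activity", -0.06, -0.12, 0.01, -0.34, -0.48, -0.20),
    ("cor_same_peer", -0.05, -0.12, 0.01, 0.16, 0.09, 0.23),
    ("young_activity", -0.18, -0.24, -0.12, -0.18, -0.28, -0.08),
    ("young_popularity", 0.11, 0.06, 0.16, -0.02, -0.10, 0.06),
    ("senior_activity", 0.04, -0.02, 0.08, -0.07, -0.14, 0.00),
    ("senior_popularity", -0.01, -0.05, 0.04, -0.09, -0.17, -0.02),
    ("admission_homophily", 0.23, 0.10, 0.37, 0.51, 0.29, 0.74),
    ("white_activity", 0.27, -0.01, 0.58, 0.14, -0.04, 0.33),
    ("white_popularity", -0.12, -0.26, 0.01, 0.29, 0.04, 0.58),
    ("race_homophily", 0.05, -0.06, 0.15, -0.08, -0.33, 0.14),
    ("age_activity", 0.00, -0.01, 0.01, -0.01, -0.02, 0.00),
    ("age_popularity", 0.00, -0.01, 0.00, 0.00, -0.01, 0.00),
    ("age_homophily", 0.19, 0.10, 0.27, -0.12, -0.26, 0.01),
    ("lsir_activity", 0.01, 0.00, 0.03, 0.00, -0.01, 0.01),
    ("lsir_popularity", 0.00, 0.00, 0.01, 0.00, 0.00, 0.01),
    ("lsir_similarity", 0.00, -0.10, 0.10, -0.03, -0.19, 0.12),
    ("staff_aff_indegree_activity", 0.02, -0.01, 0.04, -0.03, -0.06, 0.00),
    ("staff_aff_indegree_popularity", 0.01, -0.02, 0.03, -0.04, -0.07, 0.00),
    ("staff_cor_indegree_activity", -0.01, -0.04, 0.02, -0.03, -0.06, 0.01),
    ("staff_cor_indegree_popularity", 0.00, -0.02, 0.03, -0.04, -0.08, -0.01),
    ("unit_ht", -0.12, -0.57, 0.34, -0.15, -0.44, 0.15),
    ("unit_staff_ht", 0.13, -0.33, 0.59, 0.15, -0.15, 0.44),
    ("ht_indegree_activity", 0.24, -0.09, 0.54, -0.52, -1.01, -0.07),
    ("staff_ht_indegree_activity", -0.35, -0.70, 0.02, 0.54, 0.03, 1.08),
    ("ht_outdegree_popularity", 0.07, -0.28, 0.40, -0.03, -0.46, 0.39),
    ("ht_reciprocity", -0.17, -1.50, 1.08, -0.90, -2.67, 0.67),
]

REFERENCE_EFFECTS = pd.DataFrame(
    [
        (net, var, m, lo, hi)
        for var, ma, la, ua, mc, lc, uc in _ROWS
        for net, m, lo, hi in ((AFFIRMATION, ma, la, ua), (CORRECTION, mc, lc, uc))
    ],
    columns=["model", "variable", "mean", "lower", "upper"],
)

#: Reference variance components (sender, receiver, day), variance scale.
REFERENCE_VARIANCES = {
    AFFIRMATION: {"sender": 0.30, "receiver": 0.08, "day": 0.74},
    CORRECTION: {"sender": 0.17, "receiver": 0.13, "day": 0.54},
}


def reference_beta(model: str) -> dict[str, float]:
    """Named coefficient vector (posterior means) for one tie model."""
    sub = REFERENCE_EFFECTS[REFERENCE_EFFECTS["model"] == model]
    if sub.empty:
        raise KeyError(f"unknown model {model!r}")
    return dict(zip(sub["variable"], sub["mean"]))


def reference_interval(model: str, variable: str) -> tuple[float, float, float]:
    """(mean, lower, upper) of one reference coefficient."""
    sub = REFERENCE_EFFECTS[
        (REFERENCE_EFFECTS["model"] == model) & (REFERENCE_EFFECTS["variable"] == variable)
    ]
    if sub.empty:
        raise KeyError(f"no reference estimate for {model}/{variable}")
    r = sub.iloc[0]
    return float(r["mean"]), float(r["lower"]), float(r["upper"])
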
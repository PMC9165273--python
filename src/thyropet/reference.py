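"""Published summary statistics used as calibration inputs and worked examples.

The study cohort itself is not public; what is public are the printed
summaries: per-stratum contingency counts of the rule-out threshold analysis,
median/IQR SUV distributions per cytology group and outcome, and one fully
worked single-patient quantification example. These are inputs to the
package — the synthetic cohort generator is calibrated against the SUV
distributions, and the diagnostic-accuracy reproduction feeds the contingency
counts back through the statistics layer.
"""

from __future__ import annotations

# Cytology subgroups. AUS/FLUS and FN/SFN together form the non-Hürthle
# stratum; HCN/SHCN is the Hürthle (oncocytic) stratum.
GROUPS = ("AUS/FLUS", "FN/SFN", "HCN/SHCN")
SUBGROUP_FRACTIONS = {"AUS/FLUS": 55 / 123, "FN/SFN": 39 / 123, "HCN/SHCN": 29 / 123}

N_COHORT = 123
PREVALENCE_MALIGNANT = 33 / 123  # malignant/borderline rate 27%
VISUAL_POSITIVE_FRACTION = 84 / 123

# Worked single-patient example: SUVmax 9.7 g/mL, SUVpeak 7.0 g/mL over a
# contralateral-lobe background SUVmax of 1.6 g/mL -> ratios 6.1 and 4.4.
WORKED_EXAMPLE = {"suv_max": 9.7, "suv_peak": 7.0, "background_suv_max": 1.6}

# SUV metric distributions by (stratum, outcome): median, (q1, q3), in g/mL
# for the SUV metrics and dimensionless for the ratios.
SUV_DISTRIBUTIONS = {
    ("all", "malignant_or_borderline"): {
        "suv_max": (8.3, 3.6, 16.3),
        "suv_peak": (6.1, 2.8, 12.6),
        "background": (1.8, 1.7, 2.2),
    },
    ("all", "benign"): {
        "suv_max": (3.4, 2.3, 7.3),
        "suv_peak": (2.9, 1.9, 5.6),
        "background": (2.0, 1.8, 2.5),
    },
    ("non_hurthle", "malignant_or_borderline"): {
        "suv_max": (5.8, 3.3, 15.2),
        "suv_peak": (4.5, 2.5, 10.9),
        "background": (1.9, 1.7, 2.4),
    },
    ("non_hurthle", "benign"): {
        "suv_max": (3.1, 2.3, 4.7),
        "suv_peak": (2.5, 1.9, 3.9),
        "background": (2.0, 1.8, 2.5),
    },
    ("hurthle", "malignant_or_borderline"): {
        "suv_max": (12.3, 8.0, 28.4),
        "suv_peak": (9.9, 6.1, 24.0),
        "background": (1.8, 1.6, 2.1),
    },
    ("hurthle", "benign"): {
        "suv_max": (12.2, 5.0, 35.3),
        "suv_peak": (7.3, 4.0, 22.5),
        "background": (1.9, 1.6, 2.5),
    },
}

# Published rule-out threshold analysis: contingency counts per stratum and
# test. Keys: (stratum, test); values: dict with cut_off (None for the visual
# read) and the 2x2 counts (tp, fp, tn, fn). Positivity is value >= cut-off.
THRESHOLD_TABLE = {
    ("all", "visual"): dict(cut_off=None, tp=31, fp=53, tn=37, fn=2),
    ("non_hurthle", "visual"): dict(cut_off=None, tp=22, fp=34, tn=36, fn=2),
    ("hurthle", "visual"): dict(cut_off=None, tp=9, fp=19, tn=1, fn=0),
    ("all", "suv_max"): dict(cut_off=2.1, tp=32, fp=73, tn=17, fn=1),
    ("all", "suv_peak"): dict(cut_off=1.6, tp=32, fp=80, tn=10, fn=1),
    ("all", "suv_max_ratio"): dict(cut_off=1.2, tp=32, fp=56, tn=34, fn=1),
    ("all", "suv_peak_ratio"): dict(cut_off=0.9, tp=32, fp=75, tn=15, fn=1),
    ("non_hurthle", "suv_max"): dict(cut_off=2.1, tp=23, fp=54, tn=16, fn=1),
    ("non_hurthle", "suv_peak"): dict(cut_off=1.6, tp=23, fp=61, tn=9, fn=1),
    ("non_hurthle", "suv_max_ratio"): dict(cut_off=1.2, tp=23, fp=38, tn=32, fn=1),
    ("non_hurthle", "suv_peak_ratio"): dict(cut_off=0.9, tp=23, fp=57, tn=13, fn=1),
    ("hurthle", "suv_max"): dict(cut_off=5.2, tp=9, fp=15, tn=5, fn=0),
    ("hurthle", "suv_peak"): dict(cut_off=4.7, tp=9, fp=13, tn=7, fn=0),
    ("hurthle", "suv_max_ratio"): dict(cut_off=3.4, tp=9, fp=14, tn=6, fn=0),
    ("hurthle", "suv_peak_ratio"): dict(cut_off=2.8, tp=9, fp=13, tn=7, fn=0),
}
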
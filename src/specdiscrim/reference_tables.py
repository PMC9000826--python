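"""Reported diagnostic performance of the pilot clinical cohorts this package
models, used as fixed arithmetic cross-checks.

Each row carries the reported integer accuracy, sensitivity, specificity,
F-score and G-score (percent) for one evaluation block (Training / CV / Test)
of one classification task.  The raw spectra behind these numbers are not
public; what *is* checkable is the metric arithmetic: recomputing the F- and
G-scores from the reported sensitivity/specificity must reproduce the
reported integers, and the blind-test accuracy must follow from the cohort's
class sizes plus the reported rates.
"""

from __future__ import annotations

import pandas as pd

from .metrics import metrics_from_rates, round_half_away

__all__ = [
    "TISSUE_ROWS",
    "SUBGROUP_ROWS",
    "ALL_ROWS",
    "CLASS_SIZES",
    "verify_reported_scores",
    "accuracy_from_rates",
]

# (scheme, specimen, block, accuracy, sensitivity, specificity, f_score, g_score)
TISSUE_ROWS = [
    ("berden_focal_vs_mixed", "tissue", "Training", 81, 82, 78, 80, 80),
    ("berden_focal_vs_mixed", "tissue", "CV", 75, 80, 67, 73, 73),
    ("berden_focal_vs_mixed", "tissue", "Test", 69, 69, 70, 69, 69),
    ("normal_glomeruli_N0_vs_N1N2", "tissue", "Training", 90, 89, 90, 89, 89),
    ("normal_glomeruli_N0_vs_N1N2", "tissue", "CV", 77, 56, 83, 67, 68),
    ("normal_glomeruli_N0_vs_N1N2", "tissue", "Test", 93, 83, 95, 89, 89),
    ("ifta_T0_vs_T1", "tissue", "Training", 91, 86, 93, 89, 89),
    ("ifta_T0_vs_T1", "tissue", "CV", 78, 67, 82, 74, 74),
    ("ifta_T0_vs_T1", "tissue", "Test", 93, 100, 90, 95, 95),
    ("necrotising", "tissue", "Training", 100, 100, 100, 100, 100),
    ("necrotising", "tissue", "CV", 87, 88, 85, 86, 86),
    ("necrotising", "tissue", "Test", 100, 100, 100, 100, 100),
    ("infiltrate", "tissue", "Training", 88, 87, 88, 87, 87),
    ("infiltrate", "tissue", "CV", 80, 73, 84, 78, 78),
    ("infiltrate", "tissue", "Test", 100, 100, 100, 100, 100),
    ("arteritis", "tissue", "Training", 74, 80, 73, 76, 76),
    ("arteritis", "tissue", "CV", 72, 67, 73, 70, 70),
    ("arteritis", "tissue", "Test", 78, 100, 73, 84, 85),
    ("vessel_necrosis", "tissue", "Training", 74, 92, 71, 80, 81),
    ("vessel_necrosis", "tissue", "CV", 69, 58, 71, 64, 64),
    ("vessel_necrosis", "tissue", "Test", 81, 100, 78, 88, 88),
]

# Paired-subgroup comparison (10 samples, tissue and urine).
SUBGROUP_ROWS = [
    ("ifta_T0_vs_T1", "tissue", "Training", 100, 100, 100, 100, 100),
    ("ifta_T0_vs_T1", "tissue", "CV", 83, 67, 90, 77, 78),
    ("ifta_T0_vs_T1", "tissue", "Test", 100, 100, 100, 100, 100),
    ("ifta_T0_vs_T1", "urine", "Training", 100, 100, 100, 100, 100),
    ("ifta_T0_vs_T1", "urine", "CV", 66, 57, 70, 63, 63),
    ("ifta_T0_vs_T1", "urine", "Test", 100, 100, 100, 100, 100),
    ("necrotising", "tissue", "Training", 100, 100, 100, 100, 100),
    ("necrotising", "tissue", "CV", 87, 78, 90, 84, 84),
    ("necrotising", "tissue", "Test", 100, 100, 100, 100, 100),
    ("necrotising", "urine", "Training", 93, 93, 93, 93, 93),
    ("necrotising", "urine", "CV", 67, 53, 73, 61, 62),
    ("necrotising", "urine", "Test", 100, 100, 100, 100, 100),
    ("infiltrate", "tissue", "Training", 100, 100, 100, 100, 100),
    ("infiltrate", "tissue", "CV", 90, 89, 90, 89, 89),
    ("infiltrate", "tissue", "Test", 100, 100, 100, 100, 100),
    ("infiltrate", "urine", "Training", 99, 97, 100, 98, 98),
    ("infiltrate", "urine", "CV", 72, 53, 80, 64, 65),
    ("infiltrate", "urine", "Test", 100, 100, 100, 100, 100),
]

ALL_ROWS = TISSUE_ROWS + SUBGROUP_ROWS

#: (n positive, n negative) samples per scheme in the 27-sample tissue cohort.
CLASS_SIZES = {
    "berden_focal_vs_mixed": (9, 15),
    "normal_glomeruli_N0_vs_N1N2": (6, 21),
    "ifta_T0_vs_T1": (7, 20),
    "necrotising": (16, 11),
    "infiltrate": (10, 17),
    "arteritis": (5, 22),
    "vessel_necrosis": (4, 23),
}


def verify_reported_scores(rows=None) -> pd.DataFrame:
    """Recompute F- and G-scores from each row's reported sensitivity and
    specificity; flag whether the rounded integers reproduce the report."""
    rows = ALL_ROWS if rows is None else rows
    out = []
    for scheme, specimen, block, ac, sens, spec, fs, gs in rows:
        fs_c, gs_c = metrics_from_rates(float(sens), float(spec))
        out.append(
            {
                "scheme": scheme,
                "specimen": specimen,
                "block": block,
                "sens": sens,
                "spec": spec,
                "f_reported": fs,
                "f_recomputed": round_half_away(fs_c),
                "g_reported": gs,
                "g_recomputed": round_half_away(gs_c),
            }
        )
    df = pd.DataFrame(out)
    df["f_match"] = df["f_reported"] == df["f_recomputed"]
    df["g_match"] = df["g_reported"] == df["g_recomputed"]
    return df


def accuracy_from_rates(sens_pct: float, spec_pct: float, n_pos: int, n_neg: int) -> float:
    """Percent accuracy implied by rounded per-class rates and class sizes.

    TP and TN are recovered as the nearest integer counts consistent with the
    reported rates (rates were themselves rounded from integer counts)."""
    tp = round_half_away(sens_pct / 100.0 * n_pos)
    tn = round_half_away(spec_pct / 100.0 * n_neg)
    return 100.0 * (tp + tn) / (n_pos + n_neg)
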
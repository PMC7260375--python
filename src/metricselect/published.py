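"""Published per-metric clinimetric scores and the documented selection.

The package ships the printed AUC / ICC / SRD% / eta values of the 77
evaluated metrics (including the simulated-noise control) together with the
published step-1 model-quality flags, so the distribution-derived selection
cutoffs and the survivor sets can be recomputed offline without the original
patient recordings.  Two redundancy removals in the published analysis were
literature-preference choices; they ship as the manual-override list.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .clinimetrics import SelectionThresholds, percentile

__all__ = [
    "load_published_scores",
    "PUBLISHED_STEP3_REMOVALS",
    "reproduce_published_selection",
]

#: Literature-preference redundancy removals: within each correlated pair the
#: grip-force-rate spectral arc length during hole approach was kept because
#: it is independent of movement distance and most directly reflects hand
#: function.
PUBLISHED_STEP3_REMOVALS = {
    frozenset({"gf_rate_n_peaks_hole_approach", "gf_rate_sparc_hole_approach"}):
        "gf_rate_n_peaks_hole_approach",
    frozenset({"sparc_hole_approach", "gf_rate_sparc_hole_approach"}):
        "sparc_hole_approach",
}


def load_published_scores() -> pd.DataFrame:
    """The 77 published metric rows, indexed by metric name.

    Columns: characteristic, auc, icc, srd_pct, eta, plus the published
    step-2 criterion flag and step-1 model-quality failure flag (booleans).
    """
    with resources.files("metricselect.tables").joinpath(
        "published_scores.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    df["step2_criteria_met"] = df["step2_criteria_met"].astype(bool)
    df["step1_quality_fail"] = df["step1_quality_fail"].astype(bool)
    return df.set_index("metric_name")


def reproduce_published_selection(
    thresholds: SelectionThresholds = SelectionThresholds(),
) -> dict:
    """Recompute the published selection from the shipped score table.

    Applies the step-2 criteria with cutoffs recomputed from the 77 rows
    (AUC >= 0.7, ICC >= 0.7, SRD% strictly below its 80th percentile, eta
    strictly above its 20th percentile), intersects with the published
    step-1 survivors, and applies the documented redundancy removals.
    """
    df = load_published_scores()
    srd_cut = percentile(df["srd_pct"], thresholds.srd_pct_percentile,
                         thresholds.percentile_convention)
    eta_cut = percentile(df["eta"], thresholds.eta_percentile,
                         thresholds.percentile_convention)
    passed = df[
        (df["auc"] >= thresholds.auc_min)
        & (df["icc"] >= thresholds.icc_min)
        & (df["srd_pct"] < srd_cut)
        & (df["eta"] > eta_cut)
    ]
    step12 = passed[~passed["step1_quality_fail"]]
    removed = set(PUBLISHED_STEP3_REMOVALS.values())
    core = [m for m in step12.index if m not in removed]
    return {
        "srd_cutoff": float(srd_cut),
        "eta_cutoff": float(eta_cut),
        "step2_passers": list(passed.index),
        "step12_survivors": list(step12.index),
        "medians": {
            "auc": float(step12["auc"].median()),
            "icc": float(step12["icc"].median()),
            "srd_pct": float(step12["srd_pct"].median()),
            "eta": float(step12["eta"].median()),
        },
        "core_set": core,
    }
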
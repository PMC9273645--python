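"""Stage-wise CNA-burden comparison between two cohorts.

For each tumor stage (1-4) and each CNA mode, the per-patient burdens of
the two cohorts are contrasted with a Welch t-test and Bonferroni-corrected
over the family of comparisons actually run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .burden import MODES, burden
from .io import Cohort
from .survival import collapse_clinical

COMPARE_COLUMNS = [
    "stage", "mode", "n_a", "n_b", "mean_a", "sd_a", "mean_b", "sd_b",
    "t", "p_raw", "p_bonferroni", "m", "flag",
]


def _stage_burdens(cohort: Cohort, mode: str, m_threshold: int) -> pd.DataFrame:
    clin = collapse_clinical(cohort.clinical)
    b = burden(cohort.cna, mode, m_threshold)
    df = pd.DataFrame({"burden": b, "stage": clin["stage"].reindex(b.index)})
    return df.dropna()


def compare_cohorts(
    a: Cohort,
    b: Cohort,
    modes=MODES,
    m: int | str = "auto",
    burden_threshold: int = 1,
    stages=(1, 2, 3, 4),
) -> pd.DataFrame:
    """Stage-wise Welch comparison of CNA burden between cohorts ``a`` and
    ``b``, per mode, Bonferroni-corrected.

    ``m`` is the correction family size; "auto" uses the number of (stage,
    mode) rows actually tested. Rows where a stage is absent (or has a
    single patient) in either cohort are flagged and excluded from the
    automatic family size.
    """
    rows = []
    for mode in modes:
        da = _stage_burdens(a, mode, burden_threshold)
        db = _stage_burdens(b, mode, burden_threshold)
        for stage in stages:
            xa = da.loc[da["stage"] == stage, "burden"].to_numpy(dtype=float)
            xb = db.loc[db["stage"] == stage, "burden"].to_numpy(dtype=float)
            row = {
                "stage": stage, "mode": mode,
                "n_a": len(xa), "n_b": len(xb),
                "mean_a": xa.mean() if len(xa) else np.nan,
                "sd_a": xa.std(ddof=1) if len(xa) > 1 else np.nan,
                "mean_b": xb.mean() if len(xb) else np.nan,
                "sd_b": xb.std(ddof=1) if len(xb) > 1 else np.nan,
                "t": np.nan, "p_raw": np.nan, "flag": "",
            }
            if len(xa) < 2 or len(xb) < 2:
                row["flag"] = "stage absent or singleton in a cohort"
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
                row["t"], row["p_raw"] = float(t), float(p)
            rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["flag"] == ""
    family = int(tested.sum()) if m == "auto" else int(m)
    table["m"] = family
    table["p_bonferroni"] = np.minimum(1.0, family * table["p_raw"])
    return table[COMPARE_COLUMNS]


def boxplot_data(cohort: Cohort, label: str, modes=MODES, burden_threshold: int = 1) -> pd.DataFrame:
    """Per (stage, mode) burden quantiles for grouped box plots."""
    frames = []
    for mode in modes:
        df = _stage_burdens(cohort, mode, burden_threshold)
        q = (
            df.groupby("stage")["burden"]
            .quantile([0.0, 0.25, 0.5, 0.75, 1.0])
            .unstack()
        )
        q.columns = ["min", "q1", "median", "q3", "max"]
        q = q.reset_index().assign(mode=mode, cohort=label)
        frames.append(q)
    return pd.concat(frames, ignore_index=True)
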
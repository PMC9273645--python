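"""Survival-critical gene triage.

Cox proportional-hazards association of gene expression (continuous
z-score) and of altered/unaltered status (high-level amplification,
homozygous deletion, or mutation) with overall survival, adjusted for
covariates chosen by univariate screening (p < 0.05). Altered and
unaltered groups are also contrasted on expression with the Wilcoxon
rank-sum test, and each gene is triaged into a hazard-ratio magnitude band
and a drug-development direction.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

from .io import Cohort

logger = logging.getLogger(__name__)

CANDIDATE_COVARIATES = ("age", "sex", "race", "stage")

# magnitude anchors for hazard-ratio triage (two-group comparisons)
HR_SMALL, HR_MEDIUM, HR_LARGE = 1.3, 1.9, 2.8

_STAGE_RE = re.compile(r"(IV|III|II|I|[1-4])", re.IGNORECASE)
_ROMAN = {"I": 1, "II": 2, "III": 3, "IV": 4}


class CovariateError(ValueError):
    """Clinical covariates cannot be formed (e.g. no parseable stages)."""


@dataclass
class CovariateSet:
    """Candidate covariates with univariate Cox p-values and the selected
    subset (p < 0.05)."""

    pvalues: dict[str, float]
    selected: list[str]
    dropped: list[str] = field(default_factory=list)


def collapse_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Collapse raw clinical fields into analysis covariates.

    Race becomes two levels (White vs Other, small groups combined); tumor
    stage sub-levels (IA, IIIB, ...) collapse onto their main stage 1-4.
    Rows with an unparseable stage or missing required fields are marked
    ``complete = False`` for complete-case exclusion.
    """
    out = clinical.copy()
    out["race"] = np.where(
        clinical["race"].astype(str).str.strip().str.casefold() == "white",
        "White",
        "Other",
    )
    out.loc[clinical["race"].isna(), "race"] = np.nan

    def parse_stage(raw) -> float:
        if pd.isna(raw):
            return np.nan
        m = _STAGE_RE.search(str(raw).upper().replace("STAGE", " "))
        if not m:
            return np.nan
        tok = m.group(1).upper()
        return float(_ROMAN[tok]) if tok in _ROMAN else float(tok)

    out["stage"] = clinical["stage_raw"].map(parse_stage)
    if out["stage"].notna().sum() == 0:
        raise CovariateError("no parseable tumor stages in clinical table")
    required = ["age", "sex", "race", "stage", "os_time", "os_event"]
    out["complete"] = out[required].notna().all(axis=1)
    n_dropped = int((~out["complete"]).sum())
    if n_dropped:
        logger.info("complete-case exclusion flags %d patients", n_dropped)
    return out


def _design_columns(covariates: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric design columns for Cox fits (sex/race dummy-coded, stage
    ordinal, age continuous)."""
    cols = {}
    for name in names:
        if name == "sex":
            cols["sex"] = (covariates["sex"].astype(str).str.casefold() == "male").astype(float)
        elif name == "race":
            cols["race"] = (covariates["race"] == "White").astype(float)
        else:
            cols[name] = pd.to_numeric(covariates[name])
    return pd.DataFrame(cols, index=covariates.index)


def _fit_cox(df: pd.DataFrame):
    """Fit a Cox model (Efron tie handling) and return the fitter, or raise."""
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="os_time", event_col="os_event")
    return cph


def select_covariates(
    clinical: pd.DataFrame,
    candidates=CANDIDATE_COVARIATES,
    alpha: float = 0.05,
) -> CovariateSet:
    """Univariate Cox screen of candidate covariates; keep p < alpha.

    ``clinical`` must already be collapsed (see :func:`collapse_clinical`).
    Constant or non-converging candidates are dropped with a warning.
    """
    cc = clinical[clinical["complete"]]
    pvalues: dict[str, float] = {}
    dropped: list[str] = []
    for name in candidates:
        design = _design_columns(cc, [name])
        if design[name].nunique() < 2:
            dropped.append(name)
            logger.warning("covariate %s is constant; dropped", name)
            continue
        df = design.assign(os_time=cc["os_time"], os_event=cc["os_event"])
        try:
            cph = _fit_cox(df)
            pvalues[name] = float(cph.summary.loc[name, "p"])
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            dropped.append(name)
            logger.warning("covariate %s failed to converge (%s); dropped", name, exc)
    selected = [n for n, p in pvalues.items() if p < alpha]
    return CovariateSet(pvalues=pvalues, selected=selected, dropped=dropped)


def altered_status(cohort: Cohort, gene: str) -> pd.Series:
    """Altered/unaltered flag per patient for one gene: high-level
    amplification (+2), homozygous deletion (-2), or a mutation flag."""
    calls = cohort.cna.calls.loc[gene]
    altered = calls.abs() == 2
    if cohort.mutations is not None and gene in cohort.mutations.index:
        mut = cohort.mutations.loc[gene].reindex(altered.index, fill_value=False)
        altered = altered | mut
    return altered.rename("altered")


def cox_gene(
    cohort: Cohort,
    gene: str,
    covariates: list[str],
    clinical: pd.DataFrame,
    predictor: str = "expression",
) -> dict:
    """Adjusted Cox fit for one gene.

    predictor="expression" uses the continuous z-score (per-unit HR);
    predictor="altered_group" uses the binary altered/unaltered status.
    Returns {"hr", "p", "n", "flag"}; degenerate fits are flagged with HR
    absent rather than raising.
    """
    if predictor == "expression":
        x = cohort.expression.values.loc[gene]
    elif predictor == "altered_group":
        x = altered_status(cohort, gene).astype(float)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    cc = clinical[clinical["complete"]]
    design = _design_columns(cc, covariates)
    df = design.assign(
        predictor=x.reindex(cc.index),
        os_time=cc["os_time"],
        os_event=cc["os_event"],
    ).dropna()
    record = {"gene": gene, "predictor": predictor, "hr": np.nan, "p": np.nan,
              "n": int(len(df)), "flag": ""}
    if df["os_event"].sum() < 2:
        record["flag"] = "fewer than 2 events"
        return record
    if df["predictor"].nunique() < 2:
        record["flag"] = "constant predictor"
        return record
    try:
        cph = _fit_cox(df)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        record["flag"] = f"non-convergence: {exc}"
        return record
    record["hr"] = float(np.exp(cph.summary.loc["predictor", "coef"]))
    record["p"] = float(cph.summary.loc["predictor", "p"])
    return record


def altered_contrast(cohort: Cohort, gene: str) -> dict:
    """Wilcoxon rank-sum contrast of expression between altered and
    unaltered patients, with group summaries."""
    altered = altered_status(cohort, gene)
    expr = cohort.expression.values.loc[gene]
    a = expr[altered.reindex(expr.index, fill_value=False)].dropna()
    u = expr[~altered.reindex(expr.index, fill_value=True)].dropna()
    out = {
        "gene": gene,
        "n_altered": int(len(a)),
        "n_unaltered": int(len(u)),
        "mean_altered": float(a.mean()) if len(a) else np.nan,
        "sd_altered": float(a.std(ddof=1)) if len(a) > 1 else np.nan,
        "median_altered": float(a.median()) if len(a) else np.nan,
        "mean_unaltered": float(u.mean()) if len(u) else np.nan,
        "sd_unaltered": float(u.std(ddof=1)) if len(u) > 1 else np.nan,
        "median_unaltered": float(u.median()) if len(u) else np.nan,
        "wilcoxon_p": np.nan,
        "flag": "",
    }
    if len(a) == 0 or len(u) == 0:
        out["flag"] = "one group empty"
        return out
    method = "exact" if max(len(a), len(u)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, u, alternative="two-sided", method=method)
    out["wilcoxon_p"] = float(res.pvalue)
    return out


def hr_category(hr: float) -> str:
    """Magnitude band of a two-group hazard ratio, applied symmetrically to
    protective effects via 1/HR: none (HR=1), sub-small (<1.3),
    small-medium [1.3, 1.9), medium-large [1.9, 2.8), large (>=2.8)."""
    if not np.isfinite(hr) or hr <= 0:
        return "none"
    eff = max(hr, 1.0 / hr)
    if eff == 1.0:
        return "none"
    if eff < HR_SMALL:
        return "sub-small"
    if eff < HR_MEDIUM:
        return "small-medium"
    if eff < HR_LARGE:
        return "medium-large"
    return "large"


def _fig4_category(expr_higher_in_altered: bool, improved_survival: bool) -> str:
    """The four expression-direction x survival-direction categories."""
    if improved_survival:
        return "b" if expr_higher_in_altered else "a"
    return "d" if expr_higher_in_altered else "c"


def run_survival_screen(
    cohort: Cohort,
    genes,
    covariates: list[str] | None = None,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Fit both Cox models and the altered-expression contrast per gene."""
    if clinical is None:
        if cohort.clinical is None:
            raise CovariateError("cohort has no clinical table")
        clinical = collapse_clinical(cohort.clinical)
    if covariates is None:
        covariates = select_covariates(clinical).selected
    rows = []
    for gene in genes:
        expr_fit = cox_gene(cohort, gene, covariates, clinical, "expression")
        grp_fit = cox_gene(cohort, gene, covariates, clinical, "altered_group")
        contrast = altered_contrast(cohort, gene)
        rows.append(
            {
                "gene": gene,
                "expression_hr": expr_fit["hr"],
                "expression_p": expr_fit["p"],
                "group_hr": grp_fit["hr"],
                "group_p": grp_fit["p"],
                "n": expr_fit["n"],
                "n_altered": contrast["n_altered"],
                "n_unaltered": contrast["n_unaltered"],
                "mean_altered": contrast["mean_altered"],
                "sd_altered": contrast["sd_altered"],
                "median_altered": contrast["median_altered"],
                "mean_unaltered": contrast["mean_unaltered"],
                "sd_unaltered": contrast["sd_unaltered"],
                "median_unaltered": contrast["median_unaltered"],
                "wilcoxon_p": contrast["wilcoxon_p"],
                "flag": "; ".join(
                    f for f in (expr_fit["flag"], grp_fit["flag"], contrast["flag"]) if f
                ),
            }
        )
    columns = [
        "gene", "expression_hr", "expression_p", "group_hr", "group_p", "n",
        "n_altered", "n_unaltered", "mean_altered", "sd_altered",
        "median_altered", "mean_unaltered", "sd_unaltered",
        "median_unaltered", "wilcoxon_p", "flag",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("gene")


def triage(
    screen_table: pd.DataFrame,
    survival_results: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Combine the GE-CNA screen with the survival screen.

    Survival-critical genes are screen-significant genes whose continuous
    expression-survival Cox p-value is < alpha. Each is assigned an
    expression-direction x survival-direction category (a-d), a
    hazard-ratio magnitude band, and a drug direction: inhibitor for
    categories a/d, enhancer for b/c.
    """
    sig = screen_table[screen_table["direction"] != "none"].set_index("gene")
    rows = []
    for gene in sig.index:
        if gene not in survival_results.index:
            continue
        surv = survival_results.loc[gene]
        critical = pd.notna(surv["expression_p"]) and surv["expression_p"] < alpha
        hr = surv["group_hr"]
        expr_higher = surv["mean_altered"] > surv["mean_unaltered"]
        if pd.isna(hr) or hr == 1.0:
            cat, direction = "none", "none"
        else:
            cat = _fig4_category(bool(expr_higher), improved_survival=hr < 1.0)
            direction = "inhibitor" if cat in ("a", "d") else "enhancer"
        rows.append(
            {
                "gene": gene,
                "screen_direction": sig.loc[gene, "direction"],
                "survival_critical": bool(critical),
                "expression_hr": surv["expression_hr"],
                "expression_p": surv["expression_p"],
                "group_hr": hr,
                "group_p": surv["group_p"],
                "wilcoxon_p": surv["wilcoxon_p"],
                "category": cat if critical else "none",
                "hr_category": hr_category(hr) if critical else "none",
                "actionable": bool(
                    critical
                    and np.isfinite(hr)
                    and hr > 0
                    and max(hr, 1.0 / hr) >= HR_SMALL
                ),
                "drug_direction": direction if critical else "none",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "screen_direction", "survival_critical",
            "expression_hr", "expression_p", "group_hr", "group_p",
            "wilcoxon_p", "category", "hr_category", "actionable",
            "drug_direction",
        ],
    ).set_index("gene")


def km_curve(cohort: Cohort, gene: str, clinical: pd.DataFrame | None = None) -> pd.DataFrame:
    """Kaplan-Meier curve data (time, at-risk, survival) for the altered and
    unaltered groups of one gene, for external plotting."""
    from lifelines import KaplanMeierFitter

    if clinical is None:
        clinical = collapse_clinical(cohort.clinical)
    altered = altered_status(cohort, gene)
    frames = []
    for label, mask in (("altered", altered), ("unaltered", ~altered)):
        sub = clinical.loc[clinical.index.intersection(mask[mask].index)]
        sub = sub.dropna(subset=["os_time", "os_event"])
        if len(sub) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_time"], sub["os_event"])
        tab = kmf.event_table
        frames.append(
            pd.DataFrame(
                {
                    "gene": gene,
                    "group": label,
                    "time": tab.index,
                    "at_risk": tab["at_risk"].to_numpy(),
                    "survival": kmf.survival_function_at_times(tab.index).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
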
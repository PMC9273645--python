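"""The GE-CNA screen: per-gene contrast of CNA burden between
extreme-expression patient groups.

For every gene that survives the missingness filter, patients are ranked by
the gene's expression z-score; the top-k and bottom-k patients form the
high- and low-expression groups (k=10 by default). The groups' CNA burdens
are compared with a two-sample t-test (Welch by default), the resulting
p-values are corrected by Storey q-value across the tested-gene family, and
significant genes are labelled CNA *facilitators* (higher expression, more
CNA) or *suppressors* (higher expression, fewer CNA). The screen runs
jointly over all CNA (mode "total") and separately for amplification and
deletion CNA.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .burden import MODES, burden
from .io import Cohort, ExpressionMatrix
from .multitest import bh_qvalues, storey_qvalues

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "gene",
    "mode",
    "n_high",
    "n_low",
    "mean_high",
    "sd_high",
    "mean_low",
    "sd_low",
    "t",
    "df",
    "p",
    "q",
    "direction",
]


@dataclass
class ScreenConfig:
    """Tuning knobs of the GE-CNA screen.

    k : extreme-group size per tail (10 by default).
    alpha : q-value significance level for direction labels.
    missing_cutoff : genes missing in more than this fraction of patients
        are excluded (1/3 by default).
    require_complete : additionally require retained genes to have no
        missing values at all (the strict variant of the filter).
    flavor : "welch" (unequal variances, Welch-Satterthwaite df) or
        "pooled" (classic equal-variance Student t).
    multitest : "storey_q" or "bh".
    burden_threshold : magnitude threshold m passed to the burden counter.
    """

    k: int = 10
    alpha: float = 0.05
    missing_cutoff: float = 1.0 / 3.0
    require_complete: bool = True
    flavor: str = "welch"
    multitest: str = "storey_q"
    burden_threshold: int = 1

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("extreme-group size k must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.missing_cutoff <= 1:
            raise ValueError("missing_cutoff must lie in (0, 1]")
        if self.flavor not in ("welch", "pooled"):
            raise ValueError(f"unknown t-test flavor {self.flavor!r}")
        if self.multitest not in ("storey_q", "bh"):
            raise ValueError(f"unknown multiple-testing method {self.multitest!r}")


@dataclass
class ScreenResult:
    """Per-mode screen tables plus run metadata."""

    tables: dict[str, pd.DataFrame]
    pi0: dict[str, float]
    config: ScreenConfig
    skipped: list[str] = field(default_factory=list)

    def significant(self, mode: str = "total") -> pd.DataFrame:
        tab = self.tables[mode]
        return tab[tab["direction"] != "none"]


def filter_genes(
    expr: ExpressionMatrix,
    cutoff: float = 1.0 / 3.0,
    require_complete: bool = True,
) -> ExpressionMatrix:
    """Drop genes missing in more than ``cutoff`` of patients.

    With ``require_complete`` (default) retained genes must in addition be
    observed in every patient, so the downstream screen always sees complete
    expression rows.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must lie in (0, 1]")
    frac_missing = expr.missing_mask.mean(axis=1)
    keep = frac_missing <= cutoff
    if require_complete:
        keep &= frac_missing == 0
    if not keep.any():
        logger.warning("missingness filter removed every gene; screen will be empty")
    return ExpressionMatrix(expr.values.loc[keep])


def extreme_groups(values: pd.Series, k: int) -> tuple[pd.Index, pd.Index]:
    """Top-k and bottom-k patients by expression, ties broken by patient id.

    Missing values are excluded; a gene with fewer than 2k usable patients
    cannot form disjoint groups and raises ValueError (callers skip and log).
    """
    usable = values.dropna().sort_index()  # canonical id order for tie-breaks
    if len(usable) < 2 * k:
        raise ValueError(
            f"need >= {2 * k} patients with observed expression, have {len(usable)}"
        )
    v = usable.to_numpy()
    high_order = np.argsort(-v, kind="stable")
    high = usable.index[high_order[:k]]
    low_order = np.argsort(v, kind="stable")
    low_ids = [i for i in usable.index[low_order] if i not in set(high)][:k]
    return high, pd.Index(low_ids)


def _t_from_stats(mean1, sd1, n1, mean2, sd2, n2, flavor: str):
    equal_var = flavor == "pooled"
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var
    )
    if equal_var:
        df = n1 + n2 - 2.0
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return t, df, p


def burden_contrast(
    high: pd.Index,
    low: pd.Index,
    burden_profile: pd.Series,
    flavor: str = "welch",
) -> dict:
    """Two-sided two-sample t-test on CNA burden between the extreme groups.

    Returns the test statistic, degrees of freedom, p-value and the group
    summary statistics (mean/SD/n per group). Degenerate variance cases:
    both groups constant and equal means -> t=0, p=1; constant groups with
    unequal means -> p set to the smallest positive float and flagged.
    """
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both extreme groups must be nonempty")
    hb = burden_profile.loc[high].to_numpy(dtype=float)
    lb = burden_profile.loc[low].to_numpy(dtype=float)
    out = {
        "n_high": len(hb),
        "n_low": len(lb),
        "mean_high": hb.mean(),
        "sd_high": hb.std(ddof=1) if len(hb) > 1 else 0.0,
        "mean_low": lb.mean(),
        "sd_low": lb.std(ddof=1) if len(lb) > 1 else 0.0,
        "flag": "",
    }
    if out["sd_high"] == 0.0 and out["sd_low"] == 0.0:
        if out["mean_high"] == out["mean_low"]:
            out.update(t=0.0, df=float(len(hb) + len(lb) - 2), p=1.0)
        else:
            out.update(
                t=np.inf if out["mean_high"] > out["mean_low"] else -np.inf,
                df=float(len(hb) + len(lb) - 2),
                p=sys.float_info.min,
                flag="zero-variance-unequal-means",
            )
        return out
    t, df, p = _t_from_stats(
        out["mean_high"], out["sd_high"], out["n_high"],
        out["mean_low"], out["sd_low"], out["n_low"],
        flavor,
    )
    out.update(t=float(t), df=float(df), p=float(p))
    return out


def _extreme_group_indices(values: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized extreme groups for a complete genes x patients array whose
    columns are already in canonical patient-id order.

    Returns (high, low) index arrays of shape (n_genes, k). Stable argsort
    on the id-ordered axis reproduces the tie-break rule of
    :func:`extreme_groups`.
    """
    high = np.argsort(-values, axis=1, kind="stable")[:, :k]
    low = np.argsort(values, axis=1, kind="stable")[:, :k]
    return high, low


def run_screen(
    cohort: Cohort,
    config: ScreenConfig | None = None,
    modes=MODES,
) -> ScreenResult:
    """Run the full GE-CNA screen on an aligned cohort.

    Applies the missingness filter, forms per-gene extreme-expression
    groups, contrasts each mode's CNA burden between them, corrects across
    the tested-gene family per mode, and labels significant genes as
    facilitators (mean_high > mean_low) or suppressors (mean_high <
    mean_low).
    """
    config = config or ScreenConfig()
    expr = filter_genes(
        cohort.expression, config.missing_cutoff, config.require_complete
    )
    burdens = {
        mode: burden(cohort.cna, mode, config.burden_threshold) for mode in modes
    }

    # canonical patient order (align_cohort already sorts, but be safe)
    patients = expr.patients.sort_values()
    values = expr.values.loc[:, patients].to_numpy(dtype=float)
    genes = expr.genes
    k = config.k

    complete = ~np.isnan(values).any(axis=1)
    skipped = []
    if values.shape[1] < 2 * k:
        skipped.extend(
            f"{g}: fewer than {2 * k} patients with observed expression" for g in genes
        )
        tested_mask = np.zeros(len(genes), dtype=bool)
    else:
        # complete genes take the vectorized path; genes with residual
        # missingness (relaxed filter) fall back to the per-gene path below
        tested_mask = complete.copy()

    tables: dict[str, pd.DataFrame] = {}
    pi0s: dict[str, float] = {}
    for mode in modes:
        bvec = burdens[mode].loc[patients].to_numpy(dtype=float)
        records: list[dict] = []

        if tested_mask.any():
            vv = values[tested_mask]
            hi_idx, lo_idx = _extreme_group_indices(vv, k)
            hb = bvec[hi_idx]
            lb = bvec[lo_idx]
            mean_h, mean_l = hb.mean(axis=1), lb.mean(axis=1)
            sd_h, sd_l = hb.std(axis=1, ddof=1), lb.std(axis=1, ddof=1)
            t, df, p = _t_from_stats(mean_h, sd_h, k, mean_l, sd_l, k, config.flavor)
            both_const = (sd_h == 0) & (sd_l == 0)
            eq = both_const & (mean_h == mean_l)
            ne = both_const & (mean_h != mean_l)
            t = np.where(eq, 0.0, t)
            p = np.where(eq, 1.0, p)
            p = np.where(ne, sys.float_info.min, p)
            df = np.where(both_const, 2.0 * k - 2.0, df)
            for i, g in enumerate(genes[tested_mask]):
                records.append(
                    dict(
                        gene=g, mode=mode, n_high=k, n_low=k,
                        mean_high=mean_h[i], sd_high=sd_h[i],
                        mean_low=mean_l[i], sd_low=sd_l[i],
                        t=float(t[i]), df=float(df[i]), p=float(p[i]),
                    )
                )

        # per-gene fallback for genes with residual missingness
        for gi in np.nonzero(~tested_mask)[0]:
            g = genes[gi]
            row = pd.Series(values[gi], index=patients)
            try:
                high, low = extreme_groups(row, k)
            except ValueError as exc:
                if mode == modes[0]:
                    skipped.append(f"{g}: {exc}")
                continue
            res = burden_contrast(high, low, burdens[mode], config.flavor)
            records.append(
                dict(
                    gene=g, mode=mode, n_high=res["n_high"], n_low=res["n_low"],
                    mean_high=res["mean_high"], sd_high=res["sd_high"],
                    mean_low=res["mean_low"], sd_low=res["sd_low"],
                    t=res["t"], df=res["df"], p=res["p"],
                )
            )

        table = pd.DataFrame.from_records(records)
        if len(table) == 0:
            tables[mode] = pd.DataFrame(columns=SCREEN_COLUMNS)
            pi0s[mode] = 1.0
            continue
        if config.multitest == "storey_q":
            q, pi0 = storey_qvalues(table["p"].to_numpy())
        else:
            q, pi0 = bh_qvalues(table["p"].to_numpy()), float("nan")
        table["q"] = q
        pi0s[mode] = pi0
        sig = table["q"] < config.alpha
        table["direction"] = "none"
        table.loc[sig & (table["mean_high"] > table["mean_low"]), "direction"] = (
            "facilitator"
        )
        table.loc[sig & (table["mean_high"] < table["mean_low"]), "direction"] = (
            "suppressor"
        )
        tables[mode] = table[SCREEN_COLUMNS]

    for msg in skipped:
        logger.debug("screen skip: %s", msg)
    return ScreenResult(tables=tables, pi0=pi0s, config=config, skipped=skipped)
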
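"""Kaplan-Meier estimation, log-rank testing, and clinical comparisons.

Kaplan-Meier curves and the log-rank statistic are delegated to lifelines;
this module wraps them behind the pipeline's data contracts: per-subtype
survival comparison, per-gene high/low survival screens (the binary matrix
already encodes the within-cohort median split, so the gene's 0/1 value is
the high/low group), and subtype comparisons of clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .cohorts import BinaryMatrix
from .diffgsea import bh_adjust
from .scores import wilcoxon_compare


@dataclass
class SurvEstimate:
    """Product-limit estimate for one group."""

    group: str
    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
                "group": self.group,
            }
        )


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p: float


def km_estimate(times, events, group: str = "all") -> SurvEstimate:
    """Kaplan-Meier product-limit estimator for one group.

    Censored-only times shrink the risk set without a survival step; the
    returned table is restricted to times with at least one event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty group")
    if (times < 0).any():
        raise ValueError("negative times")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    ev = tbl[tbl["observed"] > 0]
    return SurvEstimate(
        group=group,
        times=ev.index.to_numpy(dtype=float),
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
        survival=surv.loc[ev.index].to_numpy(dtype=float),
    )


def logrank(times, events, groups) -> LogRankResult:
    """Standard (unweighted) log-rank test across two or more groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    for g in uniq:
        if (groups == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    if events.sum() == 0:
        raise ValueError("no events observed; log-rank undefined")
    res = multivariate_logrank_test(times, groups, events)
    chi = float(res.test_statistic)
    df = len(uniq) - 1
    return LogRankResult(chi_square=chi, df=df, p=float(stats.chi2.sf(chi, df)))


def gene_survival(
    b: BinaryMatrix, clin: pd.DataFrame, genes: list[str]
) -> pd.DataFrame:
    """Per-gene log-rank of high (1) vs low (0) callers, BH-adjusted.

    Returns one row per testable gene with the chi-square, raw and adjusted
    p, and which group fared worse (by events-over-expected sign).  Genes
    constant across samples are skipped.
    """
    clin_idx = clin.set_index("sample_id").loc[b.samples]
    times = clin_idx["os_time_years"].to_numpy(dtype=float)
    events = clin_idx["os_event"].to_numpy(dtype=int)
    pos = {g: i for i, g in enumerate(b.genes)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing[:5]}")
    rows, skipped = [], []
    for g in genes:
        x = b.values[pos[g], :]
        if x.min() == x.max():
            skipped.append(g)
            continue
        res = logrank(times, events, x)
        # Direction: compare KM at the last common event time via medians of
        # the estimates; simpler and adequate—use mean survival ordering.
        hi = km_estimate(times[x == 1], events[x == 1], "high")
        lo = km_estimate(times[x == 0], events[x == 0], "low")
        mean_hi = float(hi.survival.mean()) if len(hi.survival) else 1.0
        mean_lo = float(lo.survival.mean()) if len(lo.survival) else 1.0
        rows.append(
            {
                "gene": g,
                "chi_square": res.chi_square,
                "p": res.p,
                "worse_group": "high" if mean_hi < mean_lo else "low",
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    if skipped:
        import warnings

        warnings.warn(f"skipped constant genes: {skipped[:5]}", stacklevel=2)
    return out


def chi_square_counts(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    chi, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi), float(p)


def compare_clinical(clin: pd.DataFrame, labels: dict[str, str]) -> pd.DataFrame:
    """Subtype comparisons of age (rank-sum) and sex/stage (chi-square).

    Missing values are dropped per covariate; a covariate with no usable
    values (or a degenerate table) is reported as untestable.  Group
    summaries (means for age, category percentages otherwise) are included.
    """
    df = clin[clin["sample_id"].isin(labels)].copy()
    df["subtype"] = df["sample_id"].map(labels)
    if df["subtype"].nunique() != 2:
        raise ValueError("need exactly two subtype labels")
    rows = []
    for cov in ["age", "sex", "t_stage", "n_stage", "m_stage"]:
        sub = df[[cov, "subtype"]].dropna()
        if sub.empty:
            rows.append(
                {"covariate": cov, "test": None, "statistic": np.nan, "p": np.nan,
                 "untestable": True, "summary": ""}
            )
            continue
        if cov == "age":
            stat, p = wilcoxon_compare(sub["age"].to_numpy(), sub["subtype"].to_numpy())
            means = sub.groupby("subtype")["age"].mean()
            summary = "; ".join(f"{k} mean {v:.1f}" for k, v in means.items())
            rows.append(
                {"covariate": cov, "test": "wilcoxon", "statistic": stat, "p": p,
                 "untestable": False, "summary": summary}
            )
        else:
            tab = pd.crosstab(sub["subtype"], sub[cov])
            if tab.shape[0] < 2 or tab.shape[1] < 2:
                rows.append(
                    {"covariate": cov, "test": "chi_square", "statistic": np.nan,
                     "p": np.nan, "untestable": True, "summary": ""}
                )
                continue
            stat, p = chi_square_counts(tab.to_numpy())
            pct = (tab.div(tab.sum(axis=1), axis=0) * 100).round(1)
            summary = "; ".join(
                f"{idx}: " + ", ".join(f"{c}={pct.loc[idx, c]}%" for c in pct.columns)
                for idx in pct.index
            )
            rows.append(
                {"covariate": cov, "test": "chi_square", "statistic": stat, "p": p,
                 "untestable": False, "summary": summary}
            )
    return pd.DataFrame(rows)
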
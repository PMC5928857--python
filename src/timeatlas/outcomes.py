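"""Survival and immunotherapy-response association.

Kaplan-Meier curves with log-rank comparison, Cox proportional-hazards
modeling with a univariable P < 0.2 screen feeding one multivariable fit
(Efron tie handling), and a two-tailed Fisher exact test of signature label
versus objective response (CR/PR by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

RESPONSE_CATEGORIES = ("CR", "PR", "SD", "PD")
#: Objective response per mRECIST: complete or partial response.
DEFAULT_RESPONDER_CATEGORIES = ("CR", "PR")

CLINICAL_COLUMNS = (
    "patient_id", "time_months", "event", "age", "asbestos",
    "histology_epithelial", "stage", "response",
)


def validate_clinical(records: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table: positive times, 0/1 events, known responses."""
    missing = [c for c in ("patient_id", "time_months", "event") if c not in records]
    if missing:
        raise ValueError(f"clinical table missing columns {missing}")
    if (records["time_months"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    if "response" in records:
        bad = set(records["response"].dropna()) - set(RESPONSE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown mRECIST categories {sorted(bad)}")
    return records


def merge_cohorts(*cohorts: pd.DataFrame) -> pd.DataFrame:
    """Concatenate clinical cohorts into one merged table.

    Patient ids are prefixed by cohort ordinal when they collide so the
    merged table keys remain unique.
    """
    frames = []
    seen: set[str] = set()
    for i, cohort in enumerate(cohorts):
        c = validate_clinical(cohort).copy()
        ids = c["patient_id"].astype(str)
        if ids.isin(seen).any():
            ids = f"c{i}_" + ids
            c["patient_id"] = ids
        if ids.duplicated().any():
            raise ValueError("duplicate patient ids within one cohort")
        seen.update(ids)
        frames.append(c)
    return pd.concat(frames, ignore_index=True)


@dataclass
class SurvivalComparison:
    """Per-group Kaplan-Meier estimates plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]   # group -> columns time, survival
    statistic: float
    p: float
    group_sizes: dict[str, int]

    def __post_init__(self) -> None:
        for group, curve in self.curves.items():
            s = curve["survival"].to_numpy()
            if np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12:
                raise ValueError(f"KM curve for {group!r} is not a valid survival function")


def survival_compare(records: pd.DataFrame, groups: pd.Series) -> SurvivalComparison:
    """Kaplan-Meier estimation per group and a log-rank test between groups.

    ``records`` needs patient_id / time_months / event; ``groups`` maps
    patient id to a group label.  Right censoring (event = 0) is handled by
    the product-limit estimator; the log-rank test compares observed versus
    expected events.
    """
    records = validate_clinical(records)
    g = records["patient_id"].map(groups)
    if g.isna().any():
        raise ValueError("every patient needs a group label")
    sizes = g.value_counts().to_dict()
    if len(sizes) < 2 or min(sizes.values()) < 1:
        raise ValueError("need two non-empty groups")
    if records["event"].sum() < 1:
        raise ValueError("need at least one event")
    curves = {}
    for label, sub in records.groupby(g):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    res = multivariate_logrank_test(records["time_months"], g, records["event"])
    return SurvivalComparison(
        curves=curves,
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        group_sizes={str(k): int(v) for k, v in sizes.items()},
    )


@dataclass
class CoxResult:
    univariable: pd.DataFrame         # variable x (hr, ci_low, ci_high, p)
    multivariable: pd.DataFrame | None
    screened_in: tuple[str, ...]
    screen_p: float


def cox_model(
    records: pd.DataFrame,
    variables: Sequence[str],
    screen_p: float = 0.2,
) -> CoxResult:
    """Univariable Cox screens feeding one multivariable fit.

    Each variable is fit alone against overall survival; variables with
    univariable P < ``screen_p`` enter a single multivariable
    proportional-hazards model (partial likelihood, Efron ties).  Hazard
    ratios are reported with 95% confidence intervals.
    """
    records = validate_clinical(records)
    variables = list(variables)
    missing = [v for v in variables if v not in records.columns]
    if missing:
        raise ValueError(f"clinical table lacks variables {missing}")

    def _fit(cols: list[str]) -> pd.DataFrame:
        df = records[["time_months", "event", *cols]].astype(float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time_months", event_col="event")
        summary = cph.summary
        return pd.DataFrame(
            {
                "hr": summary["exp(coef)"],
                "ci_low": summary["exp(coef) lower 95%"],
                "ci_high": summary["exp(coef) upper 95%"],
                "coef": summary["coef"],
                "p": summary["p"],
            }
        )

    uni_rows = []
    for var in variables:
        try:
            uni_rows.append(_fit([var]).loc[[var]])
        except Exception as exc:
            raise RuntimeError(f"univariable Cox fit failed for {var!r}: {exc}") from exc
    univariable = pd.concat(uni_rows)
    screened = tuple(univariable.index[univariable["p"] < screen_p])
    multivariable = None
    if screened:
        if records["event"].sum() < len(screened):
            raise ValueError("fewer events than multivariable terms")
        multivariable = _fit(list(screened))
    return CoxResult(
        univariable=univariable,
        multivariable=multivariable,
        screened_in=screened,
        screen_p=screen_p,
    )


@dataclass
class FisherResult:
    table: pd.DataFrame
    odds_ratio: float
    p: float
    defined: bool = True


def fisher_response(
    labels: pd.Series,
    records: pd.DataFrame,
    responder_categories: Sequence[str] = DEFAULT_RESPONDER_CATEGORIES,
) -> FisherResult:
    """Two-tailed Fisher exact test of signature label vs objective response.

    Rows are good_TiME / bad_TiME, columns responder (mRECIST in
    ``responder_categories``, CR/PR by default) / non-responder.  The
    two-tailed p sums hypergeometric tables with probability <= the
    observed table's.  An empty margin yields p = 1 with the odds ratio
    undefined.
    """
    records = validate_clinical(records)
    if "response" not in records:
        raise ValueError("clinical table has no response column")
    merged = records.dropna(subset=["response"]).copy()
    merged["label"] = merged["patient_id"].map(labels)
    if merged["label"].isna().any():
        raise ValueError("every evaluable patient needs a signature label")
    merged["responder"] = merged["response"].isin(list(responder_categories))
    present = set(merged["label"].unique())
    order = [l for l in ("good_TiME", "bad_TiME") if l in present] or sorted(present)
    if set(order) != present:
        order = sorted(present, key=lambda l: (l not in ("good_TiME", "bad_TiME"), l))
    table = (
        merged.groupby("label")["responder"]
        .agg(responder="sum", total="count")
        .assign(non_responder=lambda d: d["total"] - d["responder"])
        [["responder", "non_responder"]]
        .reindex(order)
        .astype(int)
    )
    if table.shape[0] < 2 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 response table; p = 1, OR undefined")
        return FisherResult(table=table, odds_ratio=float("nan"), p=1.0, defined=False)
    odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    a, b = table.iloc[0, 0], table.iloc[0, 1]
    c, d = table.iloc[1, 0], table.iloc[1, 1]
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    return FisherResult(table=table, odds_ratio=float(odds), p=float(p))
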
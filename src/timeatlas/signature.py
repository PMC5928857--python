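"""Dual-level (mRNA + protein) discriminatory microenvironment signature.

A gene enters the signature when it is differentially expressed between the
two immunologic subtypes at BOTH the transcript and the protein level
(Welch t, raw P below threshold at each level) with concordant direction.
New samples are classified good-TiME / bad-TiME by nearest-centroid Pearson
correlation on the standardized signature-gene profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GOOD, BAD = "good_TiME", "bad_TiME"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression at one molecular level."""

    values: pd.DataFrame
    level: str  # "mRNA" or "protein"
    platform: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("mRNA", "protein"):
            raise ValueError("level must be 'mRNA' or 'protein'")
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.values.isna().all(axis=1).any():
            raise ValueError("all-missing gene rows are not allowed")


@dataclass
class TimeSignature:
    """Gene list with directions and per-subtype standardized centroids."""

    genes: tuple[str, ...]
    directions: pd.Series           # gene -> +1 (up in I/good) or -1
    centroid_good: pd.Series        # standardized mRNA centroid, subtype I
    centroid_bad: pd.Series
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = pd.Index(self.genes)
        for name, series in (
            ("directions", self.directions),
            ("centroid_good", self.centroid_good),
            ("centroid_bad", self.centroid_bad),
        ):
            if not series.index.equals(idx):
                raise ValueError(f"{name} must be indexed by exactly the signature genes")
        if not self.directions.isin([1, -1]).all():
            raise ValueError("directions must be +1 or -1")

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "directions": self.directions.astype(int).to_dict(),
            "centroid_good": self.centroid_good.to_dict(),
            "centroid_bad": self.centroid_bad.to_dict(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "TimeSignature":
        genes = tuple(data["genes"])
        return cls(
            genes=genes,
            directions=pd.Series(data["directions"]).reindex(genes),
            centroid_good=pd.Series(data["centroid_good"]).reindex(genes),
            centroid_bad=pd.Series(data["centroid_bad"]).reindex(genes),
            metadata=dict(data.get("metadata", {})),
        )


def differential_features(
    expr: ExpressionMatrix,
    groups: pd.Series,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sample two-tailed Welch t test between subtypes.

    ``groups`` maps sample -> {"I", "II"}; the reported effect direction is
    the sign of mean(I) - mean(II).  Genes with zero variance in both
    groups get t = 0, p = 1 and are flagged.  Raw p values are primary; a
    Benjamini-Hochberg column is optional.
    """
    groups = groups.reindex(expr.values.columns)
    if groups.isna().any():
        raise ValueError("groups must label every sample column")
    a = expr.values.loc[:, groups == "I"].to_numpy(dtype=float)
    b = expr.values.loc[:, groups == "II"].to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 samples per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "mean_diff": diff,
            "direction": np.where(diff >= 0, 1, -1),
            "degenerate": degenerate,
        },
        index=expr.values.index,
    )
    if bh:
        out["p_bh"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    return out


def derive_signature(
    mrna_results: pd.DataFrame,
    protein_results: pd.DataFrame,
    mrna_expr: ExpressionMatrix,
    groups: pd.Series,
    p_threshold: float = 0.05,
    require_concordance: bool = True,
) -> TimeSignature:
    """Select genes differential at both levels and build centroids.

    Signature genes satisfy p < ``p_threshold`` at both the mRNA and the
    protein level and (by default) have the same effect direction at both
    levels.  Centroids are the per-subtype means of the row-standardized
    mRNA expression over the signature genes.
    """
    shared = mrna_results.index.intersection(protein_results.index)
    if shared.empty:
        raise ValueError("no signature genes: empty mRNA/protein gene intersection")
    m = mrna_results.loc[shared]
    pr = protein_results.loc[shared]
    keep = (m["p"] < p_threshold) & (pr["p"] < p_threshold)
    if require_concordance:
        keep &= m["direction"] == pr["direction"]
    genes = tuple(shared[keep])
    if not genes:
        raise ValueError("no signature genes passed the dual-level screen")

    groups = groups.reindex(mrna_expr.values.columns)
    sub = mrna_expr.values.loc[list(genes)]
    z = standardize_rows(sub)
    centroid_good = z.loc[:, groups == "I"].mean(axis=1)
    centroid_bad = z.loc[:, groups == "II"].mean(axis=1)
    return TimeSignature(
        genes=genes,
        directions=m.loc[list(genes), "direction"].astype(int),
        centroid_good=centroid_good,
        centroid_bad=centroid_bad,
        metadata={
            "p_threshold": p_threshold,
            "require_concordance": require_concordance,
            "n_mrna_hits": int((mrna_results["p"] < p_threshold).sum()),
            "n_protein_hits": int((protein_results["p"] < p_threshold).sum()),
        },
    )


def standardize_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z scores; constant rows map to 0."""
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1).replace(0.0, np.nan)
    return values.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)


@dataclass
class SignatureCall:
    sample_id: str
    label: str
    score: float            # corr(good centroid) - corr(bad centroid)
    corr_good: float
    corr_bad: float


def classify_samples(
    signature: TimeSignature,
    expr: ExpressionMatrix,
    min_coverage: float = 0.5,
    alias: Mapping[str, str] | None = None,
) -> list[SignatureCall]:
    """Nearest-centroid good/bad classification of new samples.

    Expression gene ids may be mapped through an ``alias`` table (e.g.
    mouse -> human symbols); at least ``min_coverage`` of the signature
    genes must be present.  Each sample's profile over the available
    signature genes is standardized across genes and correlated (Pearson)
    with each centroid; ties break toward bad_TiME (conservative).
    """
    values = expr.values
    if alias:
        values = values.rename(index=dict(alias))
        values = values[~values.index.duplicated()]
    present = [g for g in signature.genes if g in values.index]
    coverage = len(present) / len(signature.genes)
    if coverage < min_coverage:
        missing = sorted(set(signature.genes) - set(present))
        raise ValueError(
            f"signature coverage {coverage:.2f} below floor {min_coverage}; "
            f"missing genes: {missing[:20]}{'...' if len(missing) > 20 else ''}"
        )
    sub = values.loc[present]
    good = signature.centroid_good.loc[present].to_numpy(dtype=float)
    bad = signature.centroid_bad.loc[present].to_numpy(dtype=float)
    calls = []
    for sample in sub.columns:
        profile = sub[sample].to_numpy(dtype=float)
        sd = profile.std(ddof=1) if len(profile) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0:
            sd = 1.0
        profile = (profile - profile.mean()) / sd
        cg = _pearson(profile, good)
        cb = _pearson(profile, bad)
        label = GOOD if cg > cb else BAD
        calls.append(
            SignatureCall(
                sample_id=str(sample), label=label,
                score=float(cg - cb), corr_good=float(cg), corr_bad=float(cb),
            )
        )
    return calls


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def calls_to_frame(calls: Sequence[SignatureCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": c.sample_id, "label": c.label, "score": c.score,
                "corr_good": c.corr_good, "corr_bad": c.corr_bad,
            }
            for c in calls
        ]
    )


def evaluate_auc(scores: Sequence[float], outcome: Sequence[int]) -> float:
    """ROC AUC of a continuous score for a binary outcome.

    Computed as the Mann-Whitney U statistic over positive/negative pairs
    divided by n1 * n0; tied scores count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome)
    if set(np.unique(y)) - {0, 1, True, False}:
        raise ValueError("outcome must be binary 0/1")
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both outcome classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))
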
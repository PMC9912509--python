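"""Arm-level copy-number calling, burden statistics, and survival analysis.

Arm gains and losses are called from GISTIC broad scores at a symmetric
cutoff (|score| >= 0.3 by default, inclusive), summarized as per-subgroup
alteration frequencies and per-sample burden counts, and related to
outcome through Kaplan–Meier curves compared with the log-rank
(Mantel–Cox) test.  A marker-arm burden association (e.g. do 6q-loss
tumors carry more arm losses genome-wide?) uses a two-sided rank-sum test
with the marker arm excluded from the burden count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "AUTOSOMAL_ARMS",
    "call_arms",
    "alteration_frequency",
    "burden",
    "burden_association",
    "km_logrank",
    "make_groups",
]

# canonical autosomal arm vocabulary: 1p..22q minus the acrocentric p-arms
# (13p, 14p, 15p, 21p, 22p carry no GISTIC broad score)
AUTOSOMAL_ARMS: tuple[str, ...] = tuple(
    f"{c}{arm}"
    for c in range(1, 23)
    for arm in ("p", "q")
    if not (arm == "p" and c in (13, 14, 15, 21, 22))
)

GAIN, LOSS, NEUTRAL = "gain", "loss", "neutral"


@dataclass(frozen=True)
class BurdenAssociation:
    """Rank-sum comparison of alteration burden by marker-arm status."""

    marker_arm: str
    direction: str
    n_marker: int
    n_other: int
    statistic: float
    p: float
    control_statistic: float  # same test on the opposite call type
    control_p: float


@dataclass
class KMLogrankResult:
    """Per-group Kaplan–Meier curves plus the log-rank comparison."""

    curves: dict[str, pd.DataFrame]  # group -> columns (time, survival)
    chi2: float
    p: float
    n_events: int


def call_arms(scores: pd.DataFrame, cutoff: float = 0.3) -> pd.DataFrame:
    """Threshold GISTIC broad scores into gain/loss/neutral calls.

    ``scores`` is samples x arms.  A score >= +cutoff is a gain and
    <= -cutoff a loss; the boundary value is called altered (inclusive).
    Idempotent and order-independent.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    vals = scores.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("arm scores must be finite")
    calls = np.where(vals >= cutoff, GAIN, np.where(vals <= -cutoff, LOSS, NEUTRAL))
    return pd.DataFrame(calls, index=scores.index, columns=scores.columns)


def alteration_frequency(
    calls: pd.DataFrame, subgroup: list[str] | pd.Index
) -> pd.DataFrame:
    """Per-arm fraction of subgroup samples gained and lost.

    Denominators are the subgroup size; gains and losses are reported in
    separate columns.
    """
    subgroup = list(subgroup)
    if not subgroup:
        raise ValueError("subgroup must be non-empty")
    sub = calls.loc[subgroup]
    return pd.DataFrame(
        {
            "frac_gain": (sub == GAIN).mean(axis=0),
            "frac_loss": (sub == LOSS).mean(axis=0),
        }
    )


def burden(
    calls: pd.DataFrame, focal_events: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-sample totals of arm gains/losses and focal amps/dels.

    ``focal_events`` is a long table with columns (sample, type) where
    type is 'amp' or 'del'; GISTIC focal output is consumed as-is, never
    recomputed.  An empty or absent focal table yields zero focal counts.
    """
    out = pd.DataFrame(
        {
            "arm_gains": (calls == GAIN).sum(axis=1),
            "arm_losses": (calls == LOSS).sum(axis=1),
        },
        index=calls.index,
    )
    out["focal_amps"] = 0
    out["focal_dels"] = 0
    if focal_events is not None and len(focal_events):
        counts = (
            focal_events.groupby(["sample", "type"]).size().unstack(fill_value=0)
        )
        for col, key in (("focal_amps", "amp"), ("focal_dels", "del")):
            if key in counts.columns:
                out[col] = counts[key].reindex(out.index).fillna(0).astype(int)
    return out


def burden_association(
    calls: pd.DataFrame,
    marker_arm: str = "6q",
    direction: str = LOSS,
) -> BurdenAssociation:
    """Test whether marker-arm-altered samples carry more alterations genome-wide.

    Samples are stratified by the marker arm's call (e.g. 6q loss vs not);
    per-sample counts of same-direction calls over the *other* arms are
    compared with a two-sided rank-sum test.  The opposite call type is
    tested identically as a negative control.
    """
    if direction not in (GAIN, LOSS):
        raise ValueError(f"direction must be 'gain' or 'loss', got {direction!r}")
    if marker_arm not in calls.columns:
        raise ValueError(f"marker arm {marker_arm!r} not in call matrix")
    marker_pos = calls[marker_arm] == direction
    if marker_pos.all() or not marker_pos.any():
        raise ValueError("both marker strata must be non-empty")
    rest = calls.drop(columns=[marker_arm])
    counts = (rest == direction).sum(axis=1)
    stat, p = stats.ranksums(counts[marker_pos], counts[~marker_pos])
    other = GAIN if direction == LOSS else LOSS
    counts_ctrl = (rest == other).sum(axis=1)
    c_stat, c_p = stats.ranksums(counts_ctrl[marker_pos], counts_ctrl[~marker_pos])
    return BurdenAssociation(
        marker_arm=marker_arm,
        direction=direction,
        n_marker=int(marker_pos.sum()),
        n_other=int((~marker_pos).sum()),
        statistic=float(stat),
        p=float(p),
        control_statistic=float(c_stat),
        control_p=float(c_p),
    )


def km_logrank(surv: pd.DataFrame) -> KMLogrankResult:
    """Kaplan–Meier curves per group and the log-rank (Mantel–Cox) test.

    ``surv`` needs columns ``time`` (months, >= 0), ``event`` (1 =
    died/progressed, 0 = censored) and a binary ``group`` label.  Requires
    exactly two groups and at least one event overall.
    """
    for col in ("time", "event", "group"):
        if col not in surv.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (surv["time"] < 0).any():
        raise ValueError("survival times must be >= 0")
    groups = sorted(surv["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")
    if int(surv["event"].sum()) == 0:
        raise ValueError("no events in the survival table")
    curves = {}
    for g in groups:
        sub = surv[surv["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    a = surv[surv["group"] == groups[0]]
    b = surv[surv["group"] == groups[1]]
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                       event_observed_B=b["event"])
    return KMLogrankResult(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        n_events=int(surv["event"].sum()),
    )


def make_groups(
    values: pd.Series | None = None,
    calls: pd.DataFrame | None = None,
    method: str = "arm_call",
    arm: str = "1q",
    direction: str = GAIN,
    quantile: float = 0.75,
) -> pd.Series:
    """Dichotomize samples for survival comparisons.

    Methods:

    * ``arm_call`` — positive iff the sample's ``arm`` call equals
      ``direction`` (e.g. 1q gain vs not; requires ``calls``).
    * ``quartile`` — positive iff ``values`` >= its ``quantile`` point
      (default top quartile, the split used for ACVR1-high tumors).
    * ``mean`` — positive iff ``values`` strictly exceeds its mean.

    Returns a boolean Series indexed by sample.
    """
    if method == "arm_call":
        if calls is None:
            raise ValueError("arm_call grouping requires a call matrix")
        out = calls[arm] == direction
    elif method == "quartile":
        if values is None:
            raise ValueError("quartile grouping requires values")
        out = values >= values.quantile(quantile)
    elif method == "mean":
        if values is None:
            raise ValueError("mean grouping requires values")
        out = values > values.mean()
    else:
        raise ValueError(f"unknown grouping method {method!r}")
    out.name = "group"
    return out.astype(bool)
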
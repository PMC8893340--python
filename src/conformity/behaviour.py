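"""Conformity statistics and the two mixed-effects revision models.

The analysis surface mirrors the task design: from a trial table it

* computes the circular revision/influence statistics and normalised
  confidence (:func:`annotate`),
* fits the pooled two-condition mixed model (:func:`fit_lmm1`) — fixed
  effects of normalised confidence c, previous-trial influence inf, a
  condition dummy (1 = human, 2 = computer) and all interactions, with a
  per-participant random intercept and random confidence slope,
* fits the per-condition model (:func:`fit_lmm2`) — c, inf and c x inf,
  with random intercept and random c and inf slopes and a fixed
  interaction,
* computes sliding-window revision dynamics and Wilcoxon signed-rank
  tests with Holm-Bonferroni correction.

Both models are estimated by REML with Satterthwaite denominator
degrees of freedom (see :mod:`conformity.mixed`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .circular import shift_fraction
from .mixed import MixedFit, fit_mixed

__all__ = [
    "annotate",
    "fit_lmm1",
    "fit_lmm2",
    "sliding_window_revision",
    "signed_rank",
    "holm_adjust",
    "TestResult",
    "DegenerateTestError",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "participant_id",
    "block",
    "trial_index",
    "role",
    "condition",
    "confidence",
    "target",
    "self_initial",
    "partner_initial",
    "reviser_final",
)


class DegenerateTestError(ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


@dataclass
class TestResult:
    """A Wilcoxon signed-rank result: W = sum of positive ranks."""

    statistic: float
    p: float
    n: int
    description: str = ""


def annotate(trials: pd.DataFrame) -> pd.DataFrame:
    """Compute the analysis columns from raw trial angles.

    Adds ``revision_stat`` (revision trials), ``influence_stat``
    (observation trials), ``conf_norm`` = confidence / 6, ``cond`` (1 =
    human, 2 = computer) and ``prev_influence`` (each revision trial gets
    the influence statistic of the immediately preceding observation
    trial of the same block).  Trials whose statistic is undefined
    because the two initial estimates coincide are dropped (count
    logged).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table is missing required columns: {missing}")
    out = trials.copy()
    revise = out["role"].to_numpy() == "revise"
    observe = out["role"].to_numpy() == "observe"
    if not np.all(revise | observe):
        raise ValueError("role column must be 'observe' or 'revise'")

    stat = np.full(len(out), np.nan)
    stat[revise] = shift_fraction(
        out.loc[revise, "self_initial"].to_numpy(),
        out.loc[revise, "reviser_final"].to_numpy(),
        out.loc[revise, "partner_initial"].to_numpy(),
    )
    out["revision_stat"] = np.where(revise, stat, np.nan)
    stat2 = np.full(len(out), np.nan)
    stat2[observe] = shift_fraction(
        out.loc[observe, "partner_initial"].to_numpy(),
        out.loc[observe, "reviser_final"].to_numpy(),
        out.loc[observe, "self_initial"].to_numpy(),
    )
    out["influence_stat"] = np.where(observe, stat2, np.nan)
    out["conf_norm"] = out["confidence"].to_numpy() / 6.0
    out["cond"] = np.where(out["condition"].to_numpy() == "human", 1.0, 2.0)

    out = out.sort_values(["participant_id", "block", "trial_index"], kind="stable")
    prev = out.groupby(["participant_id", "block"], sort=False)["influence_stat"].shift(1)
    out["prev_influence"] = np.where(out["role"] == "revise", prev, np.nan)

    undefined = (revise & ~np.isfinite(out["revision_stat"].to_numpy())) | (
        observe & ~np.isfinite(out["influence_stat"].to_numpy())
    )
    n_drop = int(undefined.sum())
    if n_drop:
        logger.info("annotate: dropping %d trial(s) with zero initial disagreement", n_drop)
        out = out.loc[~undefined]
    return out.reset_index(drop=True)


def _revision_frame(table: pd.DataFrame) -> pd.DataFrame:
    sub = table[table["role"] == "revise"].copy()
    keep = np.isfinite(sub["revision_stat"]) & np.isfinite(sub["prev_influence"])
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("model fit: dropping %d revision trial(s) with missing lagged influence", n_drop)
    return sub.loc[keep]


def fit_lmm1(table: pd.DataFrame, dof: str = "satterthwaite") -> MixedFit:
    """Pooled two-condition revision model on an annotated trial table.

    Fixed effects: intercept, c, inf, cond, c:inf, c:cond, inf:cond,
    c:inf:cond, with the condition dummy coded 1 = human, 2 = computer.
    Random structure: per-participant intercept and confidence slope.
    Raw p-values are joined by Holm-adjusted ones (family = the model's
    non-intercept fixed effects).
    """
    sub = _revision_frame(table)
    if sub["cond"].nunique() < 2:
        raise ValueError("fit_lmm1 needs both human and computer conditions present")
    fit = fit_mixed(
        sub,
        response="revision_stat",
        fixed=[
            (),
            ("conf_norm",),
            ("prev_influence",),
            ("cond",),
            ("conf_norm", "prev_influence"),
            ("conf_norm", "cond"),
            ("prev_influence", "cond"),
            ("conf_norm", "prev_influence", "cond"),
        ],
        random_slopes=["conf_norm"],
        group="participant_id",
        dof=dof,
    )
    _attach_holm(fit)
    return fit


def fit_lmm2(table: pd.DataFrame, condition: str, dof: str = "satterthwaite") -> MixedFit:
    """Single-condition revision model (c, inf, c:inf) for one partner type.

    Random structure: per-participant intercept plus confidence and
    influence slopes; the interaction is a fixed effect only (the full
    random structure is over-parameterised at this design size).
    """
    if condition not in ("human", "computer"):
        raise ValueError(f"condition must be 'human' or 'computer', got {condition!r}")
    sub = _revision_frame(table)
    sub = sub[sub["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no revision trials for condition {condition!r}")
    fit = fit_mixed(
        sub,
        response="revision_stat",
        fixed=[(), ("conf_norm",), ("prev_influence",), ("conf_norm", "prev_influence")],
        random_slopes=["conf_norm", "prev_influence"],
        group="participant_id",
        dof=dof,
    )
    _attach_holm(fit)
    return fit


def _attach_holm(fit: MixedFit) -> None:
    mask = fit.terms.index != "intercept"
    adj = np.full(len(fit.terms), np.nan)
    adj[mask] = holm_adjust(fit.terms.loc[mask, "p"].to_numpy())
    fit.terms["p_holm"] = adj


def sliding_window_revision(
    table: pd.DataFrame, window: int = 5, step: int = 1
) -> pd.DataFrame:
    """Mean revision in sliding windows of revision trials.

    Windows of ``window`` consecutive revision trials advancing by
    ``step``, computed per participant x condition x susceptibility (a
    block, under the default design).  Returns a long frame with columns
    participant_id / condition / susceptibility / window_index /
    mean_revision; groups with fewer than ``window`` revision trials
    yield no rows (with a warning).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    sub = table[table["role"] == "revise"].sort_values(
        ["participant_id", "block", "trial_index"], kind="stable"
    )
    rows = []
    short = 0
    for (pid, cond, susc), g in sub.groupby(
        ["participant_id", "condition", "susceptibility"], sort=False
    ):
        r = g["revision_stat"].to_numpy()
        if r.size < window:
            short += 1
            continue
        for w, start in enumerate(range(0, r.size - window + 1, step)):
            rows.append((pid, cond, susc, w, np.nanmean(r[start : start + window])))
    if short:
        warnings.warn(
            f"{short} participant-condition group(s) had fewer than {window} revision trials",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "condition", "susceptibility", "window_index", "mean_revision"],
    )


def signed_rank(x, y=None, mu: float = 0.0, description: str = "") -> TestResult:
    """Two-sided Wilcoxon signed-rank test (paired, or one sample vs ``mu``).

    The reported statistic is W+, the sum of ranks of positive
    differences.  P-values are exact for n <= 25 without ties, otherwise
    from the normal approximation with continuity correction.  Zero
    differences are discarded; if all are zero the test is degenerate and
    :class:`DegenerateTestError` is raised.
    """
    x = np.asarray(x, float)
    d = x - (np.asarray(y, float) if y is not None else mu)
    d = d[np.isfinite(d)]
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero (or missing)")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), alternative="two-sided",
        method=method,
    )
    return TestResult(statistic=w_plus, p=float(res.pvalue), n=n, description=description)


def holm_adjust(pvals) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if not np.all(np.isfinite(p)):
        raise ValueError("p-values must be finite")
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]
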
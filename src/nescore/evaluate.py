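"""Performance metrics for risk scores: discrimination, concordance,
correlation, and survival stratification.

Orientation convention: higher score = higher risk everywhere. A C-index
below 0.5 is reported as-is, never flipped — silent flipping hides sign
bugs in the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .containers import ValidationError


@dataclass
class EvalReport:
    name: str = ""
    auc: float | None = None
    c_index: float | None = None
    pearson_r: float | None = None
    pearson_p: float | None = None
    spearman_r: float | None = None
    spearman_p: float | None = None
    logrank_chi2: float | None = None
    logrank_p: float | None = None
    group_sizes: tuple[int, int] | None = None
    higher_score_higher_risk: bool = True
    extras: dict = field(default_factory=dict)


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney U statistic / (n_pos * n_neg); ties count 0.5."""
    s = _as_array(scores, "scores")
    y = np.asarray(labels)
    if set(np.unique(y)) - {0, 1, True, False}:
        raise ValidationError("labels must be binary 0/1")
    y = y.astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")
    ranks = stats.rankdata(s)  # average ranks give the 0.5 tie credit
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def concordance_index(
    scores: Sequence[float], time: Sequence[float], event: Sequence[int]
) -> float:
    """Harrell's C for a risk score (higher score should mean earlier event).

    A pair is comparable when the earlier time belongs to a subject with an
    event; the pair is concordant when that subject also has the higher
    score. Score ties count 0.5. With every subject experiencing an event
    at a common time against binary labels this reduces to roc_auc.
    """
    s = _as_array(scores, "scores")
    t = _as_array(time, "time")
    e = np.asarray(event).astype(int)
    if set(np.unique(e)) - {0, 1}:
        raise ValidationError("event flags must be 0/1")
    n = len(s)
    # comparable: t_i < t_j with event at i (or tied times, event i, censored j)
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None].astype(bool), e[None, :].astype(bool)
    comparable = (ti < tj) & ei
    comparable |= (ti == tj) & ei & ~ej
    si, sj = s[:, None], s[None, :]
    concordant = comparable & (si > sj)
    tied = comparable & (si == sj)
    n_comp = comparable.sum()
    if n_comp == 0:
        raise ValidationError("no comparable pair (all censored or single subject)")
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def correlate(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if len(xa) < 3:
        raise ValidationError("need n >= 3 for a correlation test")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise ValidationError("zero variance input")
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def km_logrank(
    scores: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    split: Literal["median"] | float = "median",
) -> EvalReport:
    """Two-group Kaplan-Meier comparison after a risk-score split.

    ``split='median'`` assigns scores <= median (ties included) to the
    low-risk group; a float splits at that cutpoint instead. Returns the
    1-df log-rank chi-square and p, with the per-group KM step functions
    in ``extras`` for plotting.
    """
    s = _as_array(scores, "scores")
    t = _as_array(time, "time")
    e = np.asarray(event).astype(int)
    cut = float(np.median(s)) if split == "median" else float(split)
    high = s > cut  # ties go to the low-risk group
    if high.all() or not high.any():
        raise ValidationError("degenerate split: one group is empty")
    res = logrank_test(t[high], t[~high], event_observed_A=e[high], event_observed_B=e[~high])
    report = EvalReport(
        logrank_chi2=float(res.test_statistic),
        logrank_p=float(res.p_value),
        group_sizes=(int((~high).sum()), int(high.sum())),
    )
    curves = {}
    for label, mask in (("low", ~high), ("high", high)):
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=label)
        curves[label] = kmf.survival_function_
    report.extras["km_curves"] = curves
    report.extras["cutpoint"] = cut
    return report


def compare_signatures(
    expr,
    signatures,
    labels: Sequence[int],
    method: str = "ssgsea",
    **score_kwargs,
) -> pd.DataFrame:
    """Score each signature on the same matrix and rank by AUC.

    Ties are broken deterministically by signature name; a signature that
    fails to score (or evaluate) gets an ``error`` entry instead of
    aborting the comparison.
    """
    from .scoring import score_many  # local import avoids a cycle

    if len(signatures) < 2:
        raise ValidationError("need >=2 signatures to compare")
    if len(np.unique(np.asarray(labels))) < 2:
        raise ValidationError("labels are single-class; AUC is undefined")
    tables, failures = score_many(expr, signatures, method=method, **score_kwargs)
    rows = []
    for sig in signatures:
        if sig.name in failures:
            rows.append({"signature": sig.name, "auc": np.nan, "error": failures[sig.name]})
            continue
        try:
            auc = roc_auc(tables[sig.name].risk.to_numpy(), labels)
            rows.append({"signature": sig.name, "auc": auc, "error": ""})
        except ValidationError as exc:
            rows.append({"signature": sig.name, "auc": np.nan, "error": str(exc)})
    df = pd.DataFrame(rows)
    df = df.sort_values(["auc", "signature"], ascending=[False, True], na_position="last")
    return df.reset_index(drop=True)
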
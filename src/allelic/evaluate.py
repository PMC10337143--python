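"""Benchmark scoring: FDR/TPR against simulation truth and bootstrap-interval
coverage.

Calls made at gene or TSS level are propagated to the member transcripts
(a transcript counts as called iff its group is called), so methods at
different aggregation levels are compared on a common transcript-level
footing.  Sensitivity is reported overall and stratified by AI type
(concordant vs discordant within gene).

Interval coverage follows the normal-approximation recipe: for every
feature/sample/allele the 95% interval is the bootstrap mean plus or minus
the 97.5% normal quantile (1.959964) times the bootstrap standard
deviation; a cell is covered iff the true simulated count lies inside.
Rates are summarized as mean and SD across samples, within expression
tertiles defined on the true counts pooled over samples.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .grouping import GroupMap
from .inference import AIResults
from .matrix import AllelicMatrix

__all__ = [
    "propagate_calls",
    "fdr_tpr",
    "bootstrap_coverage",
    "confusion_counts",
]

Z975 = 1.959964  # 97.5% quantile of the standard normal


def propagate_calls(
    results: AIResults,
    group_map: Optional[GroupMap],
    alpha: float,
) -> set:
    """Transcript-level call set at a q-value cutoff.

    Transcript-level results pass through unchanged (``group_map=None`` or a
    map whose groups are the transcripts themselves is unnecessary).  For
    gene- or TSS-level results, every member transcript of a called group is
    called.
    """
    called_groups = results.significant(alpha)
    if results.level == "txp" or group_map is None:
        return set(called_groups)
    known = set(group_map.groups)
    missing = [g for g in results.table["feature_id"] if g not in known]
    if missing:
        raise KeyError(f"result features absent from group map: {missing[:5]}")
    out: set = set()
    for g in called_groups:
        out.update(group_map.members(g))
    return out


def confusion_counts(
    calls: set, positives: set, universe: Iterable
) -> tuple[int, int, int]:
    """(TP, FP, P) over the evaluation universe."""
    tp = fp = npos = 0
    for f in universe:
        pos = f in positives
        called = f in calls
        npos += pos
        tp += called and pos
        fp += called and not pos
    return tp, fp, npos


def fdr_tpr(
    calls: set,
    truth: pd.DataFrame,
    universe: Optional[Iterable] = None,
) -> pd.Series:
    """Observed FDR and TPR (overall + per AI stratum) of a call set.

    ``truth`` is the simulator truth table (columns tx_id, status).  The
    evaluation universe defaults to every transcript in the truth table;
    pass the filtered feature list to restrict to expressed transcripts.
    Conventions: FDR = FP / max(1, FP + TP) (empty call set has FDR 0);
    TPR = TP / P.
    """
    universe = list(universe) if universe is not None else truth["tx_id"].tolist()
    status = dict(zip(truth["tx_id"], truth["status"]))
    positives = {t for t in universe if status.get(t, "balanced") != "balanced"}
    tp, fp, npos = confusion_counts(calls, positives, universe)
    out = {
        "TP": tp,
        "FP": fp,
        "P": npos,
        "FDR": fp / max(1, fp + tp),
        "TPR": tp / npos if npos else 0.0,
    }
    for stratum in ("concordant", "discordant"):
        strat_pos = {t for t in positives if status[t] == stratum}
        stp = len(calls & strat_pos)
        out[f"TPR_{stratum}"] = stp / len(strat_pos) if strat_pos else np.nan
    return pd.Series(out)


def _tertile_bins(pooled_truth: np.ndarray) -> np.ndarray:
    """Low/medium/high tertile index per feature, ties broken by rank."""
    order = np.argsort(pooled_truth, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(pooled_truth.size)
    return np.minimum((3 * ranks) // pooled_truth.size, 2)


def bootstrap_coverage(
    m: AllelicMatrix,
    truth_counts: np.ndarray,
    b_sub: Optional[int] = None,
    tertiles: bool = True,
) -> pd.DataFrame:
    """Coverage of 95% normal-approximation bootstrap intervals.

    Uses the first ``b_sub`` replicates (default: all; must be >= 2 so the
    SD is defined).  ``truth_counts`` has shape (F, S, 2) aligned to the
    matrix.  Returns one row per expression tertile plus an "overall" row,
    with the mean and SD across samples of the per-sample coverage rate.
    """
    B = m.n_bootstraps if b_sub is None else b_sub
    if B < 2:
        raise ValueError("need >= 2 bootstrap replicates for an interval")
    if B > m.n_bootstraps:
        raise ValueError("b_sub exceeds available replicates")
    truth_counts = np.asarray(truth_counts, dtype=float)
    if truth_counts.shape != m.counts.shape:
        raise ValueError("truth_counts shape mismatch")
    boot = m.bootstraps[:B]
    mean = boot.mean(axis=0)
    sd = boot.std(axis=0, ddof=1)
    lo, hi = mean - Z975 * sd, mean + Z975 * sd
    covered = (truth_counts >= lo) & (truth_counts <= hi)  # (F, S, 2)

    pooled = truth_counts.sum(axis=(1, 2))
    bins = _tertile_bins(pooled)
    rows = []
    labels = ["low", "medium", "high"]
    for t, label in enumerate(labels):
        sel = bins == t
        if not sel.any():
            rows.append((label, np.nan, np.nan, 0))
            continue
        per_sample = covered[sel].mean(axis=(0, 2))  # (S,)
        rows.append((label, per_sample.mean(), per_sample.std(ddof=1), int(sel.sum())))
    per_sample_all = covered.mean(axis=(0, 2))
    rows.append(("overall", per_sample_all.mean(), per_sample_all.std(ddof=1), m.n_features))
    out = pd.DataFrame(rows, columns=["tertile", "coverage", "coverage_sd", "n_features"])
    out.insert(0, "level", m.level)
    out.insert(1, "B", B)
    if not tertiles:
        out = out[out["tertile"] == "overall"].reset_index(drop=True)
    return out
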
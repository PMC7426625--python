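"""Quality control: fast-responder exclusion and rater-consistency analysis.

Raters whose mean response time over a task falls below one second are
excluded (their judgments were found to be effectively random).  Consistency
is quantified per set x attribute cell by

* the intra-observer correlation: for each rater, the mean Pearson r over the
  three repetition-vector pairs (vectors across the set's stimuli), averaged
  over raters; and
* the inter-observer correlation: Pearson r between every pair of raters'
  repetition-averaged rating vectors, averaged over pairs.

Both estimators ignore pairs with a zero-variance vector (logged warning).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import StudyDesign

logger = logging.getLogger(__name__)

#: Columns identifying one task (one rater rating one set on one attribute).
TASK_KEY = ["rater_id", "set_id", "attribute"]


@dataclass(frozen=True)
class SignificanceLine:
    """Critical Pearson r for a given df and alpha level."""

    df: int
    alpha: float
    one_sided: bool
    r_crit: float


def exclude_fast_raters(
    records: pd.DataFrame, threshold_s: float = 1.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop all records of tasks whose mean response time is strictly below the threshold.

    Exclusion is per task, not per participant: a rater excluded in one cell
    may be retained in another.

    Returns
    -------
    (kept, excluded) — kept records, and a frame of the excluded tasks with
    columns ``rater_id, set_id, attribute, mean_rt``.
    """
    if records.empty:
        return records.copy(), pd.DataFrame(columns=TASK_KEY + ["mean_rt"])
    mean_rt = records.groupby(TASK_KEY, sort=False)["response_time_s"].mean()
    bad = mean_rt[mean_rt < threshold_s].rename("mean_rt").reset_index()
    if bad.empty:
        return records.copy(), bad
    keyed = records.set_index(TASK_KEY).index
    bad_keys = set(map(tuple, bad[TASK_KEY].itertuples(index=False)))
    keep_mask = ~np.array([k in bad_keys for k in keyed])
    logger.info("excluded %d fast tasks (%d records)", len(bad), int((~keep_mask).sum()))
    return records[keep_mask].reset_index(drop=True), bad


def _pairwise_r(vectors: np.ndarray, what: str) -> float | None:
    """Mean Pearson r over all row pairs; zero-variance rows are skipped."""
    rs = []
    for i, j in itertools.combinations(range(vectors.shape[0]), 2):
        a, b = vectors[i], vectors[j]
        ok = np.isfinite(a) & np.isfinite(b)
        a, b = a[ok], b[ok]
        if len(a) < 3 or a.std() == 0 or b.std() == 0:
            logger.warning("skipping constant/short %s pair (%d, %d)", what, i, j)
            continue
        rs.append(np.corrcoef(a, b)[0, 1])
    if not rs:
        return None
    return float(np.mean(rs))


def _rep_matrix(cell: pd.DataFrame) -> pd.DataFrame:
    """stimulus x (rater, repetition) value table for one cell."""
    return cell.pivot_table(index="stimulus_id", columns=["rater_id", "repetition"],
                            values="value", aggfunc="mean")


def intra_observer_r(cell: pd.DataFrame) -> float:
    """Mean within-rater repetition correlation for one set x attribute cell.

    Per rater, Pearson r is computed for every pair of repetition vectors
    (length = set size) and averaged; rater means are then averaged.
    """
    table = _rep_matrix(cell)
    per_rater = []
    for rater in table.columns.get_level_values(0).unique():
        reps = table[rater].to_numpy().T        # repetitions x stimuli
        if reps.shape[0] < 2:
            continue
        r = _pairwise_r(reps, f"repetition ({rater})")
        if r is not None:
            per_rater.append(r)
    if not per_rater:
        raise ValueError("intra-observer correlation undefined: no usable repetition pairs")
    return float(np.mean(per_rater))


def inter_observer_r(cell: pd.DataFrame, vectors: str = "stimuli") -> float:
    """Mean between-rater correlation for one set x attribute cell.

    ``vectors="stimuli"`` (default): each rater's ratings are averaged over
    repetitions into a vector across the set's stimuli; Pearson r over every
    rater pair (45 pairs for 10 raters) is averaged.

    ``vectors="raters"``: the transposed construction — length-``n_raters``
    vectors per stimulus, correlated over stimulus pairs.  Provided because
    published significance lines for the between-rater axis sometimes assume
    vectors of length n_raters (df = n_raters - 2).
    """
    table = _rep_matrix(cell)
    rep_mean = table.T.groupby(level=0).mean()   # rater x stimulus
    mat = rep_mean.to_numpy()
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 raters")
    if vectors == "stimuli":
        r = _pairwise_r(mat, "rater")
    elif vectors == "raters":
        r = _pairwise_r(mat.T, "stimulus")
    else:
        raise ValueError("vectors must be 'stimuli' or 'raters'")
    if r is None:
        raise ValueError("inter-observer correlation undefined: all pairs degenerate")
    return r


def critical_r(df: int, alpha: float = 0.05, one_sided: bool = True) -> SignificanceLine:
    """Critical Pearson correlation at the given t-distribution significance level.

    r_crit = t / sqrt(t^2 + df) with t the (1 - alpha) (or 1 - alpha/2)
    quantile of Student's t at ``df`` degrees of freedom.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = 1 - alpha if one_sided else 1 - alpha / 2
    t = sps.t.ppf(q, df)
    r = float(t / np.sqrt(t**2 + df))
    return SignificanceLine(df=df, alpha=alpha, one_sided=one_sided, r_crit=r)


def consistency_table(records: pd.DataFrame, design: StudyDesign,
                      inter_vectors: str = "stimuli") -> pd.DataFrame:
    """Intra/inter-observer correlations for every set x attribute cell.

    Returns n_sets x n_attributes rows with columns
    ``set_id, attribute, intra_r, inter_r, n_raters``.  Raises if any cell of
    the design has no records (missing cells are an error, not silently skipped).
    """
    rows = []
    grouped = dict(tuple(records.groupby(["set_id", "attribute"], sort=False)))
    missing = []
    for set_id in range(1, design.n_sets + 1):
        for attr in design.attributes:
            cell = grouped.get((set_id, attr))
            if cell is None or cell.empty:
                missing.append((set_id, attr))
                continue
            rows.append({
                "set_id": set_id,
                "attribute": attr,
                "intra_r": intra_observer_r(cell),
                "inter_r": inter_observer_r(cell, vectors=inter_vectors),
                "n_raters": cell["rater_id"].nunique(),
            })
    if missing:
        raise ValueError(f"missing set/attribute cells: {missing}")
    return pd.DataFrame(rows, columns=["set_id", "attribute", "intra_r", "inter_r", "n_raters"])
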
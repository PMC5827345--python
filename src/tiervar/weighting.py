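"""Weighted combination of the three callers and evalue optimization.

Each caller i gets a raw value v_i on the grid {0, 0.1, ..., 1.0};
weights are w_i = v_i / sum_j v_j.  Two scoring experiments:

* binary — s = sum_i w_i * c_i over the 0/1 call vector;
* vaf    — s = sum_i w_i * (vaf_i - mean_i) / sd_i, i.e. each caller's
  reported VAF z-scored to its own dynamic range.

The objective is the *evalue*: the sum of false-positive and
false-negative counts of the thresholded score against a truth set
(unrelated to BLAST E-values).  The optimal threshold minimizes the
evalue; in binary mode the search runs over the achievable scores, in
vaf mode over a fixed grid on [-3, 3].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

from .consensus import MembershipTable
from .variant_model import VariantKey

V_GRID = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class WeightVector:
    """Raw grid values v and their normalized weights w (sum 1)."""

    v: tuple[float, float, float]
    w: tuple[float, float, float]


def normalize_weights(v: Sequence[float]) -> WeightVector:
    """w_i = v_i / sum_j v_j; rejects the all-zero triple."""
    if len(v) != 3:
        raise ValueError("exactly three raw values required")
    total = float(sum(v))
    if total <= 0.0:
        raise ValueError("all-zero weight triple is not normalizable")
    if any(x < 0 for x in v):
        raise ValueError("raw values must be non-negative")
    w = tuple(float(x) / total for x in v)
    return WeightVector(tuple(float(x) for x in v), w)  # type: ignore[arg-type]


@dataclass(frozen=True)
class CallerVafStats:
    """Per-caller mean and standard deviation of reported VAFs."""

    means: tuple[float, float, float]
    sds: tuple[float, float, float]


def compute_vaf_stats(
    mt: MembershipTable,
    universe: Iterable[VariantKey] | None = None,
    *,
    population: Literal["called", "union_zero"] = "called",
) -> CallerVafStats:
    """Estimate each caller's VAF mean/sd over the evaluation universe.

    ``population='called'`` uses only the VAFs the caller reported
    (variants it called); ``'union_zero'`` imputes 0 for uncalled
    variants first.  Missing reported VAFs count as 0.
    """
    if universe is not None:
        uni = set(universe)
        keys = [k for k in mt.rows if k in uni]
    else:
        keys = list(mt.rows)
    means, sds = [], []
    for i in range(3):
        if population == "called":
            vals = [
                (mt.rows[k].vafs[i] or 0.0)
                for k in keys
                if mt.rows[k].called[i]
            ]
        else:
            vals = [
                (mt.rows[k].vafs[i] or 0.0) if mt.rows[k].called[i] else 0.0
                for k in keys
            ]
        arr = np.asarray(vals, dtype=float)
        means.append(float(arr.mean()) if arr.size else 0.0)
        sds.append(float(arr.std(ddof=1)) if arr.size > 1 else 0.0)
    return CallerVafStats(tuple(means), tuple(sds))  # type: ignore[arg-type]


def score_binary(w: WeightVector, c: Sequence[bool]) -> float:
    """s = sum_i w_i * c_i  in [0, 1]."""
    return float(sum(wi * float(ci) for wi, ci in zip(w.w, c)))


def score_vaf(
    w: WeightVector,
    vaf_triple: Sequence[float | None],
    stats: CallerVafStats,
) -> float:
    """s = sum_i w_i * (vaf_i - mean_i) / sd_i; missing vaf_i -> 0."""
    s = 0.0
    for wi, vi, mi, si in zip(w.w, vaf_triple, stats.means, stats.sds):
        if wi == 0.0:
            continue
        if si <= 0.0:
            raise ValueError(
                "caller with positive weight has zero VAF standard deviation"
            )
        s += wi * (((vi if vi is not None else 0.0) - mi) / si)
    return float(s)


@dataclass(frozen=True)
class EvalCounts:
    """TP/FP/FN(/TN) contingency with the derived rates.

    ``evalue = fp + fn`` always.  Precision/recall are NaN (flagged via
    :attr:`precision_defined` / :attr:`recall_defined`) when their
    denominator is zero.
    """

    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def evalue(self) -> int:
        return self.fp + self.fn

    @property
    def precision_defined(self) -> bool:
        return self.tp + self.fp > 0

    @property
    def recall_defined(self) -> bool:
        return self.tp + self.fn > 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.precision_defined else math.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.recall_defined else math.nan

    @property
    def fn_rate(self) -> float:
        return self.fn / (self.tp + self.fn) if self.recall_defined else math.nan


def counts_at_threshold(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> EvalCounts:
    """Contingency for the rule call := (score >= threshold)."""
    called = scores >= threshold
    tp = int(np.sum(called & labels))
    fp = int(np.sum(called & ~labels))
    fn = int(np.sum(~called & labels))
    tn = int(np.sum(~called & ~labels))
    return EvalCounts(tp, fp, fn, tn)


def optimize_threshold(
    scores: Sequence[float],
    truth_labels: Sequence[bool],
    mode: Literal["binary", "vaf"] = "binary",
    *,
    step: float = 0.01,
    lo: float = -3.0,
    hi: float = 3.0,
) -> tuple[float, EvalCounts]:
    """Threshold minimizing the evalue; ties broken by smallest threshold.

    Binary mode searches the finite set of achievable scores; vaf mode
    a fixed-step grid on [lo, hi].
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth_labels, dtype=bool)
    if s.size == 0 or s.size != y.size:
        raise ValueError("scores and labels must be non-empty and aligned")
    if mode == "binary":
        candidates = np.unique(s)
    elif mode == "vaf":
        n_steps = int(round((hi - lo) / step))
        candidates = lo + step * np.arange(n_steps + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # vectorized evalue over the candidate grid
    called = s[None, :] >= candidates[:, None]
    fp = np.sum(called & ~y[None, :], axis=1)
    fn = np.sum(~called & y[None, :], axis=1)
    ev = fp + fn
    best = int(np.argmin(ev))  # argmin takes the first (smallest threshold) on ties
    thr = float(candidates[best])
    return thr, counts_at_threshold(s, y, thr)


def pr_metrics(
    scores: Sequence[float], truth_labels: Sequence[bool]
) -> tuple[pd.DataFrame, float]:
    """Precision-recall curve and its area (step-wise integration).

    The area is the average-precision form sum_k (R_k - R_{k-1}) P_k,
    i.e. a right-constant step integral rather than the optimistic
    trapezoid.
    """
    y = np.asarray(truth_labels, dtype=bool)
    if not y.any():
        raise ValueError("pr_metrics requires at least one positive label")
    s = np.asarray(scores, dtype=float)
    precision, recall, thresholds = precision_recall_curve(y, s)
    auprc = float(average_precision_score(y, s))
    curve = pd.DataFrame(
        {
            "threshold": np.append(thresholds, np.nan),
            "precision": precision,
            "recall": recall,
        }
    )
    return curve, auprc


@dataclass
class GridResult:
    """Full weight-grid sweep; ``table`` has one row per distinct w."""

    table: pd.DataFrame
    n_raw: int
    mode: str

    @property
    def best(self) -> pd.DataFrame:
        m = self.table["evalue"].min()
        return self.table[self.table["evalue"] == m]

    @property
    def n_collapsed(self) -> int:
        return len(self.table)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enumerate_weight_grid() -> dict[tuple[float, float, float], list[tuple[float, float, float]]]:
    """All 11^3 - 1 raw v-triples, grouped by their normalized weight.

    Returns mapping w (rounded to 10 dp) -> list of raw v provenance.
    """
    groups: dict[tuple[float, float, float], list[tuple[float, float, float]]] = {}
    for v in product(V_GRID, repeat=3):
        if sum(v) == 0:
            continue
        wv = normalize_weights(v)
        wkey = tuple(round(x, 10) for x in wv.w)
        groups.setdefault(wkey, []).append(v)  # type: ignore[arg-type]
    return groups


def grid_search(
    mt: MembershipTable,
    truth: set[VariantKey],
    mode: Literal["binary", "vaf"] = "binary",
    *,
    universe: set[VariantKey] | None = None,
    stats: CallerVafStats | None = None,
    threshold_step: float = 0.01,
    stats_population: Literal["called", "union_zero"] = "called",
) -> GridResult:
    """Sweep every weight combination and optimize the threshold for each.

    The evaluation universe defaults to the union of all called
    variants and the truth set (so a truth variant nobody called is a
    false negative at any positive threshold).  Duplicate normalized
    weight vectors from different raw triples are collapsed, keeping
    the raw triples as provenance.
    """
    if universe is None:
        universe = set(mt.rows) | set(truth)
    keys = sorted(universe)
    labels = np.array([k in truth for k in keys], dtype=bool)
    called = np.array(
        [mt.rows[k].called if k in mt.rows else (False, False, False) for k in keys],
        dtype=float,
    )
    if mode == "vaf":
        if stats is None:
            stats = compute_vaf_stats(mt, universe, population=stats_population)
        vafs = np.array(
            [
                [
                    (mt.rows[k].vafs[i] or 0.0) if k in mt.rows and mt.rows[k].called[i] else 0.0
                    for i in range(3)
                ]
                for k in keys
            ],
            dtype=float,
        )
        sds = np.asarray(stats.sds)
        means = np.asarray(stats.means)

    groups = enumerate_weight_grid()
    rows = []
    for wkey in sorted(groups):
        wv = WeightVector(groups[wkey][0], wkey)
        w_arr = np.asarray(wkey)
        if mode == "binary":
            scores = called @ w_arr
        else:
            active = w_arr > 0
            if np.any(active & (sds <= 0)):
                raise ValueError(
                    "caller with positive weight has zero VAF standard deviation"
                )
            z = np.zeros_like(vafs)
            z[:, active] = (vafs[:, active] - means[active]) / sds[active]
            scores = z @ w_arr
        thr, counts = optimize_threshold(
            scores, labels, mode, step=threshold_step
        )
        try:
            _, auprc = pr_metrics(scores, labels)
        except ValueError:
            auprc = math.nan
        rows.append(
            {
                "w_s": wkey[0], "w_r": wkey[1], "w_m": wkey[2],
                "n_raw_v": len(groups[wkey]),
                "threshold": thr,
                "evalue": counts.evalue,
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
                "precision": counts.precision,
                "recall": counts.recall,
                "auprc": auprc,
            }
        )
    table = pd.DataFrame(rows)
    n_raw = sum(len(v) for v in groups.values())
    return GridResult(table=table, n_raw=n_raw, mode=mode)
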
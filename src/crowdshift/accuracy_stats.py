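"""Accuracy measures, bootstrap uncertainty and comparison analyses.

Collective accuracy is |median(X)| — how far the group's median
log-deviation sits from the truth; individual accuracy is median(|X|) — the
typical distance of a single estimate from the truth. Both are 0 at best.
Uncertainty comes from a bootstrap over questions: a resampled experiment
redraws N_Q questions with replacement and carries *all* records of each
drawn question, which preserves the within-question correlation structure.
Error bars are asymmetric 68.3% intervals of the bootstrap distribution and
claims are scored by p0, the bootstrap probability that the opposite of the
claim holds. Improvements are always assessed on paired per-replicate
differences (the same question resample on both sides), never by comparing
overlapping error bars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._common import DomainError, as_generator
from .s_analysis import S_CLIP

DEFAULT_CONF = 0.683


def collective_accuracy(X_values) -> float:
    """|median(X)| over all records (even counts: mean of the two central
    order statistics)."""
    X = np.asarray(X_values, float)
    if X.size == 0:
        raise DomainError("collective_accuracy of an empty sample")
    return float(abs(np.median(X)))


def individual_accuracy(X_values) -> float:
    """median(|X|) over all records."""
    X = np.asarray(X_values, float)
    if X.size == 0:
        raise DomainError("individual_accuracy of an empty sample")
    return float(np.median(np.abs(X)))


@dataclass
class BootstrapSummary:
    """A statistic with asymmetric bootstrap error bars.

    b_plus is chosen so that a fraction ``conf`` of the replicates above x0
    lie within [x0, x0 + b_plus]; b_minus symmetrically below.
    """

    x0: float
    b_minus: float
    b_plus: float
    samples: np.ndarray
    n_boot: int
    conf: float = DEFAULT_CONF
    n_dropped: int = 0


def _asymmetric_bars(x0: float, samples: np.ndarray, conf: float) -> tuple[float, float]:
    above = samples[samples > x0] - x0
    below = x0 - samples[samples < x0]
    b_plus = float(np.quantile(above, conf)) if above.size else 0.0
    b_minus = float(np.quantile(below, conf)) if below.size else 0.0
    return b_minus, b_plus


def bootstrap_statistic(
    records: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    n_boot: int = 1000,
    conf: float = DEFAULT_CONF,
    rng=None,
    question_col: str = "question",
) -> BootstrapSummary:
    """Bootstrap a statistic of a record table over its questions.

    Each replicate draws N_Q questions with replacement (N_Q = number of
    distinct questions) and evaluates ``statistic`` on the concatenation of
    all their records. Replicates on which the statistic is undefined (NaN
    or raising) are dropped and counted.
    """
    if records.shape[0] == 0:
        raise DomainError("bootstrap_statistic of an empty table")
    rng = as_generator(rng)
    questions = records[question_col].to_numpy()
    uniq = np.unique(questions)
    idx_by_q = {q: np.flatnonzero(questions == q) for q in uniq}
    x0 = float(statistic(records))
    samples = []
    dropped = 0
    for _ in range(n_boot):
        draw = rng.choice(uniq, size=uniq.size, replace=True)
        idx = np.concatenate([idx_by_q[q] for q in draw])
        try:
            val = float(statistic(records.iloc[idx]))
        except (DomainError, ValueError, ZeroDivisionError):
            dropped += 1
            continue
        if np.isnan(val):
            dropped += 1
            continue
        samples.append(val)
    samples = np.asarray(samples)
    b_minus, b_plus = _asymmetric_bars(x0, samples, conf)
    return BootstrapSummary(x0=x0, b_minus=b_minus, b_plus=b_plus, samples=samples,
                            n_boot=n_boot, conf=conf, n_dropped=dropped)


def p0_significance(difference_samples, claim: str = "positive") -> float:
    """Bootstrap probability that the opposite of the claim holds.

    ``claim`` is the asserted sign of the bootstrapped difference. With zero
    opposite occurrences the true p0 is only bounded by the resolution of
    the bootstrap, so 1/n_samples is returned as the upper bound.
    """
    s = np.asarray(difference_samples, float)
    if s.size == 0:
        raise DomainError("p0_significance of an empty sample")
    if claim == "positive":
        n_opp = int(np.count_nonzero(s < 0))
    elif claim == "negative":
        n_opp = int(np.count_nonzero(s > 0))
    else:
        raise DomainError(f"claim must be 'positive' or 'negative', got {claim!r}")
    if n_opp == 0:
        return 1.0 / s.size
    return n_opp / s.size


def goodness_of_fit(observed, model, err_up, err_down) -> float:
    """Mean squared model-data residual standardized by the error-bar
    half-width C = (b_plus + b_minus)/2; ~1 means residuals comparable to
    the data's own fluctuations."""
    O = np.asarray(observed, float)
    Mv = np.asarray(model, float)
    C = 0.5 * (np.asarray(err_up, float) + np.asarray(err_down, float))
    if O.shape != Mv.shape or O.shape != C.shape:
        raise DomainError("observed, model and error sequences must align")
    if np.any(C == 0):
        raise DomainError("zero error-bar half-width in goodness_of_fit")
    return float(np.mean(((O - Mv) / C) ** 2))


def relative_error(observed, model) -> float:
    """Mean |O - M| / |M| over the observables."""
    O = np.asarray(observed, float)
    Mv = np.asarray(model, float)
    if O.shape != Mv.shape:
        raise DomainError("observed and model sequences must align")
    if np.any(Mv == 0):
        raise DomainError("zero model value in relative_error")
    return float(np.mean(np.abs(O - Mv) / np.abs(Mv)))


def recalibrate_X(X_p, log_true, gamma: float) -> np.ndarray:
    """Bias-recalibrated personal estimates.

    Recalibration divides the *log-estimate* by gamma (the analogue of the
    shifted-median construction m' = m/gamma ~ log T), i.e.
    X_recal = (X_p + log10 T)/gamma - log10 T. With gamma = 1 this is the
    identity.
    """
    if gamma <= 0:
        raise DomainError(f"gamma must be > 0, got {gamma}")
    X_p = np.asarray(X_p, float)
    log_true = np.asarray(log_true, float)
    return (X_p + log_true) / gamma - log_true


def recalibrate_baseline(records: pd.DataFrame, gamma: float) -> dict[str, float]:
    """Accuracies of recalibrated personal estimates, for comparison with
    the shifted-median treatment's second estimates.

    ``records`` needs columns X_p and log_true.
    """
    X_rec = recalibrate_X(records["X_p"].to_numpy(), records["log_true"].to_numpy(), gamma)
    X_p = records["X_p"].to_numpy()
    return {
        "collective_before": collective_accuracy(X_p),
        "individual_before": individual_accuracy(X_p),
        "collective_recalibrated": collective_accuracy(X_rec),
        "individual_recalibrated": individual_accuracy(X_rec),
    }


# ---------------------------------------------------------------------------
# Full accuracy report
# ---------------------------------------------------------------------------

_FILTER_CELLS = {
    "all": ("all",),
    "dsign": ("D<0", "D>0"),
    "squantile": ("S<=med", "S>med"),
}


@dataclass
class AccuracyReport:
    """Per-condition accuracies plus treatment-level improvements.

    ``cells``: one row per treatment x tau x filter cell with before/after
    collective and individual accuracy. ``improvements``: tau-averaged
    improvement <O> - <O'> per treatment x measure x cell with bootstrap
    bars and p0 (claim: improvement positive). ``pairwise``: paired
    differences of "all"-cell improvements between treatments.
    """

    cells: pd.DataFrame
    improvements: pd.DataFrame
    pairwise: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "cells": self.cells.to_dict(orient="records"),
            "improvements": self.improvements.to_dict(orient="records"),
            "pairwise": self.pairwise.to_dict(orient="records"),
        }


def _cell_mask(records: pd.DataFrame, cell: str, s_threshold: float | None) -> np.ndarray:
    if cell == "all":
        return np.ones(records.shape[0], dtype=bool)
    D = records["D"].to_numpy()
    if cell == "D<0":
        return D < 0
    if cell == "D>0":
        return D > 0
    S = records["S"].to_numpy()
    lo, hi = S_CLIP
    valid = np.isfinite(S) & (S >= lo) & (S <= hi)
    if cell == "S<=med":
        return valid & (S <= s_threshold)
    if cell == "S>med":
        return valid & (S > s_threshold)
    raise DomainError(f"unknown cell {cell!r}")


def accuracy_report(
    records: pd.DataFrame,
    filters: Sequence[str] = ("all", "dsign", "squantile"),
    n_boot: int = 1000,
    rng=None,
    bootstrap_filters: Sequence[str] = ("all",),
) -> AccuracyReport:
    """Build the full accuracy comparison report from a record table.

    ``records`` needs columns treatment, tau, question, X_p, X_s, D, S.
    S-quantile splits threshold at the per-condition median of the clipped
    measured sensitivities (computed once on the full data). Bootstrap
    bars/p0 are computed for the filters in ``bootstrap_filters`` (the
    overlapping-cell bootstrap is the expensive part); point accuracies are
    reported for every requested filter.
    """
    for f in filters:
        if f not in _FILTER_CELLS:
            raise DomainError(f"unknown filter {f!r}")
    rng = as_generator(rng)
    treatments = sorted(records["treatment"].unique())
    taus = sorted(records["tau"].unique())
    questions = np.unique(records["question"].to_numpy())

    # per-condition S-median thresholds on the full data
    s_thresholds: dict[tuple[str, int], float] = {}
    if "squantile" in filters:
        lo, hi = S_CLIP
        for (tr, tau), sub in records.groupby(["treatment", "tau"], sort=False):
            S = sub["S"].to_numpy()
            S = S[np.isfinite(S)]
            S = S[(S >= lo) & (S <= hi)]
            s_thresholds[(tr, tau)] = float(np.median(S)) if S.size else np.nan

    # flat arrays + per (treatment, tau, cell, question) index lists
    Xp = records["X_p"].to_numpy()
    Xs = records["X_s"].to_numpy()
    qcol = records["question"].to_numpy()
    cell_rows: list[dict] = []
    cell_qidx: dict[tuple[str, int, str], dict[object, np.ndarray]] = {}
    for tr in treatments:
        for tau in taus:
            cond_mask = (records["treatment"].to_numpy() == tr) & (records["tau"].to_numpy() == tau)
            if not cond_mask.any():
                continue
            for f in filters:
                for cell in _FILTER_CELLS[f]:
                    mask = cond_mask & _cell_mask(records, cell, s_thresholds.get((tr, tau)))
                    idx = np.flatnonzero(mask)
                    row = {
                        "treatment": tr, "tau": tau, "filter": f, "cell": cell,
                        "n": int(idx.size),
                        "collective_before": np.nan, "collective_after": np.nan,
                        "individual_before": np.nan, "individual_after": np.nan,
                    }
                    if idx.size:
                        row.update(
                            collective_before=collective_accuracy(Xp[idx]),
                            collective_after=collective_accuracy(Xs[idx]),
                            individual_before=individual_accuracy(Xp[idx]),
                            individual_after=individual_accuracy(Xs[idx]),
                        )
                    cell_rows.append(row)
                    cell_qidx[(tr, tau, cell)] = {
                        q: idx[qcol[idx] == q] for q in questions
                    }
    cells = pd.DataFrame(cell_rows)

    # bootstrap of tau-averaged improvements, paired across everything
    boot_cells = [c for f in bootstrap_filters for c in _FILTER_CELLS[f]]
    measures = ("collective", "individual")

    def improvements_for(draw: np.ndarray | None) -> dict[tuple[str, str, str], float]:
        out = {}
        for tr in treatments:
            for cell in boot_cells:
                per_tau: dict[str, list[float]] = {m: [] for m in measures}
                for tau in taus:
                    qidx = cell_qidx.get((tr, tau, cell))
                    if qidx is None:
                        continue
                    if draw is None:
                        idx = np.concatenate([qidx[q] for q in questions])
                    else:
                        idx = np.concatenate([qidx[q] for q in draw])
                    if idx.size == 0:
                        continue
                    per_tau["collective"].append(
                        collective_accuracy(Xp[idx]) - collective_accuracy(Xs[idx]))
                    per_tau["individual"].append(
                        individual_accuracy(Xp[idx]) - individual_accuracy(Xs[idx]))
                for m in measures:
                    out[(tr, cell, m)] = float(np.mean(per_tau[m])) if per_tau[m] else np.nan
        return out

    x0 = improvements_for(None)
    boot: dict[tuple[str, str, str], list[float]] = {k: [] for k in x0}
    for _ in range(n_boot):
        draw = rng.choice(questions, size=questions.size, replace=True)
        rep = improvements_for(draw)
        for k, v in rep.items():
            boot[k].append(v)

    imp_rows = []
    for (tr, cell, m), v0 in x0.items():
        samples = np.asarray(boot[(tr, cell, m)], float)
        samples = samples[np.isfinite(samples)]
        b_minus, b_plus = _asymmetric_bars(v0, samples, DEFAULT_CONF) if samples.size else (np.nan, np.nan)
        imp_rows.append({
            "treatment": tr, "cell": cell, "measure": m,
            "improvement": v0, "b_minus": b_minus, "b_plus": b_plus,
            "p0": p0_significance(samples, "positive") if samples.size else np.nan,
        })
    improvements = pd.DataFrame(imp_rows)

    pair_rows = []
    for a in treatments:
        for b in treatments:
            if a >= b:
                continue
            for m in measures:
                if ("all" not in boot_cells):
                    continue
                sa = np.asarray(boot[(a, "all", m)], float)
                sb = np.asarray(boot[(b, "all", m)], float)
                diff = sa - sb
                d0 = x0[(a, "all", m)] - x0[(b, "all", m)]
                claim = "positive" if d0 >= 0 else "negative"
                b_minus, b_plus = _asymmetric_bars(d0, diff, DEFAULT_CONF)
                pair_rows.append({
                    "treatment_a": a, "treatment_b": b, "measure": m,
                    "diff_improvement": d0, "b_minus": b_minus, "b_plus": b_plus,
                    "p0": p0_significance(diff, claim),
                })
    pairwise = pd.DataFrame(pair_rows)
    return AccuracyReport(cells=cells, improvements=improvements, pairwise=pairwise)
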
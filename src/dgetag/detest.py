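"""Differential expression between two tag libraries (Audic-Claverie test).

With a single library per condition, per-gene tag counts are modelled as
Poisson: a gene contributing a small fraction of a library of total depth N
yields a count x ~ Poisson(lambda * N).  Conditioning on the pair (x, y)
observed in libraries of depths N1, N2 under equal underlying expression
gives the Audic-Claverie conditional law

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! * (1 + N2/N1)^(x+y+1) ),

a negative-binomial distribution in y with x+1 successes and success
probability N1/(N1+N2).  The two-sided p-value doubles the smaller tail of
this distribution (observed point included, capped at 1).

Genes are called differentially expressed when the p-value, the
Benjamini-Hochberg FDR, and the fold change all pass their gates
(defaults: p < 0.005, FDR < 0.001, |log2 ratio| >= 1).

The module exposes both plain functions and a model/results pair
(`TwoLibraryDE` / `TwoLibraryDEResults`) for interactive use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .reference import InputError
from .tagproc import ExpressionTable

__all__ = [
    "ac_probability",
    "ac_pvalue",
    "bh_fdr",
    "log2_ratio",
    "call_degs",
    "deg_summary",
    "fold_change_histogram",
    "TwoLibraryDE",
    "TwoLibraryDEResults",
]


def _validate(x, y, n1, n2):
    x = np.asarray(x)
    y = np.asarray(y)
    if np.any(x < 0) or np.any(y < 0):
        raise InputError("tag counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise InputError("library totals must be positive")
    return x, y


def ac_probability(x, y, n1, n2):
    """Audic-Claverie conditional probability p(y | x) of equal expression.

    Computed in log space; vectorized over x and y.
    """
    x, y = _validate(x, y, n1, n2)
    r = n2 / n1
    logp = (
        y * np.log(r)
        + special.gammaln(x + y + 1)
        - special.gammaln(x + 1)
        - special.gammaln(y + 1)
        - (x + y + 1) * np.log1p(r)
    )
    return np.exp(logp)


def _log_nb_pmf(k, x, log_p, log_q):
    return (
        special.gammaln(x + 1 + k)
        - special.gammaln(k + 1)
        - special.gammaln(x + 1)
        + (x + 1) * log_p
        + k * log_q
    )


def _log_tail(x, y, p_success, side):
    """log of one NB(x+1, p) tail by direct summation (extreme-tail rescue)."""
    log_p, log_q = np.log(p_success), np.log1p(-p_success)
    if side == "lower":  # P(Y <= y): y sits below the mode when this is tiny
        k = np.arange(0, y + 1)
        return special.logsumexp(_log_nb_pmf(k, x, log_p, log_q))
    # upper: P(Y >= y); terms decay geometrically above the mode
    total = -np.inf
    start, chunk = y, 4096
    while True:
        k = np.arange(start, start + chunk)
        terms = _log_nb_pmf(k, x, log_p, log_q)
        total = np.logaddexp(total, special.logsumexp(terms))
        if terms[-1] < total - 40:  # remaining mass is negligible
            return total
        start += chunk


def ac_pvalue(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value.

    p = min(1, 2 * min( P(Y <= y | x), P(Y >= y | x) )) where Y follows the
    conditional law at fixed x.  Uses the negative-binomial identity
    Y | x ~ NB(x+1, N1/(N1+N2)), so both tails come from regularized
    incomplete beta functions; tails below 1e-250 (where the beta-function
    route loses relative accuracy) are recomputed by log-space summation.
    """
    x, y = _validate(x, y, n1, n2)
    p_success = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p_success)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)
    smaller = np.minimum(lower, upper)
    tiny = smaller < 1e-250
    if np.any(tiny):
        smaller = np.array(smaller, dtype=float, copy=True)
        xa, ya = np.broadcast_arrays(x, y)
        flat = smaller.reshape(-1)
        xa, ya = xa.reshape(-1), ya.reshape(-1)
        lo = np.broadcast_to(lower, flat.shape).reshape(-1)
        up = np.broadcast_to(upper, flat.shape).reshape(-1)
        for i in np.flatnonzero(np.asarray(tiny).reshape(-1)):
            side = "lower" if lo[i] <= up[i] else "upper"
            flat[i] = np.exp(_log_tail(int(xa[i]), int(ya[i]), p_success, side))
        smaller = flat.reshape(np.shape(smaller))
    return np.minimum(1.0, 2.0 * smaller)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_ratio(x, y, n1, n2):
    """log2 fold change (library1 / library2) on the TPM scale.

    Zero counts are floored at 1 before normalization so every gene with
    x+y > 0 gets a finite ratio; the untestable (0, 0) case returns 0 by
    convention.
    """
    x, y = _validate(x, y, n1, n2)
    xf = np.maximum(x, 1)
    yf = np.maximum(y, 1)
    ratio = np.log2((xf / n1) / (yf / n2))
    return np.where((x == 0) & (y == 0), 0.0, ratio)


def deg_summary(n_up: int, n_down: int) -> dict:
    """Up/down summary with percentages to one decimal."""
    n_total = n_up + n_down
    return {
        "n_total": n_total,
        "n_up": n_up,
        "n_down": n_down,
        "pct_up": round(n_up / n_total * 100, 1) if n_total else 0.0,
        "pct_down": round(n_down / n_total * 100, 1) if n_total else 0.0,
    }


def call_degs(
    expr: ExpressionTable,
    p_threshold: float = 0.005,
    fdr_threshold: float = 0.001,
    log2_threshold: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Test every gene and call up/down/ns at the joint thresholds.

    Genes with x + y = 0 are untestable and excluded from the results and
    from the BH family.  Returns the per-gene results frame (sorted by
    p-value) and the up/down summary of the DE calls.
    """
    if not (0 < p_threshold <= 1 and 0 < fdr_threshold <= 1 and log2_threshold >= 0):
        raise InputError("thresholds out of range")
    frame = expr.frame
    testable = frame.loc[(frame["x"] + frame["y"]) > 0]
    if testable.empty:
        empty = pd.DataFrame(
            columns=["x", "y", "tpm1", "tpm2", "log2_ratio", "p_value", "fdr", "call"]
        )
        empty.index.name = "gene"
        return empty, deg_summary(0, 0)

    x = testable["x"].to_numpy()
    y = testable["y"].to_numpy()
    lfc = log2_ratio(x, y, expr.n1, expr.n2)
    p = ac_pvalue(x, y, expr.n1, expr.n2)
    q = bh_fdr(p)

    de = (p < p_threshold) & (q < fdr_threshold) & (np.abs(lfc) >= log2_threshold)
    call = np.where(de, np.where(lfc > 0, "up", "down"), "ns")

    out = pd.DataFrame(
        {
            "x": x,
            "y": y,
            "tpm1": x / expr.n1 * 1e6,
            "tpm2": y / expr.n2 * 1e6,
            "log2_ratio": lfc,
            "p_value": p,
            "fdr": q,
            "call": call,
        },
        index=testable.index,
    )
    out = out.sort_values(["p_value", "fdr"], kind="mergesort")
    summary = deg_summary(int((call == "up").sum()), int((call == "down").sum()))
    return out, summary


def fold_change_histogram(
    results: pd.DataFrame,
    edges: Optional[Sequence[float]] = None,
) -> tuple[pd.DataFrame, float]:
    """Bin |log2 ratio| values and report the within-5-fold percentage.

    ``edges`` are bin edges on the |log2 ratio| scale (default: unit bins up
    to the observed maximum).  Returns (histogram frame, percentage of
    entries with linear ratio <= 5).
    """
    if results.empty:
        raise InputError("fold_change_histogram needs a non-empty results table")
    mag = np.abs(results["log2_ratio"].to_numpy())
    if edges is None:
        top = max(1.0, float(np.ceil(mag.max())))
        edges = np.arange(0.0, top + 1.0)
    counts, edges = np.histogram(mag, bins=np.asarray(edges, dtype=float))
    hist = pd.DataFrame(
        {"lo": edges[:-1], "hi": edges[1:], "count": counts}
    )
    within5 = float((mag <= np.log2(5)).mean() * 100)
    return hist, within5


@dataclass
class TwoLibraryDE:
    """Two-library differential expression model.

    Parameters
    ----------
    expr
        Per-gene x/y counts with clean-tag totals n1, n2 (see
        :func:`dgetag.tagproc.combine_libraries`).

    Examples
    --------
    >>> model = TwoLibraryDE.from_counts(counts, n1=5_864_499, n2=5_648_877)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    expr: ExpressionTable

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, n1: int, n2: int) -> "TwoLibraryDE":
        """Build from a frame with columns x, y indexed by gene id."""
        return cls(ExpressionTable(frame=counts[["x", "y"]].copy(), n1=n1, n2=n2))

    def fit(
        self,
        p_threshold: float = 0.005,
        fdr_threshold: float = 0.001,
        log2_threshold: float = 1.0,
    ) -> "TwoLibraryDEResults":
        results, summary = call_degs(
            self.expr, p_threshold, fdr_threshold, log2_threshold
        )
        return TwoLibraryDEResults(
            model=self,
            frame=results,
            de_summary=summary,
            thresholds={
                "p": p_threshold,
                "fdr": fdr_threshold,
                "log2": log2_threshold,
            },
        )


@dataclass
class TwoLibraryDEResults:
    """Fitted results: per-gene statistics, calls, and a text summary."""

    model: TwoLibraryDE
    frame: pd.DataFrame
    de_summary: dict
    thresholds: dict = field(default_factory=dict)

    @property
    def degs(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["call"] != "ns"]

    def fold_change_histogram(self, edges=None):
        return fold_change_histogram(self.frame, edges)

    def summary(self) -> str:
        s = self.de_summary
        t = self.thresholds
        lines = [
            "Two-library differential expression (Audic-Claverie test)",
            "=" * 58,
            f"Libraries: {self.model.expr.library_ids[0]} (N1={self.model.expr.n1:,})"
            f" vs {self.model.expr.library_ids[1]} (N2={self.model.expr.n2:,})",
            f"Genes tested: {len(self.frame):,}",
            f"Thresholds: P<{t.get('p')}, FDR<{t.get('fdr')},"
            f" |log2 ratio|>={t.get('log2')}",
            f"Significant DEGs: {s['n_total']:,} "
            f"({s['n_up']:,} up [{s['pct_up']}%], "
            f"{s['n_down']:,} down [{s['pct_down']}%])",
        ]
        if len(self.frame):
            _, within5 = fold_change_histogram(self.frame)
            lines.append(f"Ratios within 5-fold: {within5:.2f}%")
        return "\n".join(lines)
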
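"""Hypergeometric GO-term / pathway enrichment of a DEG set.

For a background of N annotated genes of which n are differentially
expressed, and a term carried by M background genes of which m are DEGs, the
enrichment p-value is the upper-tail hypergeometric probability

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n),

the chance of drawing at least m term members in n random draws without
replacement.  GO terms and pathways use identical mathematics and are
handled by one engine with a namespace label per term.  Significance is
assessed on raw p-values (p <= alpha, default 0.05); an optional BH
adjustment is available but off by default.
"""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .reference import InputError
from .detest import bh_fdr

__all__ = ["hypergeom_enrich_p", "enrich_terms", "top_k_report"]


def hypergeom_enrich_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric enrichment probability P(X >= m)."""
    if not (0 <= m <= min(n, M) and 0 <= n <= N and 0 <= M <= N):
        raise InputError(
            f"invalid hypergeometric configuration N={N}, n={n}, M={M}, m={m}"
        )
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def enrich_terms(
    deg_ids: Iterable[str],
    annotations: pd.DataFrame,
    background_ids: Iterable[str],
    alpha: float = 0.05,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Test every annotation term for enrichment in the DEG set.

    Parameters
    ----------
    deg_ids
        Differentially expressed gene ids.
    annotations
        Frame with columns ``gene`` and ``term`` (optional ``namespace``,
        ``label``); one row per gene-term assignment.
    background_ids
        The gene universe.  N and n count *annotated* genes only: background
        genes (and DEGs) without any annotation row are dropped before
        counting.
    alpha
        Raw-p significance cutoff (default 0.05).
    bh_adjust
        If True, add a BH-adjusted column and flag significance on it
        instead.

    Returns a frame sorted by (p_value, term) with one row per term that has
    at least one annotated background gene.
    """
    if annotations.empty:
        return pd.DataFrame(
            columns=["term", "namespace", "N", "n", "M", "m", "p_value",
                     "significant", "deg_members"]
        )
    if not {"gene", "term"} <= set(annotations.columns):
        raise InputError("annotation table needs columns 'gene' and 'term'")

    background = set(background_ids)
    degs = set(deg_ids)
    if not degs <= background:
        raise InputError("DEG ids must be a subset of the background")

    ann = annotations.loc[annotations["gene"].isin(background)]
    annotated = set(ann["gene"])
    N = len(annotated)
    annotated_degs = degs & annotated
    n = len(annotated_degs)

    rows = []
    for term, sub in ann.groupby("term", sort=True):
        members = set(sub["gene"])
        M = len(members)
        deg_members = sorted(members & annotated_degs)
        m = len(deg_members)
        namespace = sub["namespace"].iloc[0] if "namespace" in sub else ""
        rows.append(
            {
                "term": term,
                "namespace": namespace,
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "p_value": hypergeom_enrich_p(N, n, M, m),
                "deg_members": ",".join(deg_members),
            }
        )
    out = pd.DataFrame(rows)
    if bh_adjust:
        out["p_adjusted"] = bh_fdr(out["p_value"].to_numpy())
        out["significant"] = out["p_adjusted"] <= alpha
    else:
        out["significant"] = out["p_value"] <= alpha
    out = out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    return out


def top_k_report(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Top-k enriched terms (term, member gene count, p).

    Input must already be sorted ascending by p; ties at the boundary are
    broken by term id so the report is deterministic.
    """
    if k <= 0:
        raise InputError("k must be positive")
    ordered = results.sort_values(["p_value", "term"], kind="mergesort")
    top = ordered.head(k)
    return top[["term", "m", "p_value"]].rename(columns={"m": "gene_count"}).reset_index(
        drop=True
    )
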
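"""qRT-PCR validation by the comparative CT (2^-ddCt) method.

Cycle-threshold (Ct) values are normalized to a housekeeping reference gene
within each sample (dCt = mean Ct(target) - mean Ct(reference)); the
difference of dCt between a case ("deformed") and a control ("normal")
sample gives ddCt, and 2^-ddCt is the relative fold change of the target.
Replicates are averaged on the Ct scale before dCt.  Group comparisons run
Student's t-test on per-sample dCt values (one dCt per biological sample),
which is equivalent to testing log2 fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .reference import InputError

__all__ = ["CtTable", "ddct_fold_change", "compare_groups", "concordance"]

_COLUMNS = ["sample", "group", "gene", "replicate", "ct"]
_GROUPS = {"deformed", "normal"}


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements plus the endogenous-control gene."""

    frame: pd.DataFrame  # columns: sample, group, gene, replicate, ct
    reference_gene: str

    def __post_init__(self):
        missing = set(_COLUMNS) - set(self.frame.columns)
        if missing:
            raise InputError(f"Ct table missing columns {sorted(missing)}")
        if (self.frame["ct"] <= 0).any():
            raise InputError("Ct values must be positive")
        bad = set(self.frame["group"]) - _GROUPS
        if bad:
            raise InputError(f"unknown group labels {sorted(bad)}")
        by_sample = self.frame.groupby("sample")["gene"].apply(set)
        without_ref = [s for s, genes in by_sample.items()
                       if self.reference_gene not in genes]
        if without_ref:
            raise InputError(
                f"reference gene {self.reference_gene!r} missing for samples "
                f"{without_ref}"
            )

    def delta_ct(self, gene: str) -> pd.DataFrame:
        """Per-sample dCt = mean Ct(gene) - mean Ct(reference)."""
        f = self.frame
        target = f.loc[f["gene"] == gene].groupby("sample")["ct"].mean()
        if target.empty:
            raise InputError(f"gene {gene!r} absent from Ct table")
        ref = f.loc[f["gene"] == self.reference_gene].groupby("sample")["ct"].mean()
        groups = f.drop_duplicates("sample").set_index("sample")["group"]
        out = pd.DataFrame({"delta_ct": target - ref}).dropna()
        out["group"] = groups.loc[out.index]
        return out


def ddct_fold_change(
    ct: CtTable, gene: str, deformed_sample: str, normal_sample: str
) -> float:
    """Relative expression 2^-ddCt of ``gene`` for one sample pair."""
    dct = ct.delta_ct(gene)
    for s in (deformed_sample, normal_sample):
        if s not in dct.index:
            raise InputError(f"sample {s!r} lacks Ct values for {gene!r}")
    ddct = dct.loc[deformed_sample, "delta_ct"] - dct.loc[normal_sample, "delta_ct"]
    return float(2.0 ** (-ddct))


def compare_groups(ct: CtTable, gene: str) -> dict:
    """Deformed-vs-normal comparison of a gene's per-sample dCt values.

    Returns the mean log2 fold change (deformed/normal), the direction of
    change, and a two-sample t-test when both groups have >=2 samples
    (otherwise descriptive only, p_value None).  Degenerate (zero overall
    variance) inputs are flagged with an undefined p.
    """
    dct = ct.delta_ct(gene)
    d = dct.loc[dct["group"] == "deformed", "delta_ct"].to_numpy()
    n = dct.loc[dct["group"] == "normal", "delta_ct"].to_numpy()
    if len(d) == 0 or len(n) == 0:
        raise InputError(f"gene {gene!r}: need samples in both groups")
    log2_fold = float(n.mean() - d.mean())  # lower dCt = higher expression

    t_stat: Optional[float] = None
    p_value: Optional[float] = None
    degenerate = False
    if len(d) >= 2 and len(n) >= 2:
        if np.allclose(d.var(ddof=1), 0) and np.allclose(n.var(ddof=1), 0):
            degenerate = True
            if np.isclose(d.mean(), n.mean()):
                t_stat, p_value = 0.0, 1.0
        else:
            t_stat, p_value = stats.ttest_ind(d, n)
            t_stat, p_value = float(t_stat), float(p_value)
    return {
        "gene": gene,
        "log2_fold_change": log2_fold,
        "fold_change": 2.0 ** log2_fold,
        "direction": "up" if log2_fold > 0 else ("down" if log2_fold < 0 else "none"),
        "t_statistic": t_stat,
        "p_value": p_value,
        "degenerate_variance": degenerate,
        "n_deformed": len(d),
        "n_normal": len(n),
        "test": "two-sample t on per-sample delta-Ct",
    }


def concordance(qpcr_results: pd.DataFrame, dge_log2: pd.Series) -> pd.DataFrame:
    """Sign agreement between qPCR and DGE log2 fold changes, per gene."""
    out = qpcr_results.set_index("gene")[["log2_fold_change"]].copy()
    out["dge_log2_ratio"] = dge_log2.reindex(out.index)
    out["concordant"] = (
        np.sign(out["log2_fold_change"]) == np.sign(out["dge_log2_ratio"])
    )
    return out.reset_index()
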
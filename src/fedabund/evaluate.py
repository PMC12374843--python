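"""Result-table comparison metrics.

Differences are computed over the feature intersection of two tables; DE
calls use each table's *own* log fold change and BH-adjusted p value
(count-adjusted when present), so the metrics describe what a practitioner
relying on either output would conclude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ComparisonMetrics", "de_calls", "compare_results", "jaccard_topk"]

P_FLOOR = 1e-300


@dataclass
class ComparisonMetrics:
    mean_abs_dlogp: float
    max_abs_dlogp: float
    mean_abs_dlogfc: float
    max_abs_dlogfc: float
    fp: int
    fn: int
    jaccard: float
    n_common: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _adj_col(table: pd.DataFrame) -> str:
    return "sca.adj.pval" if "sca.adj.pval" in table.columns else "adj.P.Val"


def de_calls(table: pd.DataFrame, lfc: float, alpha: float) -> set[str]:
    """DE set at |logFC| > lfc and BH-adjusted p < alpha."""
    adj = table[_adj_col(table)]
    hit = (table["logFC"].abs() > lfc) & (adj < alpha)
    return set(table.index[hit.fillna(False)])


def compare_results(
    candidate: pd.DataFrame,
    reference: pd.DataFrame,
    lfc: float = 1.0,
    alpha: float = 0.05,
) -> ComparisonMetrics:
    """Mean/max |Δ(-log10 adj p)| and |ΔlogFC|, FP/FN counts and Jaccard.

    FP are candidate-only DE calls, FN reference-only.  Differences use the
    shared features; adjusted p values of 0 are floored at 1e-300.
    """
    common = candidate.index.intersection(reference.index)
    if len(common) == 0:
        raise ValueError("result tables share no features")
    ca = candidate.loc[common]
    re = reference.loc[common]
    lp_c = -np.log10(np.maximum(ca[_adj_col(candidate)].to_numpy(float), P_FLOOR))
    lp_r = -np.log10(np.maximum(re[_adj_col(reference)].to_numpy(float), P_FLOOR))
    dlp = np.abs(lp_c - lp_r)
    dfc = np.abs(ca["logFC"].to_numpy(float) - re["logFC"].to_numpy(float))
    dlp = dlp[np.isfinite(dlp)]
    dfc = dfc[np.isfinite(dfc)]
    set_c = de_calls(candidate, lfc, alpha)
    set_r = de_calls(reference, lfc, alpha)
    union = set_c | set_r
    jac = 1.0 if not union else len(set_c & set_r) / len(union)
    return ComparisonMetrics(
        mean_abs_dlogp=float(dlp.mean()) if dlp.size else float("nan"),
        max_abs_dlogp=float(dlp.max()) if dlp.size else float("nan"),
        mean_abs_dlogfc=float(dfc.mean()) if dfc.size else float("nan"),
        max_abs_dlogfc=float(dfc.max()) if dfc.size else float("nan"),
        fp=len(set_c - set_r),
        fn=len(set_r - set_c),
        jaccard=jac,
        n_common=len(common),
    )


def _ranking(table: pd.DataFrame) -> list[str]:
    adj = np.maximum(table[_adj_col(table)].to_numpy(float), P_FLOOR)
    neglog = -np.log10(adj)
    order = sorted(
        range(len(table)),
        key=lambda i: (
            -(neglog[i] if np.isfinite(neglog[i]) else -np.inf),
            -abs(table["logFC"].iloc[i]),
            table.index[i],
        ),
    )
    return [table.index[i] for i in order]


def jaccard_topk(
    candidate: pd.DataFrame,
    reference: pd.DataFrame,
    k_grid: list[int],
) -> pd.DataFrame:
    """Jaccard similarity of the top-k sets for each k.

    Rankings are by decreasing -log10(adjusted p), ties broken by |logFC|
    then feature id; no logFC filtering.  k values beyond the table size
    are truncated with a warning.
    """
    rank_c = _ranking(candidate)
    rank_r = _ranking(reference)
    nmax = min(len(rank_c), len(rank_r))
    rows = []
    for k in k_grid:
        kk = k
        if k > nmax:
            import warnings

            warnings.warn(f"top-k {k} exceeds table size {nmax}; truncated")
            kk = nmax
        top_c = set(rank_c[:kk])
        top_r = set(rank_r[:kk])
        union = top_c | top_r
        rows.append((k, len(top_c & top_r) / len(union) if union else 1.0))
    return pd.DataFrame(rows, columns=["k", "jaccard"]).set_index("k")
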
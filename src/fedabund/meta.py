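"""Meta-analysis baselines: Fisher and Stouffer p-value combination.

These combine *per-cohort* differential-abundance results -- each cohort
analyzed alone with the same moderated-statistics pipeline -- and serve as
the comparison methods a consortium could use without federation.  The
global log fold change is the mean of the local ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .centralized import run_centralized
from .io import ClientBundle, StudyConfig
from .stats import bh_adjust

__all__ = ["per_cohort_tables", "fisher_combine", "stouffer_combine"]

#: floor applied to p values before taking logs / normal quantiles
P_FLOOR = 1e-300


def per_cohort_tables(
    bundles: list[ClientBundle], config: StudyConfig
) -> list[pd.DataFrame]:
    """Run the single-cohort pipeline on every cohort separately."""
    tables = []
    for b in bundles:
        fit = run_centralized([b], config)
        tables.append(fit.table)
    return tables


def _p_and_fc(table: pd.DataFrame) -> pd.DataFrame:
    pcol = "sca.P.Value" if "sca.P.Value" in table.columns else "P.Value"
    return pd.DataFrame({"p": table[pcol], "logFC": table["logFC"]})


def fisher_combine(tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Fisher's method: -2 sum(log p) against chi-square with 2c df.

    Proteins present (with a finite p) in at least two cohorts are
    combined; the rest are excluded.  Zero p values are floored at 1e-300
    before taking logs.
    """
    frames = [_p_and_fc(t) for t in tables]
    proteins = sorted(set().union(*[set(f.index) for f in frames]))
    rows = []
    for pg in proteins:
        ps, fcs = [], []
        for f in frames:
            if pg in f.index and np.isfinite(f.at[pg, "p"]):
                ps.append(max(float(f.at[pg, "p"]), P_FLOOR))
                fcs.append(float(f.at[pg, "logFC"]))
        if len(ps) < 2:
            continue
        stat = -2.0 * np.sum(np.log(ps))
        p_comb = float(sps.chi2.sf(stat, df=2 * len(ps)))
        rows.append((pg, p_comb, float(np.mean(fcs)), len(ps)))
    out = pd.DataFrame(
        rows, columns=["protein_group", "P.Value", "logFC", "n_cohorts"]
    ).set_index("protein_group")
    out["adj.P.Val"] = bh_adjust(out["P.Value"].to_numpy())
    return out


def stouffer_combine(
    tables: list[pd.DataFrame],
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stouffer's weighted z method on signed one-sided z scores.

    Two-sided p values are converted to z with the sign of the local log
    fold change, combined as ``sum(w z) / sqrt(sum(w^2))``, and mapped back
    to a two-sided p.  Only proteins present in *all* cohorts are combined.
    The recommended weights are ``sqrt(m_i)`` (sample-size weighting, what
    the CLI uses); ``None`` means equal weights.
    """
    frames = [_p_and_fc(t) for t in tables]
    if weights is None:
        w = np.ones(len(frames))
    else:
        w = np.asarray(weights, float)
    common = set(frames[0].index)
    for f in frames[1:]:
        common &= set(f.index)
    rows = []
    for pg in sorted(common):
        ps = np.array([max(float(f.at[pg, "p"]), P_FLOOR) for f in frames])
        fcs = np.array([float(f.at[pg, "logFC"]) for f in frames])
        if not np.all(np.isfinite(ps)):
            continue
        z = sps.norm.isf(ps / 2.0) * np.sign(fcs)
        z_comb = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
        p_comb = float(2.0 * sps.norm.sf(abs(z_comb)))
        rows.append((pg, p_comb, float(np.mean(fcs)), z_comb))
    out = pd.DataFrame(
        rows, columns=["protein_group", "P.Value", "logFC", "z"]
    ).set_index("protein_group")
    out["adj.P.Val"] = bh_adjust(out["P.Value"].to_numpy())
    return out
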
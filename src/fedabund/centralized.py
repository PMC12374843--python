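"""Pooled-data reference pipeline.

Applies exactly the rules of the federated engine -- per-cohort privacy
masking, global missing-value filter, normalization, per-protein design
mask, moderated statistics, count adjustment -- but on the column-
concatenated data, computing every sufficient statistic directly from the
pooled matrices rather than by summing client blocks.  It is the oracle the
federated result is compared against, and it exposes every intermediate
(coefficients, residual variances, priors) for equivalence tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import preprocess, stats
from .io import ClientBundle, StudyConfig, RESULT_COLUMNS

__all__ = ["CentralizedFit", "run_centralized"]


@dataclass
class CentralizedFit:
    """Result table plus pooled-fit intermediates."""

    table: pd.DataFrame
    proteins: list[str]
    variables: list[str]
    mask: stats.DesignMask
    beta: np.ndarray
    stdev_unscaled: np.ndarray
    sigma2: np.ndarray
    df_residual: np.ndarray
    df_prior: float
    s2_prior: float
    pooled_Y: np.ndarray
    pooled_X: np.ndarray
    singular: np.ndarray


def _expand_design(
    bundle: ClientBundle, cohort: int, variables: list[str], cohort_of_col: dict[int, int]
) -> pd.DataFrame:
    X = pd.DataFrame(0.0, index=bundle.design.index, columns=variables)
    for var in variables:
        if var in bundle.design.columns:
            X[var] = bundle.design[var]
    for col, coh in cohort_of_col.items():
        X.iloc[:, col] = 1.0 if coh == cohort else 0.0
    return X


def run_centralized(
    bundles: list[ClientBundle], config: StudyConfig
) -> CentralizedFit:
    """Analyze the pooled cohorts centrally with the same study rules."""
    if not bundles:
        raise ValueError("no cohorts supplied")
    proteins = sorted(set().union(*[set(b.intensities.index) for b in bundles]))
    variables = [*config.target_classes, *config.covariates]
    cohort_of_col: dict[int, int] = {}
    for i, b in enumerate(bundles[1:], start=1):
        cohort_of_col[len(variables)] = i
        variables.append(f"cohort_{b.client_id}")

    mats = [b.intensities.reindex(proteins) for b in bundles]
    designs = [
        _expand_design(b, i, variables, cohort_of_col) for i, b in enumerate(bundles)
    ]
    for i in range(len(mats)):
        mats[i], _ = preprocess.mask_design_column_singletons(mats[i], designs[i])

    # global missing-value filter on pooled per-class counts
    class_counts = sum(
        preprocess.class_observed_counts(m, d, config.target_classes)
        for m, d in zip(mats, designs)
    )
    class_totals = sum(
        np.array([float((d[c] != 0).sum()) for c in config.target_classes])
        for d in designs
    )
    keep = preprocess.retained_by_missingness(
        class_counts, class_totals, config.filter_fraction, config.filter_mode
    )
    pr_min = None
    if config.use_counts and all(b.counts is not None for b in bundles):
        counts = pd.concat([b.counts.reindex(proteins) for b in bundles], axis=1)
        pr_min = counts.min(axis=1, skipna=True)
        if config.single_peptide_filter:
            arr = pr_min.to_numpy()
            keep &= (arr != 1.0) | ~np.isfinite(arr)
    retained = [p for p, k in zip(proteins, keep) if k]
    if not retained:
        import warnings

        warnings.warn("no proteins survive the missing-value filter")
    mats = [m.loc[retained] for m in mats]
    if pr_min is not None:
        pr_min = pr_min.loc[retained]

    if config.normalization in ("median", "irs_median"):
        pooled_meds = pd.concat([preprocess.sample_medians(m) for m in mats])
        global_med = float(pooled_meds.mean())
        mats = [preprocess.median_scale(m, global_med) for m in mats]
    if config.normalization == "irs_median":
        for i, b in enumerate(bundles):
            if "plex" in b.design.columns:
                plex = b.design["plex"].loc[mats[i].columns]
                mats[i], _ = preprocess.irs_normalize(mats[i], plex)
    if config.log_transform:
        mats = [preprocess.log_transform(m) for m in mats]

    Y = np.concatenate([m.to_numpy() for m in mats], axis=1)
    X = np.concatenate([d.to_numpy() for d in designs], axis=0)
    k, v = len(bundles), len(variables)

    obs_per_cohort = np.zeros((len(retained), k))
    offset = 0
    for i, m in enumerate(mats):
        mi = m.shape[1]
        obs_per_cohort[:, i] = np.isfinite(Y[:, offset : offset + mi]).sum(axis=1)
        offset += mi
    obs = np.isfinite(Y)
    support = np.column_stack([obs[:, X[:, c] != 0].sum(axis=1) for c in range(v)])
    structure = stats.DesignStructure(
        columns=tuple(variables),
        class_cols=(0, 1),
        cohort_of_col=cohort_of_col,
        n_cohorts=k,
        reference_cohort=0,
    )
    mask = stats.build_design_mask(obs_per_cohort, support, structure)

    xtx, xty = stats.local_moments(Y, X)
    beta, stdev_unscaled, cov, singular = stats.solve_global_lm(xtx, xty, mask)
    sse = stats.residual_sse(Y, X, beta)
    df = mask.df_residual.astype(float)
    df[singular] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.where(df > 0, sse / df, np.nan)

    K = np.zeros(v)
    K[0], K[1] = 1.0, -1.0
    beta_c, stdev_c = stats.fit_contrast(beta, cov, mask, K)
    usable = np.isfinite(sigma2) & (df > 0) & ~singular
    df_prior, s2_prior = stats.fit_f_dist(sigma2[usable], df[usable])
    mod = stats.moderate(
        beta_c, stdev_c, sigma2, df, df_prior, s2_prior, p_de=config.p_de
    )
    table = pd.DataFrame(
        {
            "logFC": mod.logfc,
            "CI.L": mod.ci_low,
            "CI.R": mod.ci_high,
            "t": mod.t,
            "P.Value": mod.p,
            "adj.P.Val": mod.adj_p,
            "B": mod.lods,
        },
        index=pd.Index(retained, name="protein_group"),
    )
    if pr_min is not None:
        sca = stats.count_adjust(beta_c, stdev_c, sigma2, df, pr_min.to_numpy(), mod)
        table["sca.t"] = sca.sca_t
        table["sca.P.Value"] = sca.sca_p
        table["sca.adj.pval"] = sca.sca_adj_p
        table["count"] = pr_min.to_numpy()
    table = table[[c for c in RESULT_COLUMNS if c in table.columns]]
    return CentralizedFit(
        table=table,
        proteins=retained,
        variables=variables,
        mask=mask,
        beta=beta,
        stdev_unscaled=stdev_unscaled,
        sigma2=sigma2,
        df_residual=df,
        df_prior=df_prior,
        s2_prior=s2_prior,
        pooled_Y=Y,
        pooled_X=X,
        singular=singular,
    )
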
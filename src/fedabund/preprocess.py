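"""Missing-value filters and normalization.

All cross-client decisions here depend only on *sums* of client-level
counts or medians, so in the federated engine every aggregated quantity can
travel through the secure-sum channel; the same functions back the pooled
reference pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "mask_design_column_singletons",
    "class_observed_counts",
    "retained_by_missingness",
    "sample_medians",
    "global_median_mean",
    "median_scale",
    "irs_normalize",
    "log_transform",
]


def mask_design_column_singletons(
    intensities: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Blank values that are the only observation within a design column.

    For every design column, consider the samples that carry a nonzero
    entry: if a protein has exactly one observed intensity among them, that
    value is set to missing.  Like the whole-cohort single-observation rule
    this prevents an individual measurement from being recoverable from
    aggregate counts or sums.
    """
    vals = intensities.to_numpy(copy=True)
    masked = 0
    design = design.loc[intensities.columns]
    for col in design.columns:
        sel = design[col].to_numpy() != 0
        if sel.sum() == 0:
            continue
        sub = vals[:, sel]
        obs = np.isfinite(sub)
        hit = obs.sum(axis=1) == 1
        if hit.any():
            sub[hit] = np.nan
            vals[:, sel] = sub
            masked += int(hit.sum())
    return (
        pd.DataFrame(vals, index=intensities.index, columns=intensities.columns),
        masked,
    )


def class_observed_counts(
    intensities: pd.DataFrame, design: pd.DataFrame, target_classes: tuple[str, str]
) -> np.ndarray:
    """(n_proteins, 2) observed-sample counts per target class."""
    design = design.loc[intensities.columns]
    obs = np.isfinite(intensities.to_numpy())
    return np.column_stack(
        [obs[:, design[c].to_numpy() != 0].sum(axis=1) for c in target_classes]
    )


def retained_by_missingness(
    global_counts: np.ndarray,
    class_totals: np.ndarray,
    f: float,
    mode: str = "max_missing",
) -> np.ndarray:
    """Keep proteins with enough observations in *every* target class.

    ``mode="max_missing"`` (default, f = 0.8): a protein survives when each
    class is missing in at most a fraction ``f`` of its samples, i.e. is
    observed in at least ``1 - f``.  ``mode="min_observed"``: each class
    must be observed in at least a fraction ``f``.
    """
    if not 0.0 < f <= 1.0:
        raise ValueError("filter fraction must be in (0, 1]")
    frac = global_counts / np.asarray(class_totals, float)[None, :]
    thresh = (1.0 - f) if mode == "max_missing" else f
    return np.all(frac >= thresh, axis=1)


def sample_medians(intensities: pd.DataFrame) -> pd.Series:
    """Per-sample median over observed proteins; errors on empty/zero."""
    vals = intensities.to_numpy()
    meds = np.full(vals.shape[1], np.nan)
    for j, sample in enumerate(intensities.columns):
        col = vals[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            raise ValueError(f"sample {sample!r} has no observed values")
        med = float(np.median(col))
        if med == 0.0:
            raise ValueError(f"sample {sample!r} has zero median intensity")
        meds[j] = med
    return pd.Series(meds, index=intensities.columns)


def global_median_mean(client_stats: list[tuple[float, int]]) -> float:
    """Sample-count-weighted mean of per-client mean sample medians."""
    num = sum(mean_med * m for mean_med, m in client_stats)
    den = sum(m for _, m in client_stats)
    if den == 0:
        raise ValueError("no samples across clients")
    return num / den


def median_scale(intensities: pd.DataFrame, target_median: float) -> pd.DataFrame:
    """Rescale each sample so its median becomes ``target_median``."""
    meds = sample_medians(intensities)
    return intensities / meds * target_median


def irs_normalize(
    intensities: pd.DataFrame, plex_assignment: pd.Series
) -> tuple[pd.DataFrame, list[str]]:
    """Internal reference scaling with per-plex in-silico references.

    Each plex's reference is the per-protein mean over its samples; every
    plex is scaled by (geometric mean of references) / (own reference).
    Proteins whose reference is undefined or non-positive in any plex are
    left unscaled and reported back, never silently rescaled.
    """
    plex_assignment = plex_assignment.loc[intensities.columns]
    plexes = list(dict.fromkeys(plex_assignment))
    for plex in plexes:
        if (plex_assignment == plex).sum() == 0:
            raise ValueError(f"plex {plex!r} has no samples")
    vals = intensities.to_numpy(copy=True)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN plex rows
        refs = np.column_stack(
            [
                np.nanmean(vals[:, (plex_assignment == plex).to_numpy()], axis=1)
                for plex in plexes
            ]
        )
    ok = np.all(np.isfinite(refs) & (refs > 0), axis=1)
    gm = np.full(vals.shape[0], np.nan)
    gm[ok] = np.exp(np.mean(np.log(refs[ok]), axis=1))
    for k, plex in enumerate(plexes):
        sel = (plex_assignment == plex).to_numpy()
        sf = gm / refs[:, k]
        vals[np.ix_(ok, sel)] = vals[np.ix_(ok, sel)] * sf[ok, None]
    flagged = list(intensities.index[~ok])
    return (
        pd.DataFrame(vals, index=intensities.index, columns=intensities.columns),
        flagged,
    )


def log_transform(intensities: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1); missing cells stay missing."""
    vals = intensities.to_numpy()
    if np.any(vals[np.isfinite(vals)] < 0):
        raise ValueError("negative intensities cannot be log-transformed")
    return pd.DataFrame(
        np.log2(vals + 1.0), index=intensities.index, columns=intensities.columns
    )
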
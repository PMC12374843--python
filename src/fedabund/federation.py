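"""The federated study protocol.

A study runs in seven steps between ``k >= 2`` clients and a coordinator:

1. join & harmonize — clients announce sample counts, protein-group lists
   and (optionally) minimal precursor-peptide counts; the coordinator forms
   the global feature set, the model variable list (target classes,
   covariates, cohort indicators with client 1 as reference) and global
   minimal counts, and runs the privacy guard;
2. filtering — design-column singleton masking on each client, then the
   global per-class missing-value filter and the optional single-peptide
   filter, all from securely summed counts;
3. (optional) normalization — cross-client median normalization and/or
   per-client internal reference scaling, then optional log2(x+1);
4. design-mask creation from securely summed observation counts;
5. federated least squares — secure sums of per-client X'X, X'Y, then SSE;
6. contrast fitting, empirical-Bayes moderation, BH adjustment (server);
7. (optional) peptide-count-adjusted moderation (server).

Every cross-client numeric aggregate travels through additive secret
sharing; the coordinator only ever sees share-sums, feature names,
dimensions and global model parameters.  A transcript of coordinator-bound
messages is recorded so tests can audit exactly that.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess, stats
from .io import ClientBundle, StudyConfig, RESULT_COLUMNS
from .secagg import FixedPointEncoding, secure_sum

__all__ = ["StudyAborted", "StudyState", "harmonize_features", "privacy_guard", "run_study"]


class StudyAborted(RuntimeError):
    """The privacy guard or a protocol precondition stopped the study."""


@dataclass
class Message:
    sender: str
    kind: str
    shape: tuple | None = None
    payload: object = None


@dataclass
class StudyState:
    """Coordinator-side view of the study as it advances through steps."""

    step: int
    proteins: list[str]
    variables: list[str]
    class_cols: tuple[int, int]
    cohort_of_col: dict[int, int]
    m_per_client: list[int]
    client_ids: list[str]
    pr_min: pd.Series | None
    reference_cohort: int = 0
    transcript: list[Message] = field(default_factory=list)
    mask: stats.DesignMask | None = None
    log: list[str] = field(default_factory=list)

    @property
    def n_clients(self) -> int:
        return len(self.m_per_client)


def harmonize_features(bundles: list[ClientBundle], config: StudyConfig) -> StudyState:
    """Step 1: build the global feature set, variable list and count table."""
    if len(bundles) < 2:
        raise StudyAborted(f"expected >= 2 clients, got {len(bundles)}")
    ids = [b.client_id for b in bundles]
    if len(set(ids)) != len(ids):
        raise StudyAborted("duplicate client ids")
    for b in bundles:
        if b.n_samples == 0:
            raise StudyAborted(f"client {b.client_id!r} has zero samples")
    if len(bundles) != config.expected_clients:
        raise StudyAborted(
            f"study configured for {config.expected_clients} clients, "
            f"{len(bundles)} joined"
        )
    proteins = sorted(set().union(*[set(b.intensities.index) for b in bundles]))
    variables = [*config.target_classes, *config.covariates]
    class_cols = (0, 1)
    cohort_of_col: dict[int, int] = {}
    for i, b in enumerate(bundles[1:], start=1):
        cohort_of_col[len(variables)] = i
        variables.append(f"cohort_{b.client_id}")
    pr_min = None
    if config.use_counts and all(b.counts is not None for b in bundles):
        counts = pd.concat(
            [b.counts.reindex(proteins) for b in bundles], axis=1
        )
        pr_min = counts.min(axis=1, skipna=True)
    state = StudyState(
        step=1,
        proteins=proteins,
        variables=variables,
        class_cols=class_cols,
        cohort_of_col=cohort_of_col,
        m_per_client=[b.n_samples for b in bundles],
        client_ids=ids,
        pr_min=pr_min,
    )
    for b in bundles:
        state.transcript.append(Message(b.client_id, "protein_list", payload=len(b.intensities.index)))
        state.transcript.append(Message(b.client_id, "n_samples", payload=b.n_samples))
        if pr_min is not None:
            state.transcript.append(Message(b.client_id, "peptide_min_counts", shape=(len(proteins),)))
    if len(bundles) < 3:
        state.log.append(
            "fewer than 3 clients: additive secret sharing degrades to "
            "pairwise masking; proceeding with a warning"
        )
    return state


def privacy_guard(state: StudyState) -> None:
    """Abort when clients outnumber the pooled samples (equality passes)."""
    total = sum(state.m_per_client)
    if state.n_clients > total:
        state.log.append(
            f"aborted: {state.n_clients} clients exceed {total} total samples"
        )
        raise StudyAborted(
            f"privacy guard: {state.n_clients} clients joined but only "
            f"{total} samples exist in total"
        )


def _client_design(bundle: ClientBundle, state: StudyState) -> pd.DataFrame:
    """Expand a client's design to the global variable list (cohort coding)."""
    cohort = state.client_ids.index(bundle.client_id)
    X = pd.DataFrame(0.0, index=bundle.design.index, columns=state.variables)
    for var in state.variables:
        if var in bundle.design.columns:
            X[var] = bundle.design[var]
    for col, coh in state.cohort_of_col.items():
        X.iloc[:, col] = 1.0 if coh == cohort else 0.0
    return X


def _secure(state, rng, blocks, kind):
    """Route one round of blocks through the secret-sharing channel."""
    out = secure_sum(
        blocks,
        n_parties=max(len(blocks), 2),
        encoding=FixedPointEncoding(),
        rng=rng,
    )
    state.transcript.append(
        Message("all-parties", f"secure_sum:{kind}", shape=np.asarray(out).shape)
    )
    return out


def run_study(
    config: StudyConfig,
    bundles: list[ClientBundle],
    return_state: bool = False,
):
    """Execute the full federated analysis and return the result table.

    ``bundles`` must already be validated client inputs (see
    :func:`fedabund.io.validate_client_inputs`).  The returned table is the
    one every client receives; with ``return_state=True`` the coordinator
    state (including the protocol transcript) is returned as well.
    """
    rng = random.Random(config.seed)
    state = harmonize_features(bundles, config)
    privacy_guard(state)

    # expand every client to the global feature set and variable list
    mats = [b.intensities.reindex(state.proteins) for b in bundles]
    designs = [_client_design(b, state) for b in bundles]

    # ---- step 2: filters -------------------------------------------------
    state.step = 2
    for i in range(len(mats)):
        mats[i], _ = preprocess.mask_design_column_singletons(mats[i], designs[i])
    class_counts = _secure(
        state,
        rng,
        [
            preprocess.class_observed_counts(m, d, config.target_classes)
            for m, d in zip(mats, designs)
        ],
        "class_observed_counts",
    )
    class_totals = _secure(
        state,
        rng,
        [
            np.array([float((d[c] != 0).sum()) for c in config.target_classes])
            for d in designs
        ],
        "class_sample_totals",
    )
    keep = preprocess.retained_by_missingness(
        class_counts, class_totals, config.filter_fraction, config.filter_mode
    )
    if config.single_peptide_filter and state.pr_min is not None:
        keep &= (state.pr_min.to_numpy() != 1.0) | ~np.isfinite(state.pr_min.to_numpy())
    retained = [p for p, k in zip(state.proteins, keep) if k]
    state.proteins = retained
    if state.pr_min is not None:
        state.pr_min = state.pr_min.loc[retained]
    mats = [m.loc[retained] for m in mats]

    # ---- step 3: normalization (optional) --------------------------------
    state.step = 3
    if config.normalization in ("median", "irs_median"):
        med_stats = []
        for m in mats:
            meds = preprocess.sample_medians(m)
            med_stats.append(
                np.array([float(meds.mean()) * m.shape[1], float(m.shape[1])])
            )
        agg = _secure(state, rng, med_stats, "median_stats")
        global_med = agg[0] / agg[1]
        mats = [preprocess.median_scale(m, global_med) for m in mats]
    if config.normalization == "irs_median":
        for i, b in enumerate(bundles):
            if "plex" in b.design.columns:
                plex = b.design["plex"].loc[mats[i].columns]
                mats[i], flagged = preprocess.irs_normalize(mats[i], plex)
                if flagged:
                    state.log.append(
                        f"{b.client_id}: {len(flagged)} protein(s) left "
                        "unscaled by IRS (undefined reference)"
                    )
    if config.log_transform:
        mats = [preprocess.log_transform(m) for m in mats]

    # ---- step 4: design mask ---------------------------------------------
    state.step = 4
    k, v = state.n_clients, len(state.variables)
    count_blocks = []
    for i, (m, d) in enumerate(zip(mats, designs)):
        obs = np.isfinite(m.to_numpy())
        per_cohort = np.zeros((len(retained), k))
        per_cohort[:, i] = obs.sum(axis=1)
        X = d.to_numpy()
        support = np.column_stack(
            [obs[:, X[:, c] != 0].sum(axis=1) for c in range(v)]
        )
        count_blocks.append(np.concatenate([per_cohort, support], axis=1))
    counts_agg = _secure(state, rng, count_blocks, "observation_counts")
    structure = stats.DesignStructure(
        columns=tuple(state.variables),
        class_cols=state.class_cols,
        cohort_of_col=state.cohort_of_col,
        n_cohorts=k,
        reference_cohort=0,
    )
    mask = stats.build_design_mask(counts_agg[:, :k], counts_agg[:, k:], structure)
    state.mask = mask

    # ---- step 5: federated linear model ----------------------------------
    state.step = 5
    moment_blocks = [
        stats.local_moments(m.to_numpy(), d.to_numpy()) for m, d in zip(mats, designs)
    ]
    xtx = _secure(state, rng, [b[0] for b in moment_blocks], "xtx")
    xty = _secure(state, rng, [b[1] for b in moment_blocks], "xty")
    beta, stdev_unscaled, cov, singular = stats.solve_global_lm(xtx, xty, mask)
    sse = _secure(
        state,
        rng,
        [
            stats.residual_sse(m.to_numpy(), d.to_numpy(), beta)
            for m, d in zip(mats, designs)
        ],
        "sse",
    )
    df = mask.df_residual.astype(float)
    df[singular] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma2 = np.where(df > 0, sse / df, np.nan)

    # ---- step 6: contrast + moderation -----------------------------------
    state.step = 6
    K = np.zeros(v)
    K[state.class_cols[0]] = 1.0
    K[state.class_cols[1]] = -1.0
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

    # ---- step 7: peptide-count adjustment (optional) ----------------------
    if state.pr_min is not None:
        state.step = 7
        sca = stats.count_adjust(
            beta_c, stdev_c, sigma2, df, state.pr_min.to_numpy(), mod
        )
        table["sca.t"] = sca.sca_t
        table["sca.P.Value"] = sca.sca_p
        table["sca.adj.pval"] = sca.sca_adj_p
        table["count"] = state.pr_min.to_numpy()
    table = table[[c for c in RESULT_COLUMNS if c in table.columns]]
    state.transcript.append(Message("coordinator", "result_table", shape=table.shape))
    if return_state:
        return table, state
    return table
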
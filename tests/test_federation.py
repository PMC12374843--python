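"""Protocol behavior: equivalence, privacy transcript, determinism."""

import numpy as np
import pandas as pd
import pytest

from fedabund.centralized import run_centralized
from fedabund.federation import (
    StudyAborted,
    harmonize_features,
    privacy_guard,
    run_study,
)
from fedabund.io import ClientBundle, StudyConfig


def _bundle(cid, proteins, n_samples, counts=None, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"{cid}_s{j}" for j in range(n_samples)]
    intens = pd.DataFrame(
        rng.normal(5, 1, size=(len(proteins), n_samples)), index=proteins, columns=cols
    )
    half = n_samples // 2
    design = pd.DataFrame(
        {"A": [1.0] * half + [0.0] * (n_samples - half),
         "B": [0.0] * half + [1.0] * (n_samples - half)},
        index=cols,
    )
    c = pd.Series(counts, index=proteins, dtype=float) if counts is not None else None
    return ClientBundle(cid, intens, design, c)


# ------------------------------------------------------------ harmonize


def test_feature_union_and_global_min_counts():
    b1 = _bundle("c1", ["PA", "PB"], 4, counts=[3, 3])
    b2 = _bundle("c2", ["PB", "PC"], 4, counts=[1, 5], seed=1)
    cfg = StudyConfig(expected_clients=2, use_counts=True)
    state = harmonize_features([b1, b2], cfg)
    assert state.proteins == ["PA", "PB", "PC"]
    assert state.pr_min.loc["PB"] == 1.0  # min of client minima 3 and 1
    assert np.isnan(state.pr_min.loc["PA"]) or state.pr_min.loc["PA"] == 3.0
    # 2 clients -> one cohort indicator column (reference dropped)
    assert state.variables == ["A", "B", "cohort_c2"]


def test_three_clients_gain_two_cohort_columns():
    bundles = [_bundle(f"c{i}", ["P1"], 4, seed=i) for i in range(3)]
    cfg = StudyConfig(expected_clients=3)
    state = harmonize_features(bundles, cfg)
    assert state.variables[-2:] == ["cohort_c1", "cohort_c2"]


def test_single_bundle_rejected():
    with pytest.raises(StudyAborted, match=">= 2"):
        harmonize_features([_bundle("c1", ["P1"], 4)], StudyConfig())


def test_duplicate_client_ids_rejected():
    with pytest.raises(StudyAborted, match="duplicate"):
        harmonize_features(
            [_bundle("c1", ["P1"], 4), _bundle("c1", ["P1"], 4)],
            StudyConfig(expected_clients=2),
        )


# ---------------------------------------------------------- privacy guard


def _state_with(m_per_client):
    cfg = StudyConfig(expected_clients=len(m_per_client))
    bundles = [
        _bundle(f"c{i}", ["P1", "P2"], m, seed=i) for i, m in enumerate(m_per_client)
    ]
    return harmonize_features(bundles, cfg)


def test_guard_passes_when_samples_outnumber_clients():
    privacy_guard(_state_with([20, 20, 20]))


def test_guard_aborts_when_clients_exceed_samples():
    state = _state_with([1, 1, 1, 1, 1])
    state.m_per_client = [1, 1, 1, 0, 0]  # 5 clients, 2 samples
    with pytest.raises(StudyAborted, match="privacy guard"):
        privacy_guard(state)


def test_guard_boundary_equality_passes():
    privacy_guard(_state_with([1, 1]))


# ------------------------------------------------------- end-to-end runs


def test_federated_equals_centralized_on_tiny_study(tiny_study, tiny_config):
    bundles, _, _ = tiny_study
    fed = run_study(tiny_config, bundles)
    cen = run_centralized(bundles, tiny_config).table
    assert list(fed.index) == list(cen.index)
    for col in ("logFC", "t", "P.Value", "adj.P.Val", "sca.t", "sca.adj.pval"):
        np.testing.assert_allclose(
            fed[col].to_numpy(), cen[col].to_numpy(), atol=1e-10, equal_nan=True
        )
    neglog = lambda t: -np.log10(np.maximum(t["adj.P.Val"].to_numpy(), 1e-300))
    assert np.nanmax(np.abs(neglog(fed) - neglog(cen))) < 1e-10


def test_result_table_is_deterministic(tiny_study, tiny_config):
    bundles, _, _ = tiny_study
    a = run_study(tiny_config, bundles)
    b = run_study(tiny_config, bundles)
    pd.testing.assert_frame_equal(a, b, check_exact=True)


def test_client_order_changes_nothing_but_cohort_naming(tiny_study, tiny_config):
    bundles, _, _ = tiny_study
    fwd = run_study(tiny_config, bundles)
    rev = run_study(tiny_config, bundles[::-1])
    for col in ("logFC", "t", "P.Value", "adj.P.Val"):
        np.testing.assert_allclose(
            fwd[col].to_numpy(), rev[col].to_numpy(), atol=1e-8, equal_nan=True
        )


def test_counts_omitted_drops_sca_columns(tiny_study):
    bundles, _, _ = tiny_study
    stripped = [
        ClientBundle(b.client_id, b.intensities, b.design, None) for b in bundles
    ]
    cfg = StudyConfig(expected_clients=3, use_counts=True, seed=11)
    table = run_study(cfg, stripped)
    assert "sca.t" not in table.columns and "count" not in table.columns
    with_counts = run_study(StudyConfig(expected_clients=3, use_counts=True, seed=11), bundles)
    assert {"sca.t", "sca.P.Value", "sca.adj.pval", "count"} <= set(with_counts.columns)


def test_transcript_contains_only_aggregates_and_metadata(tiny_study, tiny_config):
    bundles, _, _ = tiny_study
    n_samples = {b.intensities.shape[1] for b in bundles}
    _, state = run_study(tiny_config, bundles, return_state=True)
    allowed_prefixes = (
        "protein_list",
        "n_samples",
        "peptide_min_counts",
        "secure_sum:",
        "result_table",
    )
    for msg in state.transcript:
        assert msg.kind.startswith(allowed_prefixes), msg.kind
        # no coordinator-bound numeric payload carries a per-sample axis
        if msg.shape is not None:
            assert not any(dim in n_samples for dim in msg.shape), msg


def test_missing_features_created_as_all_missing_rows():
    b1 = _bundle("c1", ["PA", "PB"], 8, seed=0)
    b2 = _bundle("c2", ["PB", "PC"], 8, seed=1)
    cfg = StudyConfig(expected_clients=2, use_counts=False, seed=0)
    table = run_study(cfg, [b1, b2])
    # every union feature survives (each class fully observed in one cohort)
    assert set(table.index) == {"PA", "PB", "PC"}
    assert np.isfinite(table.loc["PA", "logFC"])


def test_zero_sample_client_aborts_run_study():
    b1 = _bundle("c1", ["P1", "P2"], 4, seed=0)
    b2 = _bundle("c2", ["P1", "P2"], 4, seed=1)
    b3 = _bundle("c3", ["P1", "P2"], 0, seed=2)
    cfg = StudyConfig(expected_clients=3, use_counts=False)
    with pytest.raises(StudyAborted, match="zero samples"):
        run_study(cfg, [b1, b2, b3])
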
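"""Multi-cohort proteomics-like data with known ground truth.

The generator emulates label-free protein quantification after MaxLFQ-style
normalization: per-protein population means and variances are drawn once
(``mu_p ~ N(0, 2)``, ``sigma_p^2 ~ InvGamma(shape 2, scale 3)``), cell
intensities come from a two-component mixture with outlier proportion
``pi_p``, a block of differentially abundant proteins is shifted by
``delta_mu`` in condition B (each protein realizes the shift with
probability 0.8, with a random up/down direction), and a second block is
shifted only in "confounded" class-B samples whose per-cohort frequency
creates the imbalance scenarios.  Cohort-aligned batch effects follow the
location-scale (ComBat-style) model ``y + gamma_pi + delta_pi * eps``, and
missing values combine intensity-dependent (MNAR) and completely random
dropout at controlled overall rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ClientBundle, StudyConfig, write_matrix

__all__ = [
    "SimulationParams",
    "Scenario",
    "SCENARIOS",
    "simulate_base",
    "add_batch_effects",
    "add_missing",
    "split_cohorts",
    "simulate_study",
    "write_bundles",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generative settings; defaults are the package's study conditions."""

    n_proteins: int = 6000
    n_per_condition: int = 300
    mu_mean: float = 0.0
    mu_var: float = 2.0
    var_shape: float = 2.0
    var_scale: float = 3.0
    outlier_prop: float = 0.0
    de_block: int = 200
    conf_block: int = 150
    delta_mu: float = 1.25
    shift_prob: float = 0.8
    mv_rate: float = 0.2
    mnar_rate: float = 0.5
    #: (gamma_mean, gamma_var, delta_shape, delta_scale) per batch
    batch_params: tuple = (
        (0.0, 1.0, 3.0, 2.0),
        (0.2, 0.5, 2.5, 1.0),
        (-0.2, 1.5, 4.0, 0.5),
    )
    count_poisson_mean: float = 3.0

    def __post_init__(self):
        if not 0.0 <= self.outlier_prop < 0.5:
            raise ValueError("outlier proportion must be in [0, 0.5)")
        if self.de_block + self.conf_block > self.n_proteins:
            raise ValueError("DE and confounder blocks exceed protein count")
        if not 0.0 <= self.mv_rate < 1.0:
            raise ValueError("missing-value rate must be in [0, 1)")
        if not 0.0 <= self.mnar_rate <= 1.0:
            raise ValueError("MNAR rate must be in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """Cohort sizes, class-B counts and confounder frequencies per cohort."""

    name: str
    cohort_sizes: tuple[int, ...]
    class_b_counts: tuple[int, ...]
    confounder_freq: tuple[float, ...]


SCENARIOS: dict[str, Scenario] = {
    "balanced": Scenario("balanced", (200, 200, 200), (100, 100, 100), (0.3, 0.3, 0.3)),
    "mild": Scenario("mild", (150, 200, 250), (60, 100, 140), (0.1, 0.3, 0.5)),
    "strong": Scenario("strong", (100, 200, 300), (20, 100, 180), (0.0, 0.2, 0.8)),
}


def _invgamma(rng: np.random.Generator, shape: float, scale: float, size) -> np.ndarray:
    # density proportional to x^(-shape-1) exp(-scale/x)
    return scale / rng.gamma(shape, 1.0, size=size)


def _sample_frame(scenario: Scenario, rng: np.random.Generator) -> pd.DataFrame:
    """Per-sample cohort, condition and confounder-status assignment."""
    rows = []
    for c, (size, nb, cf) in enumerate(
        zip(scenario.cohort_sizes, scenario.class_b_counts, scenario.confounder_freq)
    ):
        if nb > size:
            raise ValueError(f"cohort {c}: class-B count exceeds cohort size")
        cond = np.array(["B"] * nb + ["A"] * (size - nb))
        rng.shuffle(cond)
        conf = np.zeros(size, dtype=bool)
        b_idx = np.flatnonzero(cond == "B")
        n_conf = int(round(cf * nb))
        conf[rng.choice(b_idx, size=n_conf, replace=False)] = True
        for j in range(size):
            rows.append((f"c{c + 1}_s{j + 1}", c, cond[j], conf[j]))
    return pd.DataFrame(
        rows, columns=["sample_id", "cohort", "condition", "confounder"]
    ).set_index("sample_id")


def simulate_base(
    params: SimulationParams,
    rng: np.random.Generator,
    samples: pd.DataFrame,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw base intensities (no batch effects, no missingness).

    ``samples`` carries per-sample condition and confounder status.  The
    first ``de_block`` proteins form the differential block, the next
    ``conf_block`` the confounder block.  Returns the intensity array and
    the per-protein ground truth.
    """
    n, m = params.n_proteins, len(samples)
    if n == 0:
        return np.empty((0, m)), pd.DataFrame(
            columns=["is_de", "realized_shift", "is_confounder_block", "shift_sign"]
        )
    mu = rng.normal(params.mu_mean, np.sqrt(params.mu_var), size=n)
    sigma2 = _invgamma(rng, params.var_shape, params.var_scale, size=n)
    y = mu[:, None] + np.sqrt(sigma2)[:, None] * rng.standard_normal((n, m))
    if params.outlier_prop > 0:
        pi = np.full(n, params.outlier_prop)
        outlier = rng.random((n, m)) < pi[:, None]
        y += outlier * params.delta_mu

    is_de = np.zeros(n, dtype=bool)
    is_conf = np.zeros(n, dtype=bool)
    is_de[: params.de_block] = True
    is_conf[params.de_block : params.de_block + params.conf_block] = True
    realized = np.zeros(n, dtype=bool)
    sign = np.zeros(n)
    block = is_de | is_conf
    realized[block] = rng.random(block.sum()) < params.shift_prob
    sign[block] = rng.choice([-1.0, 1.0], size=block.sum())

    in_b = (samples["condition"] == "B").to_numpy()
    conf_sample = samples["confounder"].to_numpy()
    de_rows = is_de & realized
    y[np.ix_(de_rows, in_b)] += (sign[de_rows] * params.delta_mu)[:, None]
    conf_rows = is_conf & realized
    y[np.ix_(conf_rows, conf_sample)] += (sign[conf_rows] * params.delta_mu)[:, None]

    truth = pd.DataFrame(
        {
            "is_de": is_de,
            "realized_shift": realized,
            "is_confounder_block": is_conf,
            "shift_sign": sign,
            "mu": mu,
            "sigma2": sigma2,
        },
        index=pd.Index([f"P{i + 1:05d}" for i in range(n)], name="protein_group"),
    )
    return y, truth


def add_batch_effects(
    y: np.ndarray,
    batch: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Location-scale batch effects ``y + gamma_pi + delta_pi * eps``."""
    y = y.copy()
    batch = np.asarray(batch)
    ids = np.unique(batch)
    if np.any(ids >= len(params.batch_params)) or np.any(ids < 0):
        raise ValueError("unknown batch id")
    n = y.shape[0]
    for b in ids:
        g_mean, g_var, d_shape, d_scale = params.batch_params[int(b)]
        gamma = rng.normal(g_mean, np.sqrt(g_var), size=n)
        delta = _invgamma(rng, d_shape, d_scale, size=n)
        sel = batch == b
        eps = rng.standard_normal((n, int(sel.sum())))
        y[:, sel] += gamma[:, None] + delta[:, None] * eps
    return y


def add_missing(
    y: np.ndarray,
    mv_rate: float,
    mnar_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Introduce missing values at an exact overall rate.

    A fraction ``mnar_rate`` of the missing cells is chosen intensity-
    dependently (low-intensity cells of each protein are strongly
    preferred, via tricube-decaying weights on the within-protein intensity
    quantile); the remainder is missing completely at random.  Returns the
    matrix plus boolean MNAR and MCAR masks.
    """
    if mv_rate >= 1.0:
        raise ValueError("missing-value rate must be < 1")
    n, m = y.shape
    out = y.copy()
    mnar_mask = np.zeros((n, m), dtype=bool)
    mcar_mask = np.zeros((n, m), dtype=bool)
    total = int(round(mv_rate * n * m))
    if total == 0:
        return out, mnar_mask, mcar_mask
    n_mnar = int(round(mnar_rate * total))
    n_mcar = total - n_mnar
    if n_mnar > 0:
        ranks = np.argsort(np.argsort(y, axis=1), axis=1)
        q = ranks / max(m - 1, 1)
        logw = 3.0 * np.log1p(-(q ** 3) * (1 - 1e-12))
        gumbel = rng.gumbel(size=(n, m))
        key = (logw + gumbel).ravel()
        chosen = np.argpartition(-key, n_mnar - 1)[:n_mnar]
        mnar_mask.ravel()[chosen] = True
    if n_mcar > 0:
        remaining = np.flatnonzero(~mnar_mask.ravel())
        chosen = rng.choice(remaining, size=n_mcar, replace=False)
        mcar_mask.ravel()[chosen] = True
    out[mnar_mask | mcar_mask] = np.nan
    return out, mnar_mask, mcar_mask


def split_cohorts(
    y: np.ndarray,
    truth: pd.DataFrame,
    samples: pd.DataFrame,
    params: SimulationParams,
    rng: np.random.Generator,
    with_counts: bool = False,
) -> list[ClientBundle]:
    """Partition the sample columns into per-cohort client bundles."""
    proteins = truth.index
    counts = None
    if with_counts:
        counts = pd.Series(
            1 + rng.poisson(params.count_poisson_mean, size=len(proteins)),
            index=proteins,
            dtype=float,
        )
    bundles = []
    for c in sorted(samples["cohort"].unique()):
        sel = (samples["cohort"] == c).to_numpy()
        cols = samples.index[sel]
        intens = pd.DataFrame(y[:, sel], index=proteins, columns=cols)
        cond = samples.loc[cols, "condition"]
        design = pd.DataFrame(
            {
                "A": (cond == "A").astype(float),
                "B": (cond == "B").astype(float),
            },
            index=cols,
        )
        bundles.append(
            ClientBundle(
                client_id=f"cohort{c + 1}",
                intensities=intens,
                design=design,
                counts=counts.copy() if counts is not None else None,
            )
        )
    return bundles


def simulate_study(
    scenario: str | Scenario = "balanced",
    params: SimulationParams | None = None,
    seed: int = 0,
    with_counts: bool = False,
) -> tuple[list[ClientBundle], pd.DataFrame, pd.DataFrame]:
    """End-to-end generation of one multi-cohort study.

    Returns ``(bundles, protein_truth, sample_frame)``.  Batches coincide
    with cohorts, as in a multi-center study where each center is one
    measurement batch.
    """
    params = params or SimulationParams()
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    total = sum(scenario.cohort_sizes)
    if total != 2 * params.n_per_condition:
        params = replace(params, n_per_condition=total // 2)
    rng = np.random.default_rng(seed)
    samples = _sample_frame(scenario, rng)
    y, truth = simulate_base(params, rng, samples)
    y = add_batch_effects(y, samples["cohort"].to_numpy(), params, rng)
    y, _, _ = add_missing(y, params.mv_rate, params.mnar_rate, rng)
    bundles = split_cohorts(y, truth, samples, params, rng, with_counts=with_counts)
    return bundles, truth, samples


def write_bundles(bundles: list[ClientBundle], outdir) -> None:
    """Emit per-client directories of intensities/design/counts TSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    for b in bundles:
        d = outdir / b.client_id
        d.mkdir(parents=True, exist_ok=True)
        write_matrix(b.intensities, d / "intensities.tsv")
        write_matrix(b.design, d / "design.tsv")
        if b.counts is not None:
            write_matrix(b.counts.to_frame("min_count"), d / "counts.tsv")
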
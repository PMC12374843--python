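"""Study configuration, per-client TSV inputs and the result table.

Each client contributes up to three tab-separated files:

* an intensity matrix (protein groups x samples, empty/``NA``/``NaN`` cells
  are missing),
* a design matrix (samples x model variables; the two target classes are
  one-hot columns, optional covariates follow),
* optionally one minimal precursor-peptide count per protein group.

Protein-group identifiers are normalised by sorting the accessions inside a
group alphabetically, which makes groups assembled independently by
different sites comparable.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MISSING_TOKENS = ("", "NA", "NaN", "nan", "na")

RESULT_COLUMNS = [
    "logFC",
    "CI.L",
    "CI.R",
    "t",
    "P.Value",
    "adj.P.Val",
    "B",
    "sca.t",
    "sca.P.Value",
    "sca.adj.pval",
    "count",
]


class InputFormatError(ValueError):
    """A per-client TSV failed validation."""


def normalize_protein_group_id(pg: str) -> str:
    """Sort the accessions inside a protein-group identifier."""
    return ";".join(sorted(part.strip() for part in str(pg).split(";")))


@dataclass
class StudyConfig:
    """Coordinator-side settings shared by every client in a study."""

    target_classes: tuple[str, str] = ("A", "B")
    covariates: tuple[str, ...] = ()
    expected_clients: int = 3
    filter_fraction: float = 0.8
    #: "max_missing": keep a protein when every target class is missing in at
    #: most ``filter_fraction`` of its samples. "min_observed": keep when
    #: every class is *observed* in at least ``filter_fraction``.
    filter_mode: str = "max_missing"
    single_peptide_filter: bool = False
    normalization: str = "none"  # none | median | irs_median
    log_transform: bool = False
    lfc_threshold: float = 1.0
    alpha: float = 0.05
    p_de: float = 0.01
    use_counts: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.filter_fraction <= 1.0:
            raise ValueError("filter_fraction must be in (0, 1]")
        if self.expected_clients < 2:
            raise ValueError("a federated study needs at least 2 clients")
        if len(self.target_classes) != 2:
            raise ValueError("exactly two target classes are required")
        if self.normalization not in ("none", "median", "irs_median"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.filter_mode not in ("max_missing", "min_observed"):
            raise ValueError(f"unknown filter_mode {self.filter_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["target_classes"] = tuple(raw.get("target_classes", ("A", "B")))
        raw["covariates"] = tuple(raw.get("covariates", ()))
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["target_classes"] = list(d["target_classes"])
        d["covariates"] = list(d["covariates"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _read_tsv(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"{what} file not found: {path}")
    text = path.read_text()
    if not text.strip():
        raise InputFormatError(f"{what} file {path} has no data rows")
    df = pd.read_csv(
        _io.StringIO(text),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    if df.shape[0] == 0:
        raise InputFormatError(f"{what} file {path} has no data rows")
    if df.shape[1] == 0:
        raise InputFormatError(f"{what} file {path} has a malformed header")
    return df


def _to_float(df: pd.DataFrame, what: str) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col]
        vals = np.empty(len(raw))
        for i, cell in enumerate(raw):
            s = cell.strip()
            if s in MISSING_TOKENS:
                vals[i] = np.nan
                continue
            try:
                vals[i] = float(s)
            except ValueError as exc:
                raise InputFormatError(
                    f"non-numeric cell {cell!r} in {what} at row "
                    f"{df.index[i]!r}, column {col!r}"
                ) from exc
        out[col] = vals
    return out


def read_intensity_matrix(path: str | Path) -> pd.DataFrame:
    """Read a protein-group x sample intensity TSV (NaN = missing)."""
    df = _read_tsv(path, "intensity matrix")
    df.index = [normalize_protein_group_id(i) for i in df.index]
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise InputFormatError(f"duplicate protein group id {dup[0]!r}")
    if df.columns.duplicated().any():
        raise InputFormatError("duplicate sample ids in intensity matrix header")
    return _to_float(df, "intensity matrix")


def read_design_matrix(path: str | Path) -> pd.DataFrame:
    """Read a sample x variable design TSV."""
    df = _read_tsv(path, "design matrix")
    if df.index.duplicated().any():
        raise InputFormatError("duplicate sample ids in design matrix")
    return _to_float(df, "design matrix")


def read_peptide_counts(path: str | Path) -> pd.Series:
    """Read minimal precursor-peptide counts (one value per protein group)."""
    df = _read_tsv(path, "peptide counts")
    df.index = [normalize_protein_group_id(i) for i in df.index]
    if df.index.duplicated().any():
        raise InputFormatError("duplicate protein group id in peptide counts")
    counts = _to_float(df, "peptide counts").iloc[:, 0]
    bad = counts[(counts < 1) & counts.notna()]
    if len(bad):
        raise InputFormatError(
            f"peptide count < 1 for protein group {bad.index[0]!r}"
        )
    return counts


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    """Write a numeric matrix TSV that round-trips float64 bit-exactly."""
    df.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA")


def write_result_table(result: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in RESULT_COLUMNS if c in result.columns]
    write_matrix(result[cols], path)


def read_result_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, "result table")
    return _to_float(df, "result table")


@dataclass
class ClientBundle:
    """One client's validated inputs."""

    client_id: str
    intensities: pd.DataFrame
    design: pd.DataFrame
    counts: pd.Series | None = None

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]


@dataclass
class ValidationReport:
    """Outcome of client-side input validation."""

    bundle: ClientBundle
    n_single_value_masked: int = 0
    notes: list[str] = field(default_factory=list)


def mask_single_observations(intensities: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Blank protein rows with exactly one observed value in this cohort.

    A lone value would be recoverable from aggregate sums, so it is removed
    before any statistic leaves the client.
    """
    vals = intensities.to_numpy(copy=True)
    nobs = np.isfinite(vals).sum(axis=1)
    hit = nobs == 1
    vals[hit, :] = np.nan
    return pd.DataFrame(vals, index=intensities.index, columns=intensities.columns), int(hit.sum())


def validate_client_inputs(
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    counts: pd.Series | None,
    config: StudyConfig,
    client_id: str = "client",
) -> ValidationReport:
    """Check one client's inputs against the study configuration.

    Verifies sample-id consistency between intensity and design matrices,
    the presence and 0/1 coding of the target-class columns, and applies the
    single-observation privacy rule.  Idempotent.
    """
    missing_cols = [
        c for c in (*config.target_classes, *config.covariates) if c not in design.columns
    ]
    if missing_cols:
        raise InputFormatError(
            f"{client_id}: design matrix lacks required column(s) {missing_cols} "
            "specified by the coordinator"
        )
    if set(design.index) != set(intensities.columns):
        raise InputFormatError(
            f"{client_id}: design sample ids do not match intensity matrix columns"
        )
    design = design.loc[intensities.columns]
    classes = design[list(config.target_classes)].to_numpy()
    if not np.isin(classes, (0.0, 1.0)).all():
        raise InputFormatError(f"{client_id}: target-class columns must be 0/1")
    if not np.all(classes.sum(axis=1) == 1.0):
        raise InputFormatError(
            f"{client_id}: each sample must belong to exactly one target class"
        )
    cleaned, n_masked = mask_single_observations(intensities)
    if counts is not None:
        counts = counts.copy()
        counts.index = [normalize_protein_group_id(i) for i in counts.index]
    bundle = ClientBundle(client_id, cleaned, design, counts)
    notes = []
    if n_masked:
        notes.append(
            f"{client_id}: {n_masked} protein group(s) had a single observed "
            "value and were blanked"
        )
    return ValidationReport(bundle=bundle, n_single_value_masked=n_masked, notes=notes)


def load_client_dir(path: str | Path, config: StudyConfig, client_id: str | None = None) -> ValidationReport:
    """Load ``intensities.tsv``, ``design.tsv`` and optional ``counts.tsv``."""
    path = Path(path)
    cid = client_id or path.name
    intens = read_intensity_matrix(path / "intensities.tsv")
    design = read_design_matrix(path / "design.tsv")
    counts_path = path / "counts.tsv"
    counts = read_peptide_counts(counts_path) if counts_path.exists() else None
    return validate_client_inputs(intens, design, counts, config, client_id=cid)
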
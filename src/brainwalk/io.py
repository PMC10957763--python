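"""Reading, writing and constructing connectivity matrices.

Structural connectivity (SC) is built from white-matter fiber counts
normalized by ROI surface areas; functional connectivity (FC) from Pearson
correlations of regional time series with negative and self correlations
zeroed. Matrices are stored as delimited text (TSV by default, CSV
accepted), optionally with a header row of region labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: maximum |W - W.T| tolerated on read; larger asymmetry is a user error
ASYMMETRY_TOL = 1e-8


@dataclass
class ConnectivityMatrix:
    """A symmetric nonnegative n-by-n matrix of edge strengths for one subject.

    Parameters
    ----------
    weights
        Symmetric matrix with zero diagonal and nonnegative entries.
    modality
        Either ``"structural"`` or ``"functional"``. Functional entries are
        expected in [0, 1] (clamped Pearson correlations).
    region_labels
        Ordered ROI names; positional across subjects.
    """

    weights: np.ndarray
    modality: str
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError(f"connectivity matrix must be square, got {self.weights.shape}")
        if self.modality not in ("structural", "functional"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if np.isnan(self.weights).any():
            raise ValueError("connectivity matrix contains NaN entries")
        if (self.weights < 0).any():
            raise ValueError("connectivity matrix contains negative weights")
        if not np.allclose(self.weights, self.weights.T, atol=ASYMMETRY_TOL, rtol=0):
            raise ValueError("connectivity matrix asymmetric beyond tolerance")
        # canonical form: exactly symmetric, zero diagonal
        self.weights = 0.5 * (self.weights + self.weights.T)
        np.fill_diagonal(self.weights, 0.0)
        if not self.region_labels:
            self.region_labels = [f"ROI{i}" for i in range(self.n_regions)]
        if len(self.region_labels) != self.n_regions:
            raise ValueError("region_labels length does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class TimeSeriesMatrix:
    """Regional signal time courses: n regions by T timepoints."""

    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D regions x time array")
        if self.values.shape[1] < 3:
            raise ValueError("need at least 3 timepoints")
        if np.isnan(self.values).any():
            raise ValueError("time series contains missing values")
        if not self.region_labels:
            self.region_labels = [f"ROI{i}" for i in range(self.values.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class SubjectRecord:
    subject_id: str
    group_label: str
    sc_source: Path
    fc_source: Path


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "," if ("," in first and "\t" not in first) else "\t"


def read_connectivity_matrix(path: str | Path, modality: str) -> ConnectivityMatrix:
    """Read a square delimited numeric matrix, optionally with a label header.

    The matrix is validated (square, nonnegative for structural, symmetric
    within :data:`ASYMMETRY_TOL`), symmetrized by averaging, and its diagonal
    forced to zero.
    """
    path = Path(path)
    sep = _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, header=None)
    labels: list[str] = []
    if raw.iloc[0].apply(lambda v: isinstance(v, str)).any():
        labels = [str(v) for v in raw.iloc[0]]
        raw = raw.iloc[1:].reset_index(drop=True)
    values = raw.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"non-square matrix in {path}: shape {values.shape}")
    if not np.allclose(values, values.T, atol=ASYMMETRY_TOL, rtol=0):
        raise ValueError(f"matrix in {path} asymmetric beyond tolerance {ASYMMETRY_TOL}")
    return ConnectivityMatrix(values, modality, labels)


def write_connectivity_matrix(
    mat: ConnectivityMatrix, path: str | Path, header: bool = True
) -> None:
    """Write a matrix as TSV; inverse of :func:`read_connectivity_matrix`."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(mat.region_labels) + "\n")
        for row in mat.weights:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_timeseries(path: str | Path) -> TimeSeriesMatrix:
    """Read a regions x time TSV, optional label column is not supported:
    rows are regions in positional order."""
    path = Path(path)
    values = np.loadtxt(path, delimiter=_sniff_delimiter(path), ndmin=2)
    return TimeSeriesMatrix(values)


def fc_from_timeseries(ts: TimeSeriesMatrix) -> ConnectivityMatrix:
    """Functional connectivity: clamped Pearson correlation of regional series.

    Negative correlations carry no accepted biological interpretation and are
    set to zero, as are self-correlations. A region with a constant series has
    undefined correlations; its row/column is zeroed with a warning so one bad
    region does not abort a cohort run.
    """
    x = ts.values
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"constant time series for region(s) {np.where(constant)[0].tolist()}; "
            "their correlations are set to 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    r[constant, :] = 0.0
    r[:, constant] = 0.0
    np.clip(r, 0.0, 1.0, out=r)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(r, "functional", list(ts.region_labels))


def sc_from_fibers(fiber_counts: np.ndarray, surface_areas: np.ndarray) -> ConnectivityMatrix:
    """Structural connectivity: fiber count over the sum of the two ROI areas.

    ``w_ij = fibers_ij / (area_i + area_j)``; invariant to scaling fibers and
    areas by the same factor.
    """
    fibers = np.asarray(fiber_counts, dtype=float)
    areas = np.asarray(surface_areas, dtype=float)
    if (areas <= 0).any():
        raise ValueError("all surface areas must be positive")
    if fibers.shape[0] != fibers.shape[1] or fibers.shape[0] != areas.shape[0]:
        raise ValueError("fiber matrix and area vector shapes disagree")
    if not np.allclose(fibers, fibers.T, atol=ASYMMETRY_TOL, rtol=0):
        raise ValueError("fiber count matrix must be symmetric")
    denom = areas[:, None] + areas[None, :]
    w = fibers / denom
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, "structural")


def read_cohort_manifest(path: str | Path) -> list[SubjectRecord]:
    """Read a TSV/CSV manifest with columns subject_id, group, sc_path, fc_path.

    Paths are resolved relative to the manifest's directory. Duplicate subject
    IDs and dangling paths are errors.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_delimiter(path))
    required = {"subject_id", "group", "sc_path", "fc_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    ids = table["subject_id"].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"duplicate subject ids: {ids[ids.duplicated()].tolist()}")
    records = []
    base = path.parent
    for _, row in table.iterrows():
        sc = base / str(row["sc_path"])
        fc = base / str(row["fc_path"])
        for p in (sc, fc):
            if not p.exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
        records.append(SubjectRecord(str(row["subject_id"]), str(row["group"]), sc, fc))
    return records
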
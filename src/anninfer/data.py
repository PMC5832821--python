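"""Expression matrices, phenotype labels, and their plain-text formats.

The universal input of the pipeline is a probes x samples matrix of
continuous log-intensity values (microarray orientation: one row per probe,
one column per sample), stored on disk as a tab-separated table whose first
column holds probe identifiers and whose header row holds sample
identifiers.  The binary driver phenotype is either supplied as a
two-column TSV (sample_id, class) or derived from a designated driver probe
by a median split.

All writers prepend ``#``-prefixed provenance comment lines (package
version, seed, optional config hash); all readers skip them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import __version__

__all__ = [
    "ExpressionMatrix",
    "PhenotypeLabels",
    "MinMaxParams",
    "DataError",
    "ParseError",
    "ValidationError",
    "DegeneratePhenotypeError",
    "ScalingError",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_labels",
    "write_labels",
    "derive_labels",
    "minmax_scale",
    "inverse_minmax",
]


class DataError(ValueError):
    """Base class for data-layer failures."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line or cell."""


class ValidationError(DataError):
    """Parsed content violates an invariant (duplicates, shape mismatch, ...)."""


class DegeneratePhenotypeError(DataError):
    """A dichotomization left one phenotype class empty."""


class ScalingError(DataError):
    """A probe row cannot be min-max scaled (constant values)."""


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of continuous expression intensities.

    Parameters
    ----------
    probe_ids : list of str
        Unique row identifiers (microarray probes or gene symbols).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_probes, n_samples)
        Finite log-intensity values.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at probe {self.probe_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, probe_id: str) -> np.ndarray:
        """Return the expression vector of one probe across samples."""
        try:
            idx = self.probe_ids.index(probe_id)
        except ValueError:
            raise KeyError(f"probe {probe_id!r} not in matrix") from None
        return self.values[idx]

    def subset(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given probes, in the given order."""
        index = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probe_ids if p not in index]
        if missing:
            raise KeyError(f"probes not in matrix: {missing}")
        rows = [index[p] for p in probe_ids]
        return ExpressionMatrix(list(probe_ids), list(self.sample_ids), self.values[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(map(str, frame.index)), list(map(str, frame.columns)),
                   frame.to_numpy(dtype=float))


@dataclass
class PhenotypeLabels:
    """Binary driver phenotype per sample (0 = low, 1 = high)."""

    sample_ids: list[str]
    classes: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.classes = np.asarray(self.classes, dtype=int)
        if self.classes.shape != (len(self.sample_ids),):
            raise ValidationError("classes must align 1:1 with sample_ids")
        _check_unique(self.sample_ids, "sample")
        uniq = set(self.classes.tolist())
        if not uniq <= {0, 1}:
            raise ValidationError(f"classes must be 0/1, got {sorted(uniq)}")
        if uniq != {0, 1}:
            raise DegeneratePhenotypeError(
                "both phenotype classes must be present (training requires two classes)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Return the class vector reordered to the given sample order."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ValidationError(f"samples without labels: {missing}")
        if len(sample_ids) != len(self.sample_ids):
            raise ValidationError("label and matrix sample sets differ in size")
        return self.classes[[pos[s] for s in sample_ids]]


def _provenance_header(seed: int | None = None, extra: str | None = None) -> str:
    parts = [f"# anninfer v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if extra:
        parts.append(extra)
    return " ".join(parts) + "\n"


def _scan_rectangular(path: Path) -> None:
    """Pre-scan a TSV for ragged data rows, reporting 1-based line numbers."""
    width = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            n = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = n
            elif n != width:
                raise ParseError(
                    f"{path}: ragged row at line {lineno} "
                    f"({n} fields, expected {width})"
                )


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a probes x samples expression TSV.

    The first header cell is arbitrary; remaining header cells are sample
    IDs.  Each data row is a probe ID followed by tab-separated decimal
    numbers.  Comment lines starting with ``#`` are skipped.

    Raises
    ------
    ParseError
        Ragged rows (named by line number) or non-numeric cells (named by
        probe and sample).
    ValidationError
        Duplicate probe or sample IDs, or non-finite values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _scan_rectangular(path)
    # check the raw header ourselves: pandas silently renames duplicate columns
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            _check_unique(line.rstrip("\n").split("\t")[1:], "sample")
            break
    try:
        numeric = pd.read_csv(path, sep="\t", comment="#", header=0,
                              index_col=0, float_precision="round_trip",
                              na_filter=False)
        _check_unique(list(numeric.index), "probe")
        if all(np.issubdtype(dt, np.number) for dt in numeric.dtypes):
            return ExpressionMatrix.from_frame(numeric.astype(float))
    except (ValueError, TypeError):
        pass
    # slow path: locate the offending cell for the error message
    df = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0,
                     dtype=str, na_filter=False)
    _check_unique(list(df.index), "probe")
    for col in df.columns:
        for probe, cell in df[col].items():
            try:
                float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at probe {probe!r}, "
                    f"sample {col!r}: {cell!r}") from None
    raise ParseError(f"{path}: could not parse numeric matrix")


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path,
                            seed: int | None = None,
                            provenance: str | None = None) -> Path:
    """Write an expression TSV with a provenance comment header.

    Values are written with Python's shortest round-tripping float
    representation, so a write/read cycle is exact.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed, provenance))
        fh.write("probe_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_labels(path: str | Path) -> PhenotypeLabels:
    """Read a labels TSV with columns sample_id, class."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", header=0, dtype=str)
    if list(df.columns[:2]) != ["sample_id", "class"]:
        raise ParseError(f"{path}: expected header 'sample_id\\tclass'")
    classes = pd.to_numeric(df["class"], errors="coerce")
    if classes.isna().any():
        row = df.loc[classes.isna(), "sample_id"].iloc[0]
        raise ParseError(f"{path}: non-numeric class for sample {row!r}")
    return PhenotypeLabels(df["sample_id"].tolist(), classes.to_numpy(dtype=int))


def write_labels(labels: PhenotypeLabels, path: str | Path,
                 seed: int | None = None, provenance: str | None = None) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance_header(seed, provenance))
        fh.write("sample_id\tclass\n")
        for sid, c in zip(labels.sample_ids, labels.classes):
            fh.write(f"{sid}\t{c}\n")
    return path


def derive_labels(matrix: ExpressionMatrix, driver_probe: str,
                  threshold_rule: str = "median") -> PhenotypeLabels:
    """Dichotomize samples on a driver probe's expression.

    A sample is classed 1 ("high") iff its driver-probe value strictly
    exceeds the median of that probe across samples, else 0 ("low").  The
    median split is the only supported rule: on continuous data it
    guarantees both classes are populated.

    Raises
    ------
    KeyError
        Driver probe absent from the matrix.
    DegeneratePhenotypeError
        The split leaves one class empty (e.g. all driver values identical).
    """
    if threshold_rule != "median":
        raise ValueError(f"unsupported threshold rule {threshold_rule!r}")
    driver = matrix.row(driver_probe)
    median = float(np.median(driver))
    classes = (driver > median).astype(int)
    if classes.min() == classes.max():
        raise DegeneratePhenotypeError(
            f"median split on probe {driver_probe!r} leaves one class empty"
        )
    return PhenotypeLabels(list(matrix.sample_ids), classes)


class MinMaxParams(NamedTuple):
    """Per-probe affine parameters of a min-max transform."""

    mins: np.ndarray
    ranges: np.ndarray


def minmax_scale(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, MinMaxParams]:
    """Linearly map every probe row onto [0, 1].

    Required before any probe is used as a sigmoidal network target, since
    the output unit is bounded in (0, 1).  Returns the scaled matrix and
    the per-row (min, range) parameters so the transform is invertible.

    Raises
    ------
    ScalingError
        If a probe row is constant (max == min), naming the probe.
    """
    mins = matrix.values.min(axis=1)
    maxs = matrix.values.max(axis=1)
    ranges = maxs - mins
    flat = np.nonzero(ranges == 0)[0]
    if flat.size:
        raise ScalingError(f"constant probe row cannot be scaled: "
                           f"{matrix.probe_ids[flat[0]]!r}")
    scaled = (matrix.values - mins[:, None]) / ranges[:, None]
    out = ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids), scaled)
    return out, MinMaxParams(mins=mins, ranges=ranges)


def inverse_minmax(matrix: ExpressionMatrix, params: MinMaxParams) -> ExpressionMatrix:
    """Undo :func:`minmax_scale`."""
    values = matrix.values * params.ranges[:, None] + params.mins[:, None]
    return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids), values)
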
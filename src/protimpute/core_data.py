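"""Core matrix containers and delimited-text I/O.

The internal orientation is always samples x proteins (rows are samples).
Missing entries are carried as NaN in the value grid together with an
explicit boolean mask; the two are kept consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "IntensityMatrix",
    "LogMatrix",
    "ExternalScores",
    "GroundTruth",
    "ImputationResult",
    "MatrixParseError",
    "MatrixValidationError",
    "read_matrix",
    "write_matrix",
    "read_scores",
]

DEFAULT_NA_TOKENS = frozenset({"NA", "NaN", ""})


class MatrixParseError(ValueError):
    """A cell could not be parsed as a number or NA token."""


class MatrixValidationError(ValueError):
    """The parsed table violates a structural invariant."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(x) for x in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise MatrixValidationError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class AbundanceMatrix:
    """Samples x proteins grid with an explicit missing mask.

    ``values`` holds NaN wherever ``missing`` is True; observed entries are
    finite. Subclasses fix the measurement space.
    """

    values: np.ndarray
    sample_ids: list[str]
    protein_ids: list[str]
    space_tag: str = field(default="intensity")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixValidationError("values must be a 2-D grid")
        m, n = self.values.shape
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.protein_ids = _check_ids(self.protein_ids, "protein")
        if len(self.sample_ids) != m or len(self.protein_ids) != n:
            raise MatrixValidationError(
                f"id lengths ({len(self.sample_ids)}, {len(self.protein_ids)}) "
                f"do not match grid shape {self.values.shape}"
            )
        self._validate_values()

    def _validate_values(self) -> None:
        obs = self.values[~np.isnan(self.values)]
        if np.any(~np.isfinite(obs)):
            raise MatrixValidationError("observed values must be finite")

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the entry is missing."""
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_proteins(self) -> int:
        return self.values.shape[1]

    @property
    def missing_rate(self) -> float:
        return float(np.mean(self.missing))

    def protein_missing_rates(self) -> np.ndarray:
        return np.mean(self.missing, axis=0)

    def copy(self) -> "AbundanceMatrix":
        return replace(
            self,
            values=self.values.copy(),
            sample_ids=list(self.sample_ids),
            protein_ids=list(self.protein_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.protein_ids
        )


@dataclass
class IntensityMatrix(AbundanceMatrix):
    """Abundances in original (pre-log) intensity units; observed entries > 0."""

    space_tag: str = field(default="intensity")

    def _validate_values(self) -> None:
        super()._validate_values()
        obs = self.values[~np.isnan(self.values)]
        if obs.size and np.any(obs <= 0):
            bad = float(obs[obs <= 0][0])
            raise MatrixValidationError(
                f"intensity values must be strictly positive, found {bad}"
            )


@dataclass
class LogMatrix(AbundanceMatrix):
    """log2-transformed abundances; observed entries may be any real."""

    space_tag: str = field(default="log2")


@dataclass
class ExternalScores:
    """Complete per-sample covariate table (e.g. pathology grades)."""

    P: np.ndarray
    sample_ids: list[str]
    score_ids: list[str]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[1] < 1:
            raise MatrixValidationError("scores need at least one column")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if len(self.sample_ids) != self.P.shape[0]:
            raise MatrixValidationError("score rows do not match sample ids")
        if np.any(~np.isfinite(self.P)):
            raise MatrixValidationError("scores must be complete")

    def aligned_to(self, matrix: AbundanceMatrix) -> "ExternalScores":
        """Reorder rows to the matrix's sample order; error on mismatch."""
        if set(self.sample_ids) != set(matrix.sample_ids):
            raise MatrixValidationError(
                "score sample ids do not match target matrix"
            )
        order = [self.sample_ids.index(s) for s in matrix.sample_ids]
        return ExternalScores(
            self.P[order], list(matrix.sample_ids), list(self.score_ids)
        )


@dataclass
class GroundTruth:
    """Evaluation index set Omega with the true values held out there."""

    omega: list[tuple[int, int]]
    true_values: np.ndarray
    space_tag: str = "intensity"

    def __post_init__(self) -> None:
        self.true_values = np.asarray(self.true_values, dtype=float)
        if len(self.omega) != len(self.true_values):
            raise MatrixValidationError("omega and true_values misaligned")
        if len(self.omega) == 0:
            raise MatrixValidationError("empty evaluation set")
        if len(set(self.omega)) != len(self.omega):
            raise MatrixValidationError("omega entries must be unique")

    def __len__(self) -> int:
        return len(self.omega)

    def rows(self) -> np.ndarray:
        return np.array([i for i, _ in self.omega], dtype=int)

    def cols(self) -> np.ndarray:
        return np.array([j for _, j in self.omega], dtype=int)

    def restrict_to_proteins(self, keep: Iterable[int]) -> "GroundTruth":
        """Subset Omega to the given protein (column) indices, renumbering
        columns to the post-filter order."""
        keep = list(keep)
        remap = {old: new for new, old in enumerate(keep)}
        pairs, vals = [], []
        for (i, j), v in zip(self.omega, self.true_values):
            if j in remap:
                pairs.append((i, remap[j]))
                vals.append(v)
        return GroundTruth(pairs, np.array(vals), self.space_tag)

    def to_frame(self, matrix: AbundanceMatrix) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [matrix.sample_ids[i] for i, _ in self.omega],
                "protein_id": [matrix.protein_ids[j] for _, j in self.omega],
                "true_value": self.true_values,
                "space_tag": self.space_tag,
            }
        )


@dataclass
class ImputationResult:
    """A completed grid; observed entries are identical to the input."""

    completed: np.ndarray
    method_name: str
    params: dict
    filled: np.ndarray  # boolean mask of the entries that were imputed
    space_tag: str = "log2"

    def __post_init__(self) -> None:
        self.completed = np.asarray(self.completed, dtype=float)
        self.filled = np.asarray(self.filled, dtype=bool)
        if self.completed.shape != self.filled.shape:
            raise MatrixValidationError("completed/filled shape mismatch")
        if np.any(np.isnan(self.completed)):
            raise MatrixValidationError("completed grid contains NaN")

    def at_omega(self, truth: GroundTruth) -> np.ndarray:
        return self.completed[truth.rows(), truth.cols()]


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parse_table(
    path: str | Path, na_tokens: Iterable[str], delimiter: str | None
) -> pd.DataFrame:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise MatrixValidationError(f"{path}: duplicate column ids in header")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    tokens = set(na_tokens)
    grid = np.empty(df.shape, dtype=float)
    for jj, col in enumerate(df.columns):
        for ii, raw in enumerate(df[col].to_numpy()):
            cell = raw.strip()
            if cell in tokens:
                grid[ii, jj] = np.nan
                continue
            try:
                grid[ii, jj] = float(cell)
            except ValueError:
                raise MatrixParseError(
                    f"{path}: cell ({df.index[ii]!r}, {col!r}) is not numeric "
                    f"or an NA token: {raw!r}"
                ) from None
    out = pd.DataFrame(grid, index=df.index.astype(str), columns=df.columns.astype(str))
    return out


def read_matrix(
    path: str | Path,
    orientation: str = "samples_by_proteins",
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
    delimiter: str | None = None,
    space_tag: str = "intensity",
) -> AbundanceMatrix:
    """Read a delimited abundance table into the internal orientation.

    Parameters
    ----------
    orientation
        Layout of the *file*: ``samples_by_proteins`` (rows are samples) or
        ``proteins_by_samples`` (rows are proteins; transposed on read).
    na_tokens
        Cell strings treated as missing, in addition to empty cells.
    space_tag
        ``intensity`` (validated strictly positive) or ``log2``.
    """
    if orientation not in {"samples_by_proteins", "proteins_by_samples"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _parse_table(path, na_tokens, delimiter)
    if orientation == "proteins_by_samples":
        df = df.T
    cls = IntensityMatrix if space_tag == "intensity" else LogMatrix
    return cls(
        df.to_numpy(),
        sample_ids=list(df.index),
        protein_ids=list(df.columns),
    )


def write_matrix(
    matrix: AbundanceMatrix,
    path: str | Path,
    orientation: str = "samples_by_proteins",
    na_token: str = "NA",
    delimiter: str | None = None,
) -> None:
    """Write a matrix; values are printed with 17 significant digits so a
    read/write round trip is bit-exact."""
    path = Path(path)
    df = matrix.to_frame()
    if orientation == "proteins_by_samples":
        df = df.T
    elif orientation != "samples_by_proteins":
        raise ValueError(f"unknown orientation {orientation!r}")
    sep = _delimiter_for(path, delimiter)
    try:
        df.to_csv(path, sep=sep, na_rep=na_token, float_format="%.17g")
    except OSError as exc:
        raise OSError(f"cannot write matrix to {path}: {exc}") from exc


def read_scores(
    path: str | Path,
    na_tokens: Iterable[str] = DEFAULT_NA_TOKENS,
    delimiter: str | None = None,
) -> ExternalScores:
    """Read a complete per-sample score table (rows = samples)."""
    df = _parse_table(path, na_tokens, delimiter)
    if df.isna().to_numpy().any():
        raise MatrixValidationError(f"{path}: scores must be complete (NA found)")
    return ExternalScores(
        df.to_numpy(), sample_ids=list(df.index), score_ids=list(df.columns)
    )
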
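"""Protein filtering, log transformation, and invertible scalings.

Two scalings are provided: protein-wise standardization (observed mean 0,
population sd 1 per protein) and sample-wise median centering. Both return
parameters sufficient to undo them exactly, so imputation can run in a
method-appropriate space and results can be mapped back before evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import AbundanceMatrix, IntensityMatrix, LogMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScalingParams",
    "FilterReport",
    "filter_by_missing_rate",
    "log2_transform",
    "inverse_log2",
    "standardize_proteins",
    "destandardize_proteins",
    "normalize_samples",
    "denormalize_samples",
]


@dataclass
class ScalingParams:
    """Location/scale vectors for one scaling mode.

    mode ``protein_standardize``: per-protein mean and population sd.
    mode ``sample_normalize``: per-sample median (scale is all ones).
    """

    mode: str
    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scale entries must be strictly positive")


@dataclass
class FilterReport:
    kept_indices: list[int]
    removed_protein_ids: list[str]


def filter_by_missing_rate(
    matrix: AbundanceMatrix, max_rate: float = 0.8
) -> tuple[AbundanceMatrix, FilterReport]:
    """Drop proteins whose missing fraction strictly exceeds ``max_rate``.

    A protein missing exactly ``max_rate`` of its samples is retained.
    """
    rates = matrix.protein_missing_rates()
    keep = np.where(rates <= max_rate)[0]
    if keep.size == 0:
        raise ValueError("no proteins survive filter")
    removed = [matrix.protein_ids[j] for j in range(matrix.n_proteins) if rates[j] > max_rate]
    if removed:
        logger.info("filtered %d proteins with missing rate > %.2f", len(removed), max_rate)
    out = type(matrix)(
        matrix.values[:, keep],
        sample_ids=list(matrix.sample_ids),
        protein_ids=[matrix.protein_ids[j] for j in keep],
    )
    return out, FilterReport(list(map(int, keep)), removed)


def log2_transform(matrix: IntensityMatrix) -> LogMatrix:
    """log2 of every observed entry; the missing mask is untouched."""
    obs = matrix.values[~matrix.missing]
    if obs.size and np.any(obs <= 0):
        raise ValueError("nonpositive observed value: clean or mark missing first")
    return LogMatrix(
        np.log2(matrix.values),
        sample_ids=list(matrix.sample_ids),
        protein_ids=list(matrix.protein_ids),
    )


def inverse_log2(matrix: LogMatrix) -> IntensityMatrix:
    """Entrywise 2**value, back to the original intensity space."""
    return IntensityMatrix(
        np.exp2(matrix.values),
        sample_ids=list(matrix.sample_ids),
        protein_ids=list(matrix.protein_ids),
    )


def standardize_proteins(matrix: LogMatrix) -> tuple[LogMatrix, ScalingParams]:
    """Per protein: observed mean 0, observed population sd 1.

    Proteins with zero observed variance keep scale 1 (centering only),
    with a logged warning.
    """
    vals = matrix.values
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0)  # population sd over observed entries
    degenerate = sd == 0
    if np.any(degenerate):
        logger.warning(
            "%d proteins have zero observed variance; scale clamped to 1",
            int(degenerate.sum()),
        )
        sd = np.where(degenerate, 1.0, sd)
    out = LogMatrix(
        (vals - mean) / sd,
        sample_ids=list(matrix.sample_ids),
        protein_ids=list(matrix.protein_ids),
    )
    return out, ScalingParams("protein_standardize", mean, sd)


def destandardize_proteins(values: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Invert ``standardize_proteins`` on a value grid (works on completed
    grids as well as masked ones)."""
    if params.mode != "protein_standardize":
        raise ValueError(f"wrong params mode {params.mode!r}")
    return values * params.scale + params.location


def normalize_samples(matrix: LogMatrix) -> tuple[LogMatrix, ScalingParams]:
    """Per sample: subtract the median of the observed entries."""
    med = np.nanmedian(matrix.values, axis=1)
    out = LogMatrix(
        matrix.values - med[:, None],
        sample_ids=list(matrix.sample_ids),
        protein_ids=list(matrix.protein_ids),
    )
    return out, ScalingParams("sample_normalize", med, np.ones_like(med))


def denormalize_samples(values: np.ndarray, params: ScalingParams) -> np.ndarray:
    if params.mode != "sample_normalize":
        raise ValueError(f"wrong params mode {params.mode!r}")
    return values + params.location[:, None]
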
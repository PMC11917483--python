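"""Adaptive-index and genomic-offset projection onto environmental grids.

The adaptively enriched RDA refits the discovery model on the outlier loci
only; its predictor scores a_i on each retained axis combine with the
standardized pixel value b_i of each variable to give the per-pixel
adaptive index AI_axis = sum_i a_i b_i. The genomic offset between current
and future climates is the Euclidean distance between the two AI vectors
across retained axes — a proxy for local maladaptation risk, not a direct
fitness measure.

Grids must be standardized with the *training-site* reference (current
climate) for both current and future scenarios, so offsets reflect climate
change rather than re-standardization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rda import RDAModel, fit_rda

__all__ = [
    "AdaptiveIndexMap",
    "OffsetMap",
    "enriched_rda",
    "adaptive_index",
    "genomic_offset",
    "ensemble_mean",
]


@dataclass
class AdaptiveIndexMap:
    """Per-pixel adaptive index for each retained constrained axis."""

    pixels: pd.DataFrame  # row, col, lat, lon
    values: np.ndarray  # (n_pixels, n_axes)
    axes: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.pixels), len(self.axes)):
            raise ValueError("values shape must be (n_pixels, n_axes)")


@dataclass
class OffsetMap:
    """Per-pixel nonnegative genomic offset under a future scenario."""

    pixels: pd.DataFrame
    offset: np.ndarray
    scenario: str = ""

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float)
        if (self.offset < 0).any():
            raise ValueError("offset must be nonnegative")


def enriched_rda(
    Y: np.ndarray,
    outlier_loci: np.ndarray,
    X: np.ndarray,
    predictor_names: list[str] | None = None,
) -> RDAModel:
    """Refit the RDA on the outlier (candidate adaptive) loci only."""
    outlier_loci = np.unique(np.asarray(outlier_loci, dtype=int))
    if outlier_loci.size < 2:
        raise ValueError("enriched RDA needs >= 2 outlier loci")
    return fit_rda(
        np.asarray(Y, dtype=float)[:, outlier_loci], X, predictor_names=predictor_names
    )


def adaptive_index(
    model: RDAModel,
    grid: pd.DataFrame,
    axes: list[int] | None = None,
) -> AdaptiveIndexMap:
    """AI_axis(pixel) = sum_i a_i(axis) * b_i(pixel).

    ``grid`` must carry one column per model predictor, already
    standardized with the training-site reference; a_i are the model's
    predictor biplot scores on the retained axes.
    """
    axes = axes or [1, 2]
    missing = [v for v in model.predictor_names if v not in grid.columns]
    if missing:
        raise ValueError(f"grid lacks model variable(s): {', '.join(missing)}")
    if max(axes) > model.biplot_scores.shape[1]:
        raise ValueError("requested axis beyond the model's constrained axes")
    B = grid[model.predictor_names].to_numpy(dtype=float)
    A = model.biplot_scores[:, [ax - 1 for ax in axes]]
    meta_cols = [c for c in ("row", "col", "lat", "lon") if c in grid.columns]
    return AdaptiveIndexMap(
        pixels=grid[meta_cols].reset_index(drop=True), values=B @ A, axes=list(axes)
    )


def genomic_offset(
    current: AdaptiveIndexMap,
    future: AdaptiveIndexMap,
    scenario: str = "",
    eigenvalue_weights: np.ndarray | None = None,
) -> OffsetMap:
    """Euclidean distance between current and future adaptive indices.

    Optional per-axis eigenvalue weights rescale the axis contributions.
    """
    if current.axes != future.axes or len(current.pixels) != len(future.pixels):
        raise ValueError("current/future maps have mismatched geometry or axes")
    if not current.pixels.reset_index(drop=True).equals(
        future.pixels.reset_index(drop=True)
    ):
        raise ValueError("pixel geometry differs between current and future maps")
    diff = future.values - current.values
    if eigenvalue_weights is not None:
        w = np.asarray(eigenvalue_weights, dtype=float)
        if w.shape != (diff.shape[1],):
            raise ValueError("one weight per retained axis required")
        diff = diff * np.sqrt(w / w.sum())
    return OffsetMap(
        pixels=current.pixels.copy(),
        offset=np.sqrt((diff**2).sum(axis=1)),
        scenario=scenario,
    )


def ensemble_mean(grids: list[pd.DataFrame]) -> pd.DataFrame:
    """Per-pixel, per-variable arithmetic mean of same-geometry grids
    (e.g. a multi-model climate ensemble)."""
    if not grids:
        raise ValueError("need >= 1 grid")
    base = grids[0]
    meta = [c for c in ("row", "col", "lat", "lon") if c in base.columns]
    variables = [c for c in base.columns if c not in meta]
    for g in grids[1:]:
        if list(g.columns) != list(base.columns) or len(g) != len(base):
            raise ValueError("grids differ in variables or pixel count")
        if not g[meta].reset_index(drop=True).equals(base[meta].reset_index(drop=True)):
            raise ValueError("grids differ in pixel geometry")
    out = base.copy().reset_index(drop=True)
    out[variables] = np.mean(
        [g[variables].to_numpy(dtype=float) for g in grids], axis=0
    )
    return out
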
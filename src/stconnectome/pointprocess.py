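"""Point-process extraction: reduce regional time series to binary activations.

Each region's series is z-scored against its own mean and standard deviation
across frames, and a cell (region, frame) is marked active when the z value
reaches the threshold (default 2 SD, the convention of the spatiotemporal
connectome literature).  Only positive deflections count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._core import DimensionError, ValidationError


@dataclass(frozen=True)
class ActivationRaster:
    """Binary N x T activity matrix plus the threshold that produced it."""

    active: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        a = np.asarray(self.active)
        if a.ndim != 2:
            raise DimensionError("raster must be 2-D (regions x frames)")
        vals = np.unique(a)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError("raster entries must be 0/1")
        object.__setattr__(self, "active", a.astype(bool))

    @property
    def n_regions(self) -> int:
        return int(self.active.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.active.shape[1])


def zscore_threshold(
    values: np.ndarray,
    threshold: float = 2.0,
    ddof: int = 1,
) -> ActivationRaster:
    """Binarize a regional time-series matrix by per-region z-scoring.

    Parameters
    ----------
    values
        N x T real matrix (regions by frames).  Must be finite, T >= 2.
    threshold
        Activation cutoff in SD units; a cell is active iff z >= threshold
        (inclusive).  Default 2.0.
    ddof
        Delta degrees of freedom for the SD estimate; 1 (sample SD) by
        default, 0 for the population estimator.

    Returns
    -------
    ActivationRaster
        Same shape as the input.  Regions with zero variance across frames
        are everywhere inactive.  The input is not modified.
    """
    ts = np.asarray(values, dtype=float)
    if ts.ndim != 2:
        raise DimensionError("time series must be 2-D (regions x frames)")
    if ts.shape[1] < 2:
        raise DimensionError("need at least 2 frames to z-score")
    if not np.all(np.isfinite(ts)):
        raise ValidationError("time series contains non-finite values")

    mean = ts.mean(axis=1, keepdims=True)
    sd = ts.std(axis=1, ddof=ddof, keepdims=True)
    nonconstant = sd[:, 0] > 0
    z = np.zeros_like(ts)
    np.divide(ts - mean, sd, out=z, where=sd > 0)
    active = (z >= threshold) & nonconstant[:, None]
    return ActivationRaster(active=active, threshold_used=float(threshold))
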
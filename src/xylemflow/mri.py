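"""Contrast-enhanced MRI time-series to normalized flow-signal matrix.

A stem is scanned as ``n_slices`` axial slices at regular intervals
(default every 23 min over 7 h, i.e. 19 timepoints).  On every image,
regions for the stem, a water-reference test tube and air are segmented;
their mean intensities enter the flow-signal normalization

    F[i, t] = (stem_mean[i, t] - stem_mean[i, 0]) / air_mean[i, t],

so each slice's trace is baseline-subtracted at the first timepoint and
scaled by the concurrent air (noise-floor) level.  Slices whose trace
grows over time accumulate contrast agent (nodal plexuses, where the
gadolinium chelate is filtered out of the transpiration stream);
time-flat slices are internodes whose open vessels let it pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SliceSeries",
    "FlowSignalMatrix",
    "region_means",
    "normalize_flow_signal",
    "classify_slices",
    "suggest_slope_threshold",
    "spacetime_map",
]

REGION_NAMES = ("stem", "water", "air")


@dataclass(frozen=True)
class SliceSeries:
    """Intensity array (slice, time, y, x) with fixed per-slice masks."""

    data: np.ndarray               # (n_slices, n_times, H, W)
    masks: dict                    # region name -> bool (n_slices, H, W)
    slice_spacing_mm: float = 1.0
    time_step_min: float = 23.0

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D (slice, time, y, x), got {self.data.shape}")
        n, _, H, W = self.data.shape
        for name in ("stem", "air"):
            if name not in self.masks:
                raise ValueError(f"missing required mask {name!r}")
        taken = np.zeros((n, H, W), bool)
        for name, m in self.masks.items():
            if m.shape != (n, H, W):
                raise ValueError(f"mask {name!r} shape {m.shape} != {(n, H, W)}")
            if (taken & m).any():
                raise ValueError(f"mask {name!r} overlaps another region")
            taken |= m
            if name in ("stem", "air") and not m.reshape(n, -1).any(axis=1).all():
                raise ValueError(f"mask {name!r} empty on some slice")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def n_times(self) -> int:
        return self.data.shape[1]

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_times) * self.time_step_min

    @property
    def positions_mm(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.slice_spacing_mm


@dataclass(frozen=True)
class FlowSignalMatrix:
    """Normalized flow signal F[i, t]; F[:, 0] is identically zero."""

    F: np.ndarray                   # (n_slices, n_times)
    positions_mm: np.ndarray        # (n_slices,)
    times_min: np.ndarray           # (n_times,)
    flagged: np.ndarray = None      # slices with a non-positive air mean

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.F,
            index=pd.Index(self.positions_mm, name="position_mm"),
            columns=pd.Index(self.times_min, name="time_min"),
        )
        return df


def region_means(series: SliceSeries) -> dict:
    """Mean pixel intensity per region, slice and timepoint.

    Returns ``{region: array (n_slices, n_times)}``.  Masks are fixed per
    slice (shared across timepoints).  Raises on an empty mask.
    """
    out = {}
    for name, mask in series.masks.items():
        counts = mask.reshape(series.n_slices, -1).sum(axis=1)
        if (counts == 0).any():
            raise ValueError(f"mask {name!r} empty on slice(s) "
                             f"{np.where(counts == 0)[0].tolist()}")
        flat = series.data.reshape(series.n_slices, series.n_times, -1)
        sums = np.einsum("itp,ip->it", flat, mask.reshape(series.n_slices, -1) * 1.0)
        out[name] = sums / counts[:, None]
    return out


def normalize_flow_signal(
    stem_mean: np.ndarray,
    air_mean: np.ndarray,
    positions_mm: np.ndarray | None = None,
    times_min: np.ndarray | None = None,
) -> FlowSignalMatrix:
    """Baseline-subtracted, air-normalized flow signal.

    ``F[i, t] = (stem[i, t] - stem[i, 0]) / air[i, t]`` for every slice
    at every timepoint; the baseline is the first timepoint, so the t=0
    column is exactly zero.  Slices where the air mean is not strictly
    positive at some timepoint are flagged and their F set to NaN there.
    """
    stem = np.asarray(stem_mean, float)
    air = np.asarray(air_mean, float)
    if stem.shape != air.shape or stem.ndim != 2:
        raise ValueError("stem and air means must be matching 2-D (slice, time)")
    bad = air <= 0
    with np.errstate(all="ignore"):
        F = (stem - stem[:, :1]) / air
    F[bad] = np.nan
    F[:, 0] = np.where(bad[:, 0], np.nan, 0.0)
    n_i, n_t = stem.shape
    if positions_mm is None:
        positions_mm = np.arange(n_i, dtype=float)
    if times_min is None:
        times_min = np.arange(n_t, dtype=float)
    return FlowSignalMatrix(F=F, positions_mm=np.asarray(positions_mm, float),
                            times_min=np.asarray(times_min, float),
                            flagged=bad.any(axis=1))


def _slopes(matrix: FlowSignalMatrix) -> np.ndarray:
    """Least-squares slope of each slice's trace vs time (per minute)."""
    t = matrix.times_min
    F = matrix.F
    tc = t - t.mean()
    denom = (tc**2).sum()
    return np.nansum(F * tc[None, :], axis=1) / denom


def suggest_slope_threshold(matrix: FlowSignalMatrix) -> float:
    """Data-driven slope threshold for phantom studies.

    Half the median of the strictly positive per-slice slopes — adequate
    when accumulating and flat slices are well separated, as in the
    phantom; real data need an explicitly chosen threshold.
    """
    s = _slopes(matrix)
    pos = s[s > 0]
    if pos.size == 0:
        return np.inf
    return 0.5 * float(np.median(pos))


def classify_slices(
    matrix: FlowSignalMatrix, slope_threshold: float
) -> pd.DataFrame:
    """Label each slice node (accumulating) or internode (flat).

    Fits a least-squares line to each slice's F trace over time; slices
    with slope above ``slope_threshold`` (1/min) are nodes.  Requires at
    least 3 timepoints.
    """
    if matrix.F.shape[1] < 3:
        raise ValueError("need at least 3 timepoints to estimate slopes")
    s = _slopes(matrix)
    return pd.DataFrame(
        {
            "slice": np.arange(matrix.F.shape[0]) + 1,
            "position_mm": matrix.positions_mm,
            "slope_per_min": s,
            "label": np.where(s > slope_threshold, "node", "internode"),
        }
    )


def spacetime_map(matrix: FlowSignalMatrix, csv_path=None, png_path=None):
    """Space-time rendering of the flow-signal matrix.

    Returns the matrix as a DataFrame (slice position in mm x time in
    min) and optionally writes it as CSV and as a PNG heat map with
    axial position on the vertical axis and scan time on the horizontal.
    """
    df = matrix.to_frame()
    if csv_path is not None:
        df.to_csv(csv_path)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        t, p = matrix.times_min, matrix.positions_mm
        im = ax.pcolormesh(t, p, matrix.F, shading="nearest", cmap="magma")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("slice position (mm)")
        fig.colorbar(im, ax=ax, label="normalized flow signal")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return df
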
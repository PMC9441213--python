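"""Speckle-motion tracking by sub-image cross-correlation.

Digital image correlation in the style used for specklegram sensors: each
frame is divided into a grid of sub-images; every sub-image of frame *t*
is compared against a shifted search window in the partner frame, and the
location and height of the correlation peak give the local displacement
(in whole camera pixels) and a similarity score.  The grid-averaged
per-step displacements and peak heights form the time series that the
lock-in and classification stages consume.

Two correlation variants are exposed:

* :func:`cross_correlate` — the raw product-sum form
  R(dx, dy) = (1/NM) sum_ij A(i, j) A'(i+dy, j+dx), kept for fidelity and
  as the oracle-checked primitive;
* :func:`normalized_cross_correlate` — zero-mean, unit-variance (Pearson)
  correlation over the overlapping region, bounded in [-1, 1] and
  invariant to affine intensity changes.  Peak tracking uses this variant
  because the raw form is biased toward bright regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .exceptions import DegenerateDataError, ValidationError
from .synthetic_data import SpeckleRecording

__all__ = [
    "SubImageGrid",
    "CorrelationMap",
    "DisplacementTrace",
    "cross_correlate",
    "normalized_cross_correlate",
    "find_peak",
    "track_sequence",
    "write_trace_csv",
    "read_trace_csv",
]


@dataclass(frozen=True)
class SubImageGrid:
    """Sub-image tiling and shift-search geometry.

    ``stride`` spaces sub-image origins; ``search_radius`` is the maximum
    |dx| and |dy| swept.  Sub-image plus search window must fit inside the
    frame for full-overlap tracking.
    """

    subimage_rows: int = 32
    subimage_cols: int = 32
    stride: int = 32
    search_radius: int = 8

    def __post_init__(self) -> None:
        if self.subimage_rows < 2 or self.subimage_cols < 2:
            raise ValidationError("sub-image must be at least 2x2")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.search_radius < 1:
            raise ValidationError("search_radius must be >= 1")

    def cell_origins(self, frame_shape: tuple[int, int]) -> list[tuple[int, int]]:
        """Top-left corners of all cells whose search window fits the frame."""
        rows, cols = frame_shape
        r = self.search_radius
        row_stops = rows - r - self.subimage_rows + 1
        col_stops = cols - r - self.subimage_cols + 1
        origins = [(i, j)
                   for i in range(r, row_stops, self.stride)
                   for j in range(r, col_stops, self.stride)]
        if not origins:
            raise ValidationError(
                f"no {self.subimage_rows}x{self.subimage_cols} sub-image with "
                f"search radius {r} fits a {rows}x{cols} frame")
        return origins


@dataclass(frozen=True)
class CorrelationMap:
    """Correlation values over the swept shift window.

    ``values[dy + r, dx + r]`` holds R(dx, dy) for dx, dy in [-r, r] with
    dx along columns (x) and dy along rows (y).
    """

    values: np.ndarray
    search_radius: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        side = 2 * self.search_radius + 1
        if v.shape != (side, side):
            raise ValidationError(
                f"values must be {side}x{side} for search_radius "
                f"{self.search_radius}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("correlation map contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass
class DisplacementTrace:
    """Per-step displacement and correlation-peak-height series.

    ``mode`` is ``"adjacent"`` (frame t vs t+1; series length T-1) or
    ``"fixed-reference"`` (every frame vs frame 0; length T with step 0
    fixed at (0, 0, 1)).  Cumulative series are prefix sums of the
    per-step displacements.
    """

    time_s: np.ndarray
    dx_px: np.ndarray
    dy_px: np.ndarray
    peak_height: np.ndarray
    mode: str = "adjacent"
    recording_id: str = ""
    sample_rate_hz: float = float("nan")
    cumulative_x: np.ndarray = field(init=False)
    cumulative_y: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("dx_px", "dy_px", "peak_height"):
            if len(getattr(self, name)) != n:
                raise ValidationError("all trace series must share length")
        self.cumulative_x = np.cumsum(self.dx_px)
        self.cumulative_y = np.cumsum(self.dy_px)

    def __len__(self) -> int:
        return len(self.time_s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_s": self.time_s,
            "dx_px": self.dx_px,
            "dy_px": self.dy_px,
            "peak_height": self.peak_height,
            "cum_x_px": self.cumulative_x,
            "cum_y_px": self.cumulative_y,
        })


# --------------------------------------------------------------------------
# correlation primitives
# --------------------------------------------------------------------------

def _check_pair(a: np.ndarray, a_prime: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(a_prime, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValidationError("A and A' must be 2-D arrays")
    if b.shape[0] < a.shape[0] or b.shape[1] < a.shape[1]:
        raise ValidationError("A' must be at least as large as A")
    return a, b


def cross_correlate(a: np.ndarray, a_prime: np.ndarray,
                    grid: SubImageGrid) -> CorrelationMap:
    """Raw product-sum cross-correlation over the search window.

    R(dx, dy) = (1/NM) sum_ij A(i, j) A'(i+dy, j+dx); A is anchored
    centered in A' (for same-size inputs that is index-aligned), and
    product terms whose shifted index falls outside A' are dropped
    (valid-region convention).  The divisor stays NM for every shift.
    """
    a, b = _check_pair(a, a_prime)
    n, m = a.shape
    oi, oj = (b.shape[0] - n) // 2, (b.shape[1] - m) // 2
    r = grid.search_radius
    side = 2 * r + 1
    values = np.zeros((side, side))
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            sy, sx = oi + dy, oj + dx
            i0, i1 = max(0, -sy), min(n, b.shape[0] - sy)
            j0, j1 = max(0, -sx), min(m, b.shape[1] - sx)
            if i0 >= i1 or j0 >= j1:
                continue
            values[dy + r, dx + r] = np.sum(
                a[i0:i1, j0:j1] * b[i0 + sy:i1 + sy, j0 + sx:j1 + sx]
            ) / (n * m)
    return CorrelationMap(values=values, search_radius=r)


def normalized_cross_correlate(a: np.ndarray, a_prime: np.ndarray,
                               grid: SubImageGrid) -> CorrelationMap:
    """Zero-mean unit-variance (Pearson) correlation over each overlap.

    Values lie in [-1, 1]; a value of 1 at a shift means the overlapping
    window of A' is a positive affine transform of A there.  A is anchored
    centered in A' as in :func:`cross_correlate`.  Shifts with a
    zero-variance window in either image get value 0; a zero-variance A is
    a degenerate sub-image and raises.
    """
    a, b = _check_pair(a, a_prime)
    if float(np.var(a)) == 0.0:
        raise DegenerateDataError("zero-variance sub-image cannot be "
                                  "normalized-correlated")
    n, m = a.shape
    oi, oj = (b.shape[0] - n) // 2, (b.shape[1] - m) // 2
    r = grid.search_radius
    side = 2 * r + 1
    values = np.zeros((side, side))
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            sy, sx = oi + dy, oj + dx
            i0, i1 = max(0, -sy), min(n, b.shape[0] - sy)
            j0, j1 = max(0, -sx), min(m, b.shape[1] - sx)
            if i0 >= i1 or j0 >= j1:
                continue
            wa = a[i0:i1, j0:j1]
            wb = b[i0 + sy:i1 + sy, j0 + sx:j1 + sx]
            da = wa - wa.mean()
            db = wb - wb.mean()
            denom = np.sqrt(np.sum(da * da) * np.sum(db * db))
            if denom > 0:
                values[dy + r, dx + r] = np.sum(da * db) / denom
    return CorrelationMap(values=values, search_radius=r)


def _shift_rank(search_radius: int) -> np.ndarray:
    """Tie-break priority per shift: smallest |dx|+|dy|, then dy, then dx."""
    r = search_radius
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    order = np.lexsort((dx.ravel(), dy.ravel(),
                        (np.abs(dx) + np.abs(dy)).ravel()))
    rank = np.empty(order.size, dtype=int)
    rank[order] = np.arange(order.size)
    return rank


def find_peak(corr: CorrelationMap) -> tuple[int, int, float]:
    """Integer argmax of a correlation map with deterministic tie-breaks.

    Ties (exact value equality) resolve to the smallest |dx|+|dy|, then
    smallest dy, then smallest dx; an all-equal map therefore yields
    (0, 0).  Returns (dx, dy, height).
    """
    r = corr.search_radius
    flat = corr.values.ravel()
    best = flat.max()
    rank = _shift_rank(r)
    candidates = np.flatnonzero(flat == best)
    idx = candidates[np.argmin(rank[candidates])]
    dy, dx = divmod(idx, 2 * r + 1)
    return int(dx - r), int(dy - r), float(best)


# --------------------------------------------------------------------------
# batched normalized correlation (internal acceleration)
# --------------------------------------------------------------------------

def _window_sums(x: np.ndarray, n: int, m: int) -> np.ndarray:
    """Sliding n x m window sums over the trailing axes of a (B, P, Q) stack."""
    c = x.cumsum(axis=1).cumsum(axis=2)
    c = np.pad(c, ((0, 0), (1, 0), (1, 0)))
    return (c[:, n:, m:] - c[:, :-n, m:] - c[:, n:, :-m] + c[:, :-n, :-m])


def _ncc_stack(templates: np.ndarray, regions: np.ndarray) -> np.ndarray:
    """Full-overlap Pearson correlation maps for a batch of pairs.

    templates: (B, N, M); regions: (B, N+2r, M+2r).  Returns (B, 2r+1,
    2r+1) maps identical (to FFT rounding) to looping
    :func:`normalized_cross_correlate` over the batch.
    """
    b, n, m = templates.shape
    nm = n * m
    raw = fftconvolve(regions, templates[:, ::-1, ::-1], mode="valid",
                      axes=(1, 2))
    s1 = _window_sums(regions, n, m)
    s2 = _window_sums(regions * regions, n, m)
    tsum = templates.sum(axis=(1, 2))[:, None, None]
    tdev = (templates * templates).sum(axis=(1, 2))[:, None, None] \
        - tsum * tsum / nm
    num = raw - tsum * s1 / nm
    wdev = s2 - s1 * s1 / nm
    den_sq = np.clip(tdev, 0.0, None) * np.clip(wdev, 0.0, None)
    out = np.zeros_like(num)
    good = den_sq > 0
    np.divide(num, np.sqrt(den_sq, where=good, out=np.ones_like(den_sq)),
              out=out, where=good)
    return out


def _peaks_batch(maps: np.ndarray, rank: np.ndarray,
                 search_radius: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized find_peak over a (B, side, side) stack of maps."""
    r = search_radius
    side = 2 * r + 1
    flat = maps.reshape(maps.shape[0], side * side)
    best = flat.max(axis=1)
    # mask non-maximal entries, then take the best-ranked tied shift
    ranked = np.where(flat == best[:, None], rank[None, :], side * side)
    idx = ranked.argmin(axis=1)
    dy, dx = np.divmod(idx, side)
    return dx - r, dy - r, best


def track_sequence(
    recording: SpeckleRecording | np.ndarray,
    grid: SubImageGrid | None = None,
    mode: str = "adjacent",
) -> DisplacementTrace:
    """Track speckle motion through a frame stack.

    For ``mode="adjacent"`` frame t is correlated with frame t+1 (one step
    per frame pair); for ``mode="fixed-reference"`` every frame is
    correlated with frame 0 and step 0 is defined as (0, 0, 1).  Per step,
    the normalized-correlation peak (dx, dy, height) of every grid cell is
    averaged (cells with a zero-variance template are skipped; if a step
    has no usable cell the stack is untrackable).  Output is invariant to
    a global positive rescaling of all frames.
    """
    if grid is None:
        grid = SubImageGrid()
    if mode not in ("adjacent", "fixed-reference"):
        raise ValidationError(f"unknown tracking mode {mode!r}")

    if isinstance(recording, SpeckleRecording):
        frames = np.asarray(recording.frames, dtype=np.float64)
        fs = recording.acquisition.frame_rate_hz
        rec_id = recording.recording_id
    else:
        frames = np.asarray(recording, dtype=np.float64)
        fs = float("nan")
        rec_id = ""
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValidationError("need a (T, rows, cols) stack with T >= 2")

    t_frames = frames.shape[0]
    origins = grid.cell_origins(frames.shape[1:])
    r = grid.search_radius
    n, m = grid.subimage_rows, grid.subimage_cols
    rank = _shift_rank(r)

    if mode == "adjacent":
        n_steps = t_frames - 1
        tmpl_frames = frames[:-1]
        target_frames = frames[1:]
        step_times = (np.arange(1, t_frames)) / fs if np.isfinite(fs) \
            else np.arange(1, t_frames).astype(float)
    else:
        n_steps = t_frames - 1
        tmpl_frames = np.broadcast_to(frames[0], (n_steps, *frames.shape[1:]))
        target_frames = frames[1:]
        step_times = (np.arange(1, t_frames)) / fs if np.isfinite(fs) \
            else np.arange(1, t_frames).astype(float)

    sum_dx = np.zeros(n_steps)
    sum_dy = np.zeros(n_steps)
    sum_h = np.zeros(n_steps)
    n_valid = np.zeros(n_steps, dtype=int)

    for (i0, j0) in origins:
        templates = np.ascontiguousarray(
            tmpl_frames[:, i0:i0 + n, j0:j0 + m])
        regions = np.ascontiguousarray(
            target_frames[:, i0 - r:i0 + n + r, j0 - r:j0 + m + r])
        tvar = templates.var(axis=(1, 2))
        valid = tvar > 0
        if not valid.any():
            continue
        maps = _ncc_stack(templates, regions)
        dx, dy, h = _peaks_batch(maps, rank, r)
        sum_dx[valid] += dx[valid]
        sum_dy[valid] += dy[valid]
        sum_h[valid] += h[valid]
        n_valid[valid] += 1

    if np.any(n_valid == 0):
        raise DegenerateDataError(
            "zero-variance sub-images in every grid cell for at least one "
            "frame pair; stack is untrackable")

    dx_t = sum_dx / n_valid
    dy_t = sum_dy / n_valid
    h_t = sum_h / n_valid

    if mode == "fixed-reference":
        step_times = np.concatenate([[0.0], step_times])
        dx_t = np.concatenate([[0.0], dx_t])
        dy_t = np.concatenate([[0.0], dy_t])
        h_t = np.concatenate([[1.0], h_t])

    return DisplacementTrace(time_s=step_times, dx_px=dx_t, dy_px=dy_t,
                             peak_height=h_t, mode=mode, recording_id=rec_id,
                             sample_rate_hz=fs)


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

def write_trace_csv(trace: DisplacementTrace, path, grid: SubImageGrid | None = None) -> None:
    """Write a trace as CSV plus a JSON sidecar with its provenance."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    sidecar = {
        "mode": trace.mode,
        "recording_id": trace.recording_id,
        "sample_rate_hz": None if not np.isfinite(trace.sample_rate_hz)
        else trace.sample_rate_hz,
    }
    if grid is not None:
        sidecar["grid"] = {
            "subimage_rows": grid.subimage_rows,
            "subimage_cols": grid.subimage_cols,
            "stride": grid.stride,
            "search_radius": grid.search_radius,
        }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, sort_keys=True, indent=2))


def read_trace_csv(path) -> DisplacementTrace:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fs = meta.get("sample_rate_hz")
    return DisplacementTrace(
        time_s=df["t_s"].to_numpy(),
        dx_px=df["dx_px"].to_numpy(),
        dy_px=df["dy_px"].to_numpy(),
        peak_height=df["peak_height"].to_numpy(),
        mode=meta.get("mode", "adjacent"),
        recording_id=meta.get("recording_id", ""),
        sample_rate_hz=float("nan") if fs is None else float(fs),
    )
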
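"""Time warping, smoothing and per-stage summarisation of fluorescence traces.

Raw inputs are per-branch nuclear intensity time series spanning three cell
cycles (8-, 16- and 32-cell), with the two division times recorded per
branch. Time within every cycle is linearly warped to (0, 1], rounded to the
nearest multiple of 0.05 (20 grid points per cycle; colliding samples are
averaged) and shifted by the cycle index, so warped time runs over (0, 3]
with division times mapping to 1 and 2 exactly. Early/late half-cycle
cutoffs at 0.5 within the 16- and 32-cell cycles define the five stages
8, 16E, 16L, 32E and 32L.

Conventions (declared, since the source procedures leave them open):

* the warped grid per cycle is {0.05, ..., 1.00}; a sample rounding to the
  cycle start is merged into the first grid point;
* a grid point exactly at a half-cycle boundary belongs to the late stage;
* smoothing (centred moving average, 2.5 h window, never crossing a
  division; the window shrinks at cycle edges) runs before the 2 h
  post-division exclusion, and both act in raw time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

GRID_STEP = 0.05
POINTS_PER_CYCLE = 20
SMOOTH_WINDOW_H = 2.5
EXCLUDE_POST_DIVISION_H = 2.0

CHANNEL_OF_VAR = {"Y": "YAP", "C": "CDX2", "S": "SOX2"}


@dataclass
class TraceBranch:
    """One lineage branch's raw per-channel samples plus division times."""

    embryo_id: str
    batch_id: str
    lineage_id: int
    branch_code: str
    samples: dict[str, tuple[np.ndarray, np.ndarray]]
    division_times: tuple[float, float]
    span: tuple[float, float]

    def __post_init__(self) -> None:
        t0, t_end = self.span
        d1, d2 = self.division_times
        if not (t0 <= d1 <= d2 <= t_end):
            raise ValueError(
                f"division times {self.division_times} outside span {self.span}"
            )
        if not set(self.branch_code) <= {"a", "b"} or len(self.branch_code) != 2:
            raise ValueError(f"malformed branch code {self.branch_code!r}")
        clean = {}
        for channel, (t, v) in self.samples.items():
            t = np.asarray(t, dtype=float)
            v = np.asarray(v, dtype=float)
            if len(t) != len(v):
                raise ValueError(f"{channel}: time/value length mismatch")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{channel}: times must be strictly increasing")
            clean[channel] = (t, v)
        self.samples = clean

    @property
    def cycle_boundaries(self) -> np.ndarray:
        return np.array(
            [self.span[0], self.division_times[0], self.division_times[1], self.span[1]]
        )

    def cycle_of(self, t: np.ndarray) -> np.ndarray:
        """Cycle index 0..2; a sample exactly at a division ends its cycle."""
        return np.clip(
            np.searchsorted(self.cycle_boundaries[1:3], t, side="left"), 0, 2
        )


@dataclass
class WarpedSeries:
    """Per-channel values on the shifted warped-time grid (multiples of 0.05)."""

    branch: TraceBranch
    series: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def stage_values(self, channel: str, stage: int) -> tuple[np.ndarray, np.ndarray]:
        t, v = self.series[channel]
        mask = assign_stage(t) == stage
        return t[mask], v[mask]


def warp_branch(branch: TraceBranch) -> WarpedSeries:
    """Warp each channel onto the 20-point-per-cycle shifted grid."""
    bounds = branch.cycle_boundaries
    if np.any(np.diff(bounds) <= 0):
        raise ValueError("cycle of zero duration")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for channel, (t, v) in branch.samples.items():
        keep = (t >= bounds[0]) & (t <= bounds[-1])
        t, v = t[keep], v[keep]
        c = branch.cycle_of(t)
        x = (t - bounds[c]) / (bounds[c + 1] - bounds[c])
        grid = np.round(x / GRID_STEP).astype(int)
        grid = np.clip(grid, 1, POINTS_PER_CYCLE)  # cycle-start samples -> 0.05
        key = c * POINTS_PER_CYCLE + grid
        uniq, inv = np.unique(key, return_inverse=True)
        sums = np.bincount(inv, weights=v)
        counts = np.bincount(inv)
        wt = np.round(uniq * GRID_STEP, 2)
        out[channel] = (wt, sums / counts)
    return WarpedSeries(branch, out)


def assign_stage(warped_time: float | np.ndarray) -> int | np.ndarray:
    """Stage index 0..4 of a shifted warped time in (0, 3].

    The 8-cell cycle (0, 1] is stage 0; the 16- and 32-cell cycles split at
    their half-cycle point, with the boundary itself belonging to the late
    stage.
    """
    x = np.asarray(warped_time, dtype=float)
    if np.any((x < 0) | (x > 3)):
        raise ValueError("warped time outside [0, 3]")
    stage = np.select(
        [x <= 1.0, x < 1.5, x <= 2.0, x < 2.5],
        [0, 1, 2, 3],
        default=4,
    )
    return int(stage) if np.isscalar(warped_time) else stage


def _moving_average_shrinking(v: np.ndarray, half: int) -> np.ndarray:
    """Centred moving average whose window shrinks at the segment edges."""
    n = len(v)
    if n == 0 or half <= 0:
        return v.copy()
    csum = np.concatenate([[0.0], np.cumsum(v)])
    i = np.arange(n)
    lo = np.maximum(0, i - half)
    hi = np.minimum(n - 1, i + half)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def smooth_and_trim(
    branch: TraceBranch,
    window_h: float = SMOOTH_WINDOW_H,
    exclude_h: float = EXCLUDE_POST_DIVISION_H,
) -> TraceBranch:
    """Smooth within each cycle, then drop the first ``exclude_h`` hours of
    every cycle (the post-division recovery window)."""
    bounds = branch.cycle_boundaries
    new_samples = {}
    for channel, (t, v) in branch.samples.items():
        c = branch.cycle_of(t)
        sv = np.empty_like(v)
        for cyc in range(3):
            mask = c == cyc
            seg_t, seg_v = t[mask], v[mask]
            if len(seg_t) > 1:
                dt = np.median(np.diff(seg_t))
                half = int(np.floor(window_h / (2.0 * dt)))
            else:
                half = 0
            sv[mask] = _moving_average_shrinking(seg_v, half)
        cycle_start = bounds[c]
        keep = (t - cycle_start) >= exclude_h
        new_samples[channel] = (t[keep], sv[keep])
    return replace(branch, samples=new_samples)


@dataclass
class StageSummary:
    stage: int
    value: float
    missing: bool = False


def summarize(branch: TraceBranch, variable: str) -> list[StageSummary]:
    """Per-stage summaries of an (already normalised) branch.

    YAP: the mean over each stage's grid points, stages 1-4. CDX2/SOX2: the
    final grid value of each stage, stages 2-4; SOX2 additionally subtracts
    the branch's value at the start of the 16-cell stage (its first 16-cell
    grid point) to normalise branch-specific backgrounds.
    """
    channel = CHANNEL_OF_VAR.get(variable, variable)
    warped = warp_branch(branch)
    if channel not in warped.series:
        raise KeyError(f"branch has no channel {channel!r}")
    t, v = warped.series[channel]
    stages = range(1, 5) if variable == "Y" else range(2, 5)
    baseline = 0.0
    if variable == "S":
        in16 = t > 1.0
        if not in16.any():
            warnings.warn("no 16-cell samples for SOX2 baseline; using 0")
        else:
            baseline = v[in16][0]
    out = []
    for stage in stages:
        mask = (assign_stage(t) == stage) & ~np.isnan(v)
        if not mask.any():
            out.append(StageSummary(stage, np.nan, missing=True))
        elif variable == "Y":
            out.append(StageSummary(stage, float(v[mask].mean())))
        else:
            out.append(StageSummary(stage, float(v[mask][-1] - baseline)))
    return out
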
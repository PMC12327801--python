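"""Synthetic imaging-like inputs with known ground truth.

Two levels of synthesis are provided. :func:`generate_trajectories` samples
binary stage-indexed trajectories directly from a reference fixture network
via the lineage simulator. :func:`generate_traces` goes one level deeper and
emits continuous per-branch fluorescence traces whose discretisation should
recover the sampled binary states:

* cleavage timing — every cell's cycle length is drawn from a normal
  distribution (default 12 h +/- 0.75 h), giving asynchronous 8->16->32
  lineage trees;
* nuclear YAP — a baseline plus ``yap_state_separation`` when the hidden
  state is nuclear, a slow embryo-wide downward linear trend (removed by the
  per-time-point z-scoring downstream) and i.i.d. Gaussian noise; the
  16-cell-stage intensities are therefore bimodal;
* CDX2/SOX2 — smooth logistic ramps that switch with the hidden binary
  state at stage boundaries (configurable halftime) plus noise; SOX2
  additionally carries a batch-specific additive background;
* sampling — 15 min for YAP, 30 min for the target channels, as in the
  imaging protocol being emulated.

Noise realisations are drawn per *cell*, so sister branches share their
pre-division samples exactly. One global seed expands into per-embryo
substreams, so the embryo count never reshuffles earlier embryos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import FixtureDBN
from .preprocess import TraceBranch
from .simulate import (
    _ANCESTOR,
    N_CELLS,
    Cohort,
    _sample_embryo,
    simulate_cohort,
)
from .structures import node_stage

YAP_BASE = 100.0
YAP_TREND_PER_H = -1.5
TF_BASE = 5.0
TF_AMPLITUDE = 50.0
SOX2_BATCH_BACKGROUND_STEP = 2.0
DEFAULT_BATCHES = ("B1", "B2", "B3")


@dataclass
class TraceGenConfig:
    """Parameters of the continuous-trace generator (times in hours unless noted)."""

    n_embryos: int = 12
    batch_ids: tuple[str, ...] | None = None  # per-embryo labels
    cycle_length_mean: float = 12.0
    cycle_length_sd: float = 0.75
    sampling_interval_yap: float = 15.0  # minutes
    sampling_interval_tf: float = 30.0  # minutes
    noise_sd: float = 3.0  # intensity units
    yap_state_separation: float = 40.0  # intensity units
    tf_ramp_halftime: float = 1.5  # hours after stage entry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval_yap <= 0 or self.sampling_interval_tf <= 0:
            raise ValueError("sampling intervals must be positive")
        if self.cycle_length_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.batch_ids is not None and len(self.batch_ids) != self.n_embryos:
            raise ValueError("batch_ids must have one label per embryo")

    def resolved_batches(self) -> tuple[str, ...]:
        if self.batch_ids is not None:
            return tuple(self.batch_ids)
        return tuple(
            DEFAULT_BATCHES[i % len(DEFAULT_BATCHES)] for i in range(self.n_embryos)
        )


def generate_trajectories(
    fixture: FixtureDBN, n_embryos: int, seed: int
) -> pd.DataFrame:
    """Sample binary trajectories from a fixture: 32 branches per embryo,
    with the ground-truth induction class recorded per branch."""
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    return simulate_cohort(fixture.to_results(), n_embryos, seed).to_frame()


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _ramp(t: np.ndarray, transitions: list[tuple[float, int]], halftime: float) -> np.ndarray:
    """Smooth 0/1 response following state transitions at given times."""
    r = np.zeros_like(t)
    prev = 0
    k = halftime / 3.0
    for t_k, target in transitions:
        if target != prev:
            r = r + (target - prev) * _sigmoid((t - t_k - halftime) / k)
            prev = target
    return r


def generate_traces(
    fixture: FixtureDBN, cfg: TraceGenConfig
) -> tuple[dict[str, list[TraceBranch]], pd.DataFrame]:
    """Continuous traces per embryo plus the hidden ground-truth table."""
    results = fixture.to_results()
    channels = [c for c in results.structure.channels if c != "Y"]
    batches = cfg.resolved_batches()
    batch_bg = {
        b: SOX2_BATCH_BACKGROUND_STEP * k
        for k, b in enumerate(dict.fromkeys(batches))
    }
    dt_yap = cfg.sampling_interval_yap / 60.0
    dt_tf = cfg.sampling_interval_tf / 60.0

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_embryos)
    embryos: dict[str, list[TraceBranch]] = {}
    cell_values = {
        node: np.empty((cfg.n_embryos, N_CELLS[node_stage(node)]), dtype=np.int8)
        for node in results.structure.nodes
    }
    anc = _ANCESTOR
    for e, ss in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        embryo_id = f"e{e:04d}"
        batch = batches[e]
        vals = _sample_embryo(results, rng)
        for node, arr in vals.items():
            cell_values[node][e] = arr

        len0 = rng.normal(cfg.cycle_length_mean, cfg.cycle_length_sd, 8)
        len1 = rng.normal(cfg.cycle_length_mean, cfg.cycle_length_sd, 16)
        len2 = rng.normal(cfg.cycle_length_mean, cfg.cycle_length_sd, 32)
        for arr in (len0, len1, len2):
            np.clip(arr, 0.25 * cfg.cycle_length_mean, None, out=arr)
        b = np.arange(32)
        d1 = len0[anc[0]]
        d2 = d1 + len1[anc[1]]
        end = d2 + len2[b]
        # observation stops at the embryo's first 32->64 division, so every
        # retained time point sees all 32 branches (their own cycle ends are
        # still recorded per branch for warping)
        t_obs = float(end.min())

        # per-cell noise, in a fixed draw order, per channel
        grids = {"YAP": np.arange(0.0, t_obs + 1e-9, dt_yap)}
        for g in channels:
            grids[{"C": "CDX2", "S": "SOX2"}[g]] = np.arange(
                0.0, t_obs + 1e-9, dt_tf
            )
        noise: dict[str, dict[tuple[int, int], np.ndarray]] = {}
        for ch, grid in grids.items():
            per_cell = {}
            for lin in range(8):
                m = grid <= len0[lin]
                per_cell[(0, lin)] = rng.normal(0, cfg.noise_sd, int(m.sum()))
            for j in range(16):
                a, bnd = len0[j // 2], len0[j // 2] + len1[j]
                m = (grid > a) & (grid <= bnd)
                per_cell[(1, j)] = rng.normal(0, cfg.noise_sd, int(m.sum()))
            for j in range(32):
                m = (grid > d2[j]) & (grid <= t_obs)
                per_cell[(2, j)] = rng.normal(0, cfg.noise_sd, int(m.sum()))
            noise[ch] = per_cell

        branches = []
        for bi in range(32):
            lineage = bi // 4
            code = "ab"[(bi % 4) // 2] + "ab"[bi % 2]
            mid1 = d1[bi] + (d2[bi] - d1[bi]) / 2.0
            mid2 = d2[bi] + (end[bi] - d2[bi]) / 2.0
            samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}

            t = grids["YAP"][grids["YAP"] <= t_obs]
            y_states = np.select(
                [t <= d1[bi], t <= mid1, t <= d2[bi], t <= mid2],
                [
                    vals["Y0"][anc[0][bi]],
                    vals["Y1"][anc[1][bi]],
                    vals["Y2"][anc[2][bi]],
                    vals["Y3"][anc[3][bi]],
                ],
                default=vals["Y4"][bi],
            )
            signal = (
                YAP_BASE
                + cfg.yap_state_separation * y_states
                + YAP_TREND_PER_H * t
            )
            nz = np.concatenate(
                [
                    noise["YAP"][(0, lineage)],
                    noise["YAP"][(1, anc[1][bi])],
                    noise["YAP"][(2, bi)],
                ]
            )
            samples["YAP"] = (t, signal + nz[: len(t)])

            for g in channels:
                ch = {"C": "CDX2", "S": "SOX2"}[g]
                tg = grids[ch][grids[ch] <= t_obs]
                transitions = [
                    (mid1, int(vals[f"{g}2"][anc[2][bi]])),
                    (d2[bi], int(vals[f"{g}3"][bi])),
                    (mid2, int(vals[f"{g}4"][bi])),
                ]
                sig = TF_BASE + TF_AMPLITUDE * _ramp(tg, transitions, cfg.tf_ramp_halftime)
                if g == "S":
                    sig = sig + batch_bg[batch]
                nz = np.concatenate(
                    [
                        noise[ch][(0, lineage)],
                        noise[ch][(1, anc[1][bi])],
                        noise[ch][(2, bi)],
                    ]
                )
                samples[ch] = (tg, sig + nz[: len(tg)])

            branches.append(
                TraceBranch(
                    embryo_id=embryo_id,
                    batch_id=batch,
                    lineage_id=lineage + 1,
                    branch_code=code,
                    samples=samples,
                    division_times=(float(d1[bi]), float(d2[bi])),
                    span=(0.0, float(end[bi])),
                )
            )
        embryos[embryo_id] = branches

    cohort = Cohort(
        results.structure.name,
        results.structure.channels,
        cell_values,
        seed=cfg.seed,
        metadata={"generator": "traces", "fixture": fixture.name},
    )
    truth = cohort.to_frame()
    truth.insert(1, "batch_id", np.repeat(list(batches), 32))
    return embryos, truth
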
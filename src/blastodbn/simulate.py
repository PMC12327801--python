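"""Lineage-aware forward simulation of synthetic embryos from a DBN.

A synthetic embryo is a collection of 8 independent lineage trees; every
lineage comprises 13 cells (1 + 2 + 2 + 4 + 4 across the five stages), with
divisions between stages 0->1 and 2->3 and daughters sampled independently
conditional on their mother. An embryo therefore ends with 32 cells, i.e.
32 branch trajectories.

Randomness: one cohort seed expands into per-embryo substreams via
``numpy.random.SeedSequence.spawn``, so increasing the embryo count never
reshuffles earlier embryos. Within an embryo the draw order is fixed
(stages in order, nodes in topological order, all cells of a stage drawn in
one vectorised call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import UndefinedCPD
from .model import DBNResults
from .structures import node_stage

N_LINEAGES = 8
CELLS_PER_LINEAGE = (1, 2, 2, 4, 4)  # 13 cells per lineage
N_CELLS = tuple(N_LINEAGES * c for c in CELLS_PER_LINEAGE)  # (8, 16, 16, 32, 32)
DIVISION_STEPS = (0, 2)  # divisions between stages 0->1 and 2->3
BRANCH_CODES = ("aa", "ab", "ba", "bb")
CLASS_LABELS = ("2+", "3+", "4+", "-")

# predecessor cell index (within an embryo, lineages folded) for each stage
_PREV_INDEX = {}
for _s in range(1, 5):
    _n, _np_ = CELLS_PER_LINEAGE[_s], CELLS_PER_LINEAGE[_s - 1]
    _idx = np.arange(N_CELLS[_s])
    _lineage, _within = _idx // _n, _idx % _n
    _prev_within = _within // 2 if _s - 1 in DIVISION_STEPS else _within
    _PREV_INDEX[_s] = _lineage * _np_ + _prev_within

# ancestor cell index at each stage for the 32 final branches
_b = np.arange(32)
_ANCESTOR = {
    0: _b // 4,
    1: (_b // 4) * 2 + (_b % 4) // 2,
    2: (_b // 4) * 2 + (_b % 4) // 2,
    3: _b,
    4: _b,
}


def _cell_code(stage: int, within: int) -> str:
    """Binary lineage code of a cell (s/sa/sb-style coding over {a, b})."""
    n_letters = sum(1 for d in DIVISION_STEPS if d < stage)
    return "".join("ab"[(within >> (n_letters - 1 - k)) & 1] for k in range(n_letters))


@dataclass
class SimLineage:
    """One simulated lineage tree: 13 cells keyed by (stage, code)."""

    cells: dict[tuple[int, str], dict[str, int]]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def branches(self) -> dict[str, dict[str, int]]:
        """The 4 final branches: full per-node trajectories keyed by code."""
        out = {}
        for code in BRANCH_CODES:
            states: dict[str, int] = {}
            for stage in range(5):
                n_letters = sum(1 for d in DIVISION_STEPS if d < stage)
                states.update(self.cells[(stage, code[:n_letters])])
            out[code] = states
        return out


@dataclass
class SimEmbryo:
    lineages: list[SimLineage]

    @property
    def n_final_branches(self) -> int:
        return sum(len(lin.branches()) for lin in self.lineages)


@dataclass
class Cohort:
    """A simulated cohort: per-node cell-level state arrays.

    ``cell_values[node]`` has shape ``(n_embryos, N_CELLS[stage])`` with
    lineages folded (cell index = lineage * cells_per_lineage + within).
    """

    structure_name: str
    channels: tuple[str, ...]
    cell_values: dict[str, np.ndarray]
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_embryos(self) -> int:
        return next(iter(self.cell_values.values())).shape[0]

    def branch_values(self, node: str) -> np.ndarray:
        """(n_embryos, 32) values of ``node`` along the 32 final branches."""
        return self.cell_values[node][:, _ANCESTOR[node_stage(node)]]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_embryos
        df = pd.DataFrame(
            {
                "embryo_id": np.repeat([f"e{i:04d}" for i in range(n)], 32),
                "lineage_id": np.tile(np.arange(32) // 4 + 1, n),
                "branch_code": np.tile(np.array(BRANCH_CODES * 8), n),
            }
        )
        for node in sorted(self.cell_values, key=lambda s: (s[0] != "Y", s)):
            df[node] = self.branch_values(node).reshape(-1)
        for g in self.channels:
            if g == "Y":
                continue
            cls = induction_classes(
                *(self.branch_values(f"{g}{i}") for i in (2, 3, 4))
            )
            df[f"class_{g}"] = np.array(
                [f"{g}{c}" for c in CLASS_LABELS], dtype=object
            )[cls.reshape(-1)]
        return df


def _sample_embryo(
    results: DBNResults, rng: np.random.Generator, n_lineages: int = N_LINEAGES
) -> dict[str, np.ndarray]:
    """Sample cell-level states for one embryo (vectorised over lineages)."""
    order = results.structure.topological_order()
    vals: dict[str, np.ndarray] = {}
    scale = n_lineages / N_LINEAGES
    for node in order:
        stage = node_stage(node)
        n_cells = int(N_CELLS[stage] * scale)
        cpd = results.cpds[node]
        if cpd.parents:
            pa_vals = []
            for pa in cpd.parents:
                pv = vals[pa]
                if node_stage(pa) == stage - 1:
                    prev = _PREV_INDEX[stage]
                    if n_lineages != N_LINEAGES:
                        prev = prev[: n_cells] % int(N_CELLS[stage - 1] * scale)
                    pv = pv[prev]
                pa_vals.append(pv)
            p1 = np.asarray(cpd.p)[tuple(pa_vals)]
        else:
            p1 = np.full(n_cells, float(cpd.p))
        if np.isnan(p1).any():
            raise UndefinedCPD(
                f"simulation reached an unobserved parent configuration of {node}"
            )
        vals[node] = (rng.random(n_cells) < p1).astype(np.int8)
    return vals


def simulate_lineage(results: DBNResults, rng: np.random.Generator) -> SimLineage:
    """Simulate a single 13-cell lineage tree."""
    vals = _sample_embryo(results, rng, n_lineages=1)
    cells: dict[tuple[int, str], dict[str, int]] = {}
    for stage in range(5):
        for within in range(CELLS_PER_LINEAGE[stage]):
            code = _cell_code(stage, within)
            cells[(stage, code)] = {
                node: int(vals[node][within])
                for node in vals
                if node_stage(node) == stage
            }
    return SimLineage(cells)


def simulate_embryo(results: DBNResults, rng: np.random.Generator) -> SimEmbryo:
    """Simulate one embryo as 8 independent lineage trees."""
    return SimEmbryo([simulate_lineage(results, rng) for _ in range(N_LINEAGES)])


def simulate_cohort(results: DBNResults, n_embryos: int, seed: int) -> Cohort:
    """Simulate a reproducible cohort of lineage-structured embryos."""
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_embryos)
    structure = results.structure
    cell_values = {
        node: np.empty((n_embryos, N_CELLS[node_stage(node)]), dtype=np.int8)
        for node in structure.nodes
    }
    for e, ss in enumerate(streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        vals = _sample_embryo(results, rng)
        for node, arr in vals.items():
            cell_values[node][e] = arr
    return Cohort(
        structure.name,
        structure.channels,
        cell_values,
        seed=seed,
        metadata={"n_embryos": n_embryos},
    )


def induction_classes(g2: np.ndarray, g3: np.ndarray, g4: np.ndarray) -> np.ndarray:
    """Class codes 0..3 for (G2+, G3+, G4+, G-) from the stage values."""
    g2, g3, g4 = (np.asarray(a) for a in (g2, g3, g4))
    return np.where(g2 == 1, 0, np.where(g3 == 1, 1, np.where(g4 == 1, 2, 3)))


def class_frequency_stats(cohort: Cohort, channel: str) -> pd.DataFrame:
    """Mean and SD across embryos of per-embryo induction-class fractions."""
    if channel not in cohort.channels:
        raise ValueError(f"cohort has no channel {channel!r}")
    cls = induction_classes(
        *(cohort.branch_values(f"{channel}{i}") for i in (2, 3, 4))
    )
    fracs = np.stack([(cls == k).mean(axis=1) for k in range(4)], axis=1)
    return pd.DataFrame(
        {
            "class": [f"{channel}{c}" for c in CLASS_LABELS],
            "mean": fracs.mean(axis=0),
            "sd": fracs.std(axis=0, ddof=0),
        }
    )


@dataclass
class CellStateCounts:
    """Per-stage distributions of CDX2/SOX2 cell-state counts.

    ``per_embryo[stage]`` is an (n_embryos, 4) array of counts over the
    classes (C+S-, C-S+, C+S+, C-S-); rows sum to the cell count at that
    stage.
    """

    per_embryo: dict[int, np.ndarray]
    labels: tuple[str, ...] = ("C+S-", "C-S+", "C+S+", "C-S-")

    def summary(self) -> pd.DataFrame:
        rows = []
        for stage, counts in sorted(self.per_embryo.items()):
            for k, label in enumerate(self.labels):
                rows.append(
                    {
                        "stage": stage,
                        "state": label,
                        "mean": counts[:, k].mean(),
                        "sd": counts[:, k].std(ddof=0),
                    }
                )
        return pd.DataFrame(rows)

    def plot(self, stage: int = 4, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        counts = self.per_embryo[stage]
        ax.violinplot([counts[:, k] for k in range(4)], showmeans=True)
        ax.set_xticks(range(1, 5), self.labels)
        ax.set_ylabel("cells")
        ax.set_title(f"cell-state counts, stage {stage}")
        return ax


def state_count_distribution(cohort: Cohort, stages: tuple[int, ...] = (2, 3, 4)) -> CellStateCounts:
    """Joint C/S cell-state counts per stage for a fused-model cohort."""
    if not {"C", "S"} <= set(cohort.channels):
        raise ValueError("state counts require a fused (Y, C, S) cohort")
    per_embryo = {}
    for stage in stages:
        c = cohort.cell_values[f"C{stage}"]
        s = cohort.cell_values[f"S{stage}"]
        classes = [
            (c == 1) & (s == 0),
            (c == 0) & (s == 1),
            (c == 1) & (s == 1),
            (c == 0) & (s == 0),
        ]
        per_embryo[stage] = np.stack([m.sum(axis=1) for m in classes], axis=1)
    return CellStateCounts(per_embryo)
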
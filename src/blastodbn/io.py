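"""Readers and writers for the pipeline's plain-text artifact formats.

Traces travel as a tidy TSV (embryo_id, batch_id, lineage_id, branch_code,
channel, time_h, value) with a companion JSON of per-branch division times
and cycle spans. Trajectory tables are TSV with Y0..Y4 / C0..C4 / S0..S4
columns (NA for a missing channel) plus induction-class columns. Fixtures,
fitted models, thresholds and reports are JSON; probabilities are written at
full double precision. All readers validate their schema and report the
offending row or field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .discretize import ThresholdSet
from .model import CPDTable, DBNResults, DiscreteDBN
from .preprocess import TraceBranch
from .structures import build_structure

TRACE_COLUMNS = [
    "embryo_id",
    "batch_id",
    "lineage_id",
    "branch_code",
    "channel",
    "time_h",
    "value",
]
NODE_COLUMNS = [f"{v}{i}" for v in ("Y", "C", "S") for i in range(5)]


# --------------------------------------------------------------------- #
# traces


def write_traces(
    embryos: dict[str, list[TraceBranch]],
    out_dir: str | Path,
    truth: pd.DataFrame | None = None,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    divisions: dict = {}
    for embryo_id, branches in embryos.items():
        divisions[embryo_id] = {}
        for br in branches:
            key = f"L{br.lineage_id}:{br.branch_code}"
            divisions[embryo_id][key] = {
                "batch_id": br.batch_id,
                "division_times": list(br.division_times),
                "span": list(br.span),
            }
            for channel, (t, v) in br.samples.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "embryo_id": embryo_id,
                            "batch_id": br.batch_id,
                            "lineage_id": br.lineage_id,
                            "branch_code": br.branch_code,
                            "channel": channel,
                            "time_h": t,
                            "value": v,
                        }
                    )
                )
    pd.concat(rows, ignore_index=True).to_csv(out / "traces.tsv", sep="\t", index=False)
    (out / "divisions.json").write_text(json.dumps(divisions, indent=1))
    if truth is not None:
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def read_traces(
    in_dir: str | Path,
) -> tuple[dict[str, list[TraceBranch]], pd.DataFrame | None]:
    src = Path(in_dir)
    df = pd.read_csv(src / "traces.tsv", sep="\t")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"traces.tsv lacks columns {missing}")
    divisions = json.loads((src / "divisions.json").read_text())
    embryos: dict[str, list[TraceBranch]] = {}
    for (embryo_id, lineage_id, code), grp in df.groupby(
        ["embryo_id", "lineage_id", "branch_code"], sort=True
    ):
        meta = divisions[str(embryo_id)][f"L{lineage_id}:{code}"]
        samples = {
            channel: (
                sub["time_h"].to_numpy(dtype=float),
                sub["value"].to_numpy(dtype=float),
            )
            for channel, sub in grp.groupby("channel")
        }
        embryos.setdefault(str(embryo_id), []).append(
            TraceBranch(
                embryo_id=str(embryo_id),
                batch_id=str(meta["batch_id"]),
                lineage_id=int(lineage_id),
                branch_code=str(code),
                samples=samples,
                division_times=tuple(meta["division_times"]),
                span=tuple(meta["span"]),
            )
        )
    truth = None
    if (src / "truth.tsv").exists():
        truth = pd.read_csv(src / "truth.tsv", sep="\t")
    return embryos, truth


# --------------------------------------------------------------------- #
# trajectories


def write_trajectories(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
    return path


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in ("embryo_id", "branch_code"):
        if col not in df.columns:
            raise ValueError(f"trajectory table lacks column {col!r}")
    bad = ~df["branch_code"].astype(str).str.fullmatch("[ab]{2}")
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"malformed branch code {df.loc[row, 'branch_code']!r} at row {row}"
        )
    node_cols = [c for c in df.columns if c in NODE_COLUMNS]
    values = df[node_cols].to_numpy(dtype=float)
    ok = np.isnan(values) | np.isin(values, (0.0, 1.0))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ValueError(
            f"non-binary value {values[r, c]} in column {node_cols[c]}, row {r}"
        )
    return df


# --------------------------------------------------------------------- #
# models and thresholds


def write_model(results: DBNResults, path: str | Path) -> Path:
    payload = {
        "structure": results.structure.name,
        "channels": list(results.structure.channels),
        "nobs": results.nobs,
        "loglik": None if np.isnan(results.loglik) else results.loglik,
        "metadata": results.metadata,
        "cpds": [],
    }
    for node in results.structure.topological_order():
        c = results.cpds[node]
        for cfg in np.ndindex(*((2,) * len(c.parents))):
            payload["cpds"].append(
                {
                    "node": node,
                    "parents": list(c.parents),
                    "config": list(map(int, cfg)),
                    "p": None
                    if np.isnan(np.asarray(c.p)[cfg])
                    else float(np.asarray(c.p)[cfg]),
                    "n": float(np.asarray(c.n)[cfg]),
                    "n1": float(np.asarray(c.n1)[cfg]),
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_model(path: str | Path) -> DBNResults:
    payload = json.loads(Path(path).read_text())
    channels = payload["channels"]
    target = [c for c in channels if c != "Y"]
    structure = build_structure(
        payload["structure"], channel=target[0] if len(target) == 1 else "G"
    )
    cpds: dict[str, CPDTable] = {}
    by_node: dict[str, list[dict]] = {}
    for e in payload["cpds"]:
        by_node.setdefault(e["node"], []).append(e)
    for node in structure.topological_order():
        entries = by_node.get(node)
        if not entries:
            raise ValueError(f"model file lacks CPD for node {node}")
        parents = tuple(entries[0]["parents"])
        shape = (2,) * len(parents)
        p = np.full(shape, np.nan)
        n = np.zeros(shape)
        n1 = np.zeros(shape)
        for e in entries:
            cfg = tuple(e["config"])
            p[cfg] = np.nan if e["p"] is None else e["p"]
            n[cfg] = e["n"]
            n1[cfg] = e["n1"]
        if not parents:
            p, n, n1 = np.array(float(p)), np.array(float(n)), np.array(float(n1))
        cpds[node] = CPDTable(node, parents, p, n, n1)
    loglik = payload["loglik"]
    return DBNResults(
        DiscreteDBN(structure),
        cpds,
        nobs=int(payload["nobs"]),
        loglik=np.nan if loglik is None else float(loglik),
        metadata=payload.get("metadata", {}),
    )


def write_thresholds(thresholds: dict[str, ThresholdSet], path: str | Path) -> Path:
    payload = {
        var: {
            "variable": ts.variable,
            "by_stage": {str(k): v for k, v in ts.by_stage.items()},
            "by_batch": ts.by_batch,
            "derivation": ts.derivation,
        }
        for var, ts in thresholds.items()
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_thresholds(path: str | Path) -> dict[str, ThresholdSet]:
    payload = json.loads(Path(path).read_text())
    return {
        var: ThresholdSet(
            variable=d["variable"],
            by_stage={int(k): float(v) for k, v in d["by_stage"].items()},
            by_batch={k: float(v) for k, v in d["by_batch"].items()},
            derivation=d["derivation"],
        )
        for var, d in payload.items()
    }


# --------------------------------------------------------------------- #
# reports and configuration


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, path: str | Path, markdown: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(report), indent=1))
    if markdown:

        def render(d, depth=2):
            lines = []
            for k, v in d.items():
                if isinstance(v, dict):
                    lines.append(f"{'#' * min(depth, 6)} {k}\n")
                    lines.extend(render(v, depth + 1))
                else:
                    vv = f"{v:.4f}" if isinstance(v, float) else v
                    lines.append(f"- **{k}**: {vv}")
            return lines

        md = "# Inference report\n\n" + "\n".join(render(_jsonable(report)))
        path.with_suffix(".md").write_text(md)
    return path


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration; serialized into every artifact."""

    out_dir: str = "artifacts"
    channels: str = "YS"  # YC | YS | YCS
    mode: str = "traces"  # traces | trajectories
    n_embryos: int = 9
    threshold_mode: str = "derive"
    candidates: tuple[str, ...] = ("M1", "M2", "M3", "M4")
    cohort_size: int = 3000
    split_mode: str = "exhaustive"
    seed: int = 0
    pseudocount: float = 0.0
    trace_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channels not in ("YC", "YS", "YCS"):
            raise ValueError("channels must be YC, YS or YCS")
        if self.mode not in ("traces", "trajectories"):
            raise ValueError("mode must be 'traces' or 'trajectories'")
        if self.n_embryos < 1 or self.cohort_size < 1:
            raise ValueError("embryo counts must be positive")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if not (
            self.split_mode == "exhaustive"
            or self.split_mode.startswith("random:")
        ):
            raise ValueError("split_mode must be 'exhaustive' or 'random:N'")

    @property
    def fixture_name(self) -> str:
        return {"YS": "F1", "YC": "F2", "YCS": "F3"}[self.channels]

    @property
    def target_channels(self) -> tuple[str, ...]:
        return tuple(c for c in self.channels if c != "Y")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "candidates" in data:
            data["candidates"] = tuple(data["candidates"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["candidates"] = list(self.candidates)
        return d
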
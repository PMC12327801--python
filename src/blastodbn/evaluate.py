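"""Model selection, robustness, calibration, and headline inference reports.

Selection compares the four candidate architectures by BIC structure score
(``-BIC``; higher preferred) on a training set of embryos. Robustness runs
the selection across train/test splits — exhaustive over all size-6 subsets
for small cohorts, or a seeded random sample of splits. Calibration scores
one-step-ahead node predictions (p(node = 1 | observed parents) pooled over
all non-root nodes of held-out trajectories) with the expected calibration
error over M equal-width probability bins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DBNResults, DiscreteDBN
from .simulate import (
    CLASS_LABELS,
    class_frequency_stats,
    simulate_cohort,
    state_count_distribution,
)
from .structures import PAIRWISE_MODELS

TRAIN_SIZE = 6


@dataclass
class SplitPlan:
    """Train/test embryo splits: exhaustive size-6 subsets or a random sample."""

    embryo_ids: tuple[str, ...]
    mode: str = "exhaustive"  # or "random"
    n_splits: int = 100
    seed: int = 0
    train_size: int = TRAIN_SIZE

    def splits(self) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
        ids = tuple(self.embryo_ids)
        if self.train_size >= len(ids):
            raise ValueError("train size must be smaller than the cohort")
        if self.mode == "exhaustive":
            combos = itertools.combinations(ids, self.train_size)
        elif self.mode == "random":
            rng = np.random.default_rng(self.seed)
            combos = (
                tuple(sorted(rng.choice(len(ids), self.train_size, replace=False)))
                for _ in range(self.n_splits)
            )
            combos = (tuple(ids[i] for i in idx) for idx in combos)
        else:
            raise ValueError(f"unknown split mode {self.mode!r}")
        out = []
        for train in combos:
            test = tuple(i for i in ids if i not in train)
            out.append((tuple(train), test))
        return out


@dataclass
class SelectionResult:
    table: pd.DataFrame
    winner: str | None
    tie: tuple[str, ...] = ()

    def __str__(self) -> str:
        head = f"winner: {self.winner}" if self.winner else f"tie: {self.tie}"
        return head + "\n" + self.table.to_string(index=False)


def select_model(
    train: pd.DataFrame,
    channel: str,
    candidates: tuple[str, ...] = PAIRWISE_MODELS,
    pseudocount: float = 0.0,
) -> SelectionResult:
    """Fit every candidate on the training trajectories and rank by
    structure score. Ties are reported explicitly, never broken silently."""
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    rows = []
    for name in candidates:
        res = DiscreteDBN(name, train, channel).fit(pseudocount)
        rows.append(
            {
                "model": name,
                "loglik": res.loglik,
                "k": res.k_params,
                "n": res.nobs,
                "bic": res.bic,
                "structure_score": res.structure_score,
            }
        )
    table = pd.DataFrame(rows).sort_values("structure_score", ascending=False)
    best = table["structure_score"].max()
    top = tuple(table.loc[np.isclose(table["structure_score"], best, atol=1e-9), "model"])
    if len(top) > 1:
        return SelectionResult(table, winner=None, tie=top)
    return SelectionResult(table, winner=top[0])


def threshold_sensitivity(
    summaries: pd.DataFrame,
    y_binary: pd.DataFrame,
    channel: str,
    thetas: np.ndarray,
    candidates: tuple[str, ...] = PAIRWISE_MODELS,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Winner of BIC selection as the TF binarization threshold varies.

    ``summaries`` is the tidy per-branch TF summary table (stages 2-4);
    ``y_binary`` carries the fixed Y0..Y4 columns per branch. Thresholds
    producing an all-constant channel are flagged degenerate, not fatal.
    """
    sub = summaries[summaries["variable"] == channel]
    wide = sub.pivot_table(
        index=["embryo_id", "lineage_id", "branch_code"],
        columns="stage",
        values="value",
    )
    merged = y_binary.set_index(["embryo_id", "lineage_id", "branch_code"]).join(wide)
    rows = []
    for theta in np.asarray(thetas, dtype=float):
        df = merged.reset_index().copy()
        df[f"{channel}0"] = 0
        df[f"{channel}1"] = 0
        for stage in (2, 3, 4):
            df[f"{channel}{stage}"] = (df[stage] >= theta).astype(float)
        g = df[[f"{channel}{i}" for i in (2, 3, 4)]].to_numpy()
        if g.min() == g.max():
            rows.append({"theta": theta, "winner": None, "degenerate": True})
            continue
        sel = select_model(df, channel, candidates, pseudocount)
        rows.append(
            {"theta": theta, "winner": sel.winner, "degenerate": False}
        )
    return pd.DataFrame(rows)


CLASS_EVIDENCE = {
    "2+": {2: 1},
    "3+": {2: 0, 3: 1},
    "4+": {2: 0, 3: 0, 4: 1},
    "-": {2: 0, 3: 0, 4: 0},
}


def class_evidence(channel: str, label: str) -> dict[str, int]:
    """Evidence set of an induction class, e.g. S3+ -> {S2: 0, S3: 1}."""
    return {f"{channel}{i}": v for i, v in CLASS_EVIDENCE[label].items()}


def predict_class_frequencies(results: DBNResults, channel: str) -> pd.Series:
    """Exact induction-class probabilities of a trained pairwise model."""
    marg = results.posterior(tuple(f"{channel}{i}" for i in (2, 3, 4)))
    probs = {}
    for label in CLASS_LABELS:
        ev = CLASS_EVIDENCE[label]
        sl = tuple(ev.get(i, slice(None)) for i in (2, 3, 4))
        probs[f"{channel}{label}"] = float(np.sum(marg.values[sl]))
    return pd.Series(probs)


@dataclass
class CalibrationReport:
    """Reliability summary: M equal-width bins over [0, 1] and the ECE.

    ``ece`` is the bin-size-weighted mean absolute gap between the mean
    predicted probability and the empirical positive rate. Predictions on a
    bin boundary fall in the lower bin, except 1.0 which stays in the top
    bin.
    """

    n_bins: int
    bin_counts: np.ndarray
    bin_mean_pred: np.ndarray
    bin_pos_rate: np.ndarray
    ece: float

    def frame(self) -> pd.DataFrame:
        edges = np.linspace(0, 1, self.n_bins + 1)
        return pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "count": self.bin_counts,
                "mean_pred": self.bin_mean_pred,
                "pos_rate": self.bin_pos_rate,
            }
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ok = self.bin_counts > 0
        ax.plot([0, 1], [0, 1], "k--", lw=1)
        ax.plot(self.bin_mean_pred[ok], self.bin_pos_rate[ok], "o-")
        ax.set_xlabel("mean predicted probability")
        ax.set_ylabel("empirical positive rate")
        ax.set_title(f"reliability diagram (ECE = {self.ece:.4f})")
        return ax


def expected_calibration_error(
    predictions: np.ndarray, labels: np.ndarray, n_bins: int = 10
) -> CalibrationReport:
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if len(predictions) == 0:
        raise ValueError("no predictions to calibrate")
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels differ in length")
    if np.any((predictions < 0) | (predictions > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    idx = np.ceil(predictions * n_bins).astype(int) - 1
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore"):
        mean_pred = np.bincount(idx, weights=predictions, minlength=n_bins) / counts
        pos_rate = np.bincount(idx, weights=labels, minlength=n_bins) / counts
    gaps = np.abs(pos_rate - mean_pred)
    ece = float(np.nansum(counts / len(predictions) * gaps))
    return CalibrationReport(n_bins, counts, mean_pred, pos_rate, ece)


def one_step_predictions(
    results: DBNResults, test: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled one-step-ahead (p(node=1 | parents), observed value) pairs for
    every non-root node over held-out trajectories."""
    preds, labels = [], []
    for node in results.structure.topological_order():
        c = results.cpds[node]
        if not c.parents or node not in test.columns:
            continue
        p = results.predict_proba(test, node)
        v = test[node].to_numpy(dtype=float)
        ok = ~np.isnan(p) & ~np.isnan(v)
        preds.append(p[ok])
        labels.append(v[ok])
    return np.concatenate(preds), np.concatenate(labels)


def calibration_over_splits(
    df: pd.DataFrame,
    channel: str,
    plan: SplitPlan,
    structure: str = "M3",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Fit on each training split, score ECE on the held-out embryos."""
    rows = []
    for train_ids, test_ids in plan.splits():
        train = df[df["embryo_id"].isin(train_ids)]
        test = df[df["embryo_id"].isin(test_ids)]
        res = DiscreteDBN(structure, train, channel).fit(pseudocount)
        preds, labels = one_step_predictions(res, test)
        rep = expected_calibration_error(preds, labels)
        freqs = predict_class_frequencies(res, channel)
        rows.append(
            {"train": train_ids, "ece": rep.ece, **freqs.to_dict()}
        )
    return pd.DataFrame(rows)


CONSISTENTLY_NUCLEAR = (1, 1, 1, 1, 1)


def _trajectory_posterior(
    results: DBNResults, var: str, evidence: dict[str, int]
) -> pd.Series:
    nodes = tuple(f"{var}{i}" for i in range(5))
    post = results.posterior(nodes, evidence)
    labels, probs = [], []
    for idx in np.ndindex(*post.values.shape):
        labels.append("".join(map(str, idx)))
        probs.append(post.values[idx])
    return pd.Series(probs, index=labels).sort_values(ascending=False)


def report_headline_inference(
    pairwise: dict[str, DBNResults],
    fused: DBNResults | None = None,
    n_embryos: int = 3000,
    seed: int = 0,
    top_k: int = 8,
) -> dict:
    """Structured inference report mirroring the analysis figures.

    For each pairwise model: exact induction-class probabilities, simulated
    class-frequency mean +/- SD over a cohort, and Y-trajectory posteriors
    conditioned on each induction class (with the consistently-nuclear
    trajectory Y = 11111 reported by name). For the fused model: cell-state
    count distributions per stage and Y/C/S trajectory posteriors of
    double-positive (C4 = 1, S4 = 1) cells.
    """
    report: dict = {"n_embryos": n_embryos, "seed": seed, "pairwise": {}}
    for channel, res in pairwise.items():
        cohort = simulate_cohort(res, n_embryos, seed)
        freq = class_frequency_stats(cohort, channel)
        entry: dict = {
            "class_probabilities": predict_class_frequencies(res, channel).to_dict(),
            "class_frequencies_simulated": freq.set_index("class")[
                ["mean", "sd"]
            ].to_dict("index"),
            "y_posterior_by_class": {},
        }
        for label in ("2+", "3+", "4+"):
            ev = class_evidence(channel, label)
            try:
                post = _trajectory_posterior(res, "Y", ev)
            except Exception as exc:  # zero-probability class
                entry["y_posterior_by_class"][f"{channel}{label}"] = {
                    "warning": str(exc)
                }
                continue
            entry["y_posterior_by_class"][f"{channel}{label}"] = {
                "top": post.head(top_k).to_dict(),
                "consistently_nuclear_yap": float(
                    post.get("".join(map(str, CONSISTENTLY_NUCLEAR)), 0.0)
                ),
            }
        report["pairwise"][channel] = entry
    if fused is not None:
        cohort = simulate_cohort(fused, n_embryos, seed)
        counts = state_count_distribution(cohort)
        dp_ev = {"C4": 1, "S4": 1}
        report["fused"] = {
            "state_counts": {
                int(stage): {
                    lab: {
                        "mean": float(arr[:, k].mean()),
                        "sd": float(arr[:, k].std(ddof=0)),
                    }
                    for k, lab in enumerate(counts.labels)
                }
                for stage, arr in counts.per_embryo.items()
            },
            "double_positive_posteriors": {
                var: _trajectory_posterior(fused, var, dp_ev).head(top_k).to_dict()
                for var in ("Y", "C", "S")
            },
        }
    return report
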
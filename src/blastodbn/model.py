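"""Discrete dynamic Bayesian network model and results objects.

The modelling interface follows the Model/Results convention: a
:class:`DiscreteDBN` is built from a trajectory table and a named structure;
``fit()`` performs maximum-likelihood estimation of the Bernoulli conditional
probability tables and returns a :class:`DBNResults` carrying the estimates,
their binomial standard errors, the log-likelihood, BIC and a ``summary()``
table. Exact inference (joint enumeration, variable elimination) and
lineage-structured simulation hang off the results object.

Missing channels (rows observing only one of C/S alongside Y, as produced by
the pairwise imaging datasets) are handled by complete-family counting: a
record contributes to a CPD only when the node and all of its parents are
observed. For the fused network this coincides with the exact marginal
likelihood, because an entirely missing channel marginalises out of the
factorisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import Factor, UndefinedCPD, ZeroProbabilityEvidence, cpd_factor, variable_elimination
from .structures import DBNStructure, build_structure, node_stage


@dataclass
class CPDTable:
    """Bernoulli CPD of one node: p(node=1 | parent configuration).

    ``p`` has shape ``(2,) * len(parents)`` indexed by parent values in the
    structure's parent order; ``n`` holds the number of complete-family
    observations per configuration and ``n1`` the successes among them.
    Configurations never observed at pseudocount 0 carry ``p = NaN``.
    """

    node: str
    parents: tuple[str, ...]
    p: np.ndarray
    n: np.ndarray
    n1: np.ndarray

    @property
    def n_configs(self) -> int:
        return int(np.prod(self.p.shape)) if self.parents else 1

    def standard_errors(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.sqrt(self.p * (1.0 - self.p) / self.n)

    def filled(self, value: float = 0.5) -> np.ndarray:
        return np.where(np.isnan(self.p), value, self.p)


class DiscreteDBN:
    """Stage-indexed binary dynamic Bayesian network over trajectory records.

    Parameters
    ----------
    structure
        A :class:`DBNStructure` or a model name (``M1``-``M4``, ``FUSED``).
    data
        DataFrame with one row per trajectory and one column per node
        (``Y0..Y4`` plus ``C0..C4`` and/or ``S0..S4``); entries are 0/1 or
        NaN for a missing channel.
    channel
        Target channel letter used when ``structure`` is a pairwise name.
    """

    def __init__(
        self,
        structure: DBNStructure | str,
        data: pd.DataFrame | None = None,
        channel: str = "G",
    ):
        if isinstance(structure, str):
            structure = build_structure(structure, channel)
        self.structure = structure
        self.data = None
        if data is not None:
            missing = [n for n in structure.nodes if n not in data.columns]
            if missing:
                raise ValueError(f"data lacks columns for nodes: {missing}")
            self.data = data.reset_index(drop=True)

    @classmethod
    def from_trajectories(
        cls, df: pd.DataFrame, structure: str = "M3", channel: str = "G"
    ) -> "DiscreteDBN":
        """Build a model from a tidy trajectory table.

        If the requested pairwise channel column is absent but the generic
        one exists (or vice versa), the target channel is inferred from the
        available ``C0``/``S0`` columns.
        """
        if structure.upper() != "FUSED" and channel == "G":
            present = [c for c in ("C", "S") if f"{c}0" in df.columns]
            if len(present) != 1:
                raise ValueError(
                    "cannot infer target channel; pass channel='C' or 'S'"
                )
            channel = present[0]
        return cls(structure, df, channel)

    @property
    def nobs(self) -> int:
        return 0 if self.data is None else len(self.data)

    def fit(self, pseudocount: float = 0.0) -> "DBNResults":
        """Maximum-likelihood fit (optionally Laplace-smoothed) of all CPDs.

        Each entry is ``(count[v=1] + pc) / (count + 2 pc)`` under
        complete-family counting; the log-likelihood is evaluated at the
        fitted tables on the fitting data.
        """
        if self.data is None:
            raise ValueError("model was built without data")
        if pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        cpds: dict[str, CPDTable] = {}
        loglik = 0.0
        for node in self.structure.topological_order():
            parents = self.structure.parents(node)
            family = list(parents) + [node]
            sub = self.data[family].dropna()
            if sub.empty:
                raise ValueError(
                    f"family of node {node} is never fully observed in the data"
                )
            vals = sub.to_numpy(dtype=np.int64)
            shape = (2,) * len(parents)
            n = np.zeros(shape)
            n1 = np.zeros(shape)
            if parents:
                code = np.zeros(len(vals), dtype=np.int64)
                for j in range(len(parents)):
                    code = code * 2 + vals[:, j]
                n_flat = np.bincount(code, minlength=2 ** len(parents))
                n1_flat = np.bincount(
                    code, weights=vals[:, -1], minlength=2 ** len(parents)
                )
                n = n_flat.reshape(shape).astype(float)
                n1 = n1_flat.reshape(shape).astype(float)
            else:
                n = np.array(float(len(vals)))
                n1 = np.array(float(vals[:, -1].sum()))
            with np.errstate(divide="ignore", invalid="ignore"):
                p = (n1 + pseudocount) / (n + 2.0 * pseudocount)
            if pseudocount == 0:
                p = np.where(n > 0, p, np.nan)
            cpd = CPDTable(node, parents, p, n, n1)
            cpds[node] = cpd
            # per-record contribution at the fitted table
            if parents:
                p_row = cpd.p.reshape(-1)[code]
            else:
                p_row = np.full(len(vals), float(cpd.p))
            v = vals[:, -1]
            with np.errstate(divide="ignore"):
                ll = np.where(v == 1, np.log(p_row), np.log1p(-p_row))
            loglik += float(np.sum(ll))
        return DBNResults(self, cpds, nobs=self.nobs, loglik=loglik)


@dataclass
class DBNResults:
    """Fitted (or fully specified) DBN: CPD tables plus fit metadata.

    ``bic = k ln(n) - 2 loglik`` with ``k`` counting one free parameter per
    parent configuration per node (roots included); ``structure_score`` is
    ``-bic`` so that higher is better.
    """

    model: DiscreteDBN
    cpds: dict[str, CPDTable]
    nobs: int = 0
    loglik: float = math.nan
    metadata: dict = field(default_factory=dict)

    @property
    def structure(self) -> DBNStructure:
        return self.model.structure

    @property
    def k_params(self) -> int:
        return sum(c.n_configs for c in self.cpds.values())

    @property
    def bic(self) -> float:
        return self.k_params * math.log(self.nobs) - 2.0 * self.loglik

    @property
    def structure_score(self) -> float:
        return -self.bic

    # ------------------------------------------------------------------ #
    # inference

    def factors(self, fill: float | None = None) -> list[Factor]:
        out = []
        for node in self.structure.topological_order():
            c = self.cpds[node]
            p = c.p if fill is None else c.filled(fill)
            out.append(cpd_factor(node, c.parents, np.atleast_1d(p) if c.parents else p))
        return out

    def joint_distribution(self, fill: float | None = None) -> "JointDistribution":
        """Brute-force enumeration of the joint over all 2^m trajectories."""
        nodes = self.structure.topological_order()
        m = len(nodes)
        assign = np.indices((2,) * m).reshape(m, -1).T  # (2^m, m)
        prob = np.ones(2 ** m)
        for j, node in enumerate(nodes):
            c = self.cpds[node]
            p = c.p if fill is None else c.filled(fill)
            if np.isnan(np.min(p)):
                raise UndefinedCPD(
                    f"CPD of {node} has unobserved entries; pass fill=0.5 or refit "
                    "with a pseudocount"
                )
            if c.parents:
                idx = tuple(assign[:, nodes.index(pa)] for pa in c.parents)
                p1 = np.asarray(p)[idx]
            else:
                p1 = np.full(2 ** m, float(p))
            prob *= np.where(assign[:, j] == 1, p1, 1.0 - p1)
        return JointDistribution(nodes, assign, prob)

    def posterior(
        self,
        query: tuple[str, ...] | list[str],
        evidence: dict[str, int] | None = None,
        fill: float | None = None,
    ) -> Factor:
        """Exact posterior p(query | evidence) by variable elimination."""
        return variable_elimination(self.factors(fill), tuple(query), evidence)

    def predict_proba(self, df: pd.DataFrame, node: str) -> np.ndarray:
        """One-step-ahead p(node=1 | observed parents) for each row of ``df``.

        Rows whose parent set is not fully observed get NaN.
        """
        c = self.cpds[node]
        if not c.parents:
            return np.full(len(df), float(c.p))
        vals = df[list(c.parents)].to_numpy(dtype=float)
        out = np.full(len(df), np.nan)
        ok = ~np.isnan(vals).any(axis=1)
        if ok.any():
            idx = tuple(vals[ok, j].astype(int) for j in range(len(c.parents)))
            out[ok] = c.p[idx]
        return out

    def fill_unobserved(self, value: float = 0.5) -> "DBNResults":
        """Copy with NaN CPD entries (never-observed parent configurations)
        replaced by ``value``. Entries unreachable under the model's own
        boundary conditions contribute zero probability regardless of the
        fill, so exact inference is unaffected for them."""
        cpds = {
            node: CPDTable(c.node, c.parents, c.filled(value), c.n, c.n1)
            for node, c in self.cpds.items()
        }
        meta = {**self.metadata, "filled_unobserved": value}
        return DBNResults(self.model, cpds, self.nobs, self.loglik, meta)

    # ------------------------------------------------------------------ #
    # simulation and plotting conveniences (implemented in sibling modules)

    def simulate(self, n_embryos: int, seed: int):
        from .simulate import simulate_cohort

        return simulate_cohort(self, n_embryos, seed)

    def plot_posterior(self, var: str, evidence: dict[str, int] | None = None, ax=None):
        """Plot the posterior over the 32 stage trajectories of one variable."""
        import matplotlib.pyplot as plt

        nodes = tuple(f"{var}{i}" for i in range(5))
        post = self.posterior(nodes, evidence)
        if ax is None:
            _, ax = plt.subplots()
        for idx in np.ndindex(*post.values.shape):
            w = post.values[idx]
            if w < 1e-4:
                continue
            ax.plot(range(5), idx, lw=8 * w, alpha=min(1.0, 0.15 + w), color="C0")
        ax.set_xticks(range(5))
        ax.set_yticks([0, 1])
        ax.set_xlabel("stage")
        ax.set_ylabel(var)
        ax.set_title(f"posterior {var} | {evidence or {}}")
        return ax

    # ------------------------------------------------------------------ #

    def summary(self) -> str:
        lines = [
            f"Discrete DBN results — structure {self.structure.name} "
            f"over channels {'/'.join(self.structure.channels)}",
            f"nobs: {self.nobs}    loglik: {self.loglik:.3f}    "
            f"k: {self.k_params}    BIC: {self.bic:.3f}" if self.nobs else
            f"(fully specified model; no fitting data)",
            "-" * 64,
            f"{'node':<5} {'parent config':<24} {'p(=1)':>8} {'se':>8} {'n':>7}",
        ]
        for node in self.structure.topological_order():
            c = self.cpds[node]
            se = c.standard_errors()
            for idx in np.ndindex(*((2,) * len(c.parents))):
                cfg = ", ".join(f"{p}={v}" for p, v in zip(c.parents, idx)) or "(root)"
                pv = c.p[idx] if c.parents else float(c.p)
                nv = c.n[idx] if c.parents else float(c.n)
                sv = se[idx] if c.parents else float(se)
                p_str = f"{pv:8.4f}" if not np.isnan(pv) else "     nan"
                s_str = f"{sv:8.4f}" if not np.isnan(sv) else "       -"
                lines.append(f"{node:<5} {cfg:<24} {p_str} {s_str} {nv:7.0f}")
        return "\n".join(lines)

    def params_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.structure.topological_order():
            c = self.cpds[node]
            se = np.asarray(c.standard_errors())
            for idx in np.ndindex(*((2,) * len(c.parents))):
                rows.append(
                    {
                        "node": node,
                        "parents": ",".join(c.parents),
                        "config": ",".join(str(v) for v in idx),
                        "p": float(np.asarray(c.p)[idx]),
                        "se": float(se[idx]),
                        "n": float(np.asarray(c.n)[idx]),
                        "n1": float(np.asarray(c.n1)[idx]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class JointDistribution:
    """Explicit probability table over every complete trajectory."""

    nodes: tuple[str, ...]
    assignments: np.ndarray  # (2^m, m) of 0/1
    probs: np.ndarray  # (2^m,)

    def __len__(self) -> int:
        return len(self.probs)

    def total(self) -> float:
        return float(self.probs.sum())

    def condition(self, evidence: dict[str, int]) -> "JointDistribution":
        mask = np.ones(len(self.probs), dtype=bool)
        for var, val in evidence.items():
            mask &= self.assignments[:, self.nodes.index(var)] == val
        z = self.probs[mask].sum()
        if z <= 0:
            raise ZeroProbabilityEvidence(f"evidence {evidence} has probability 0")
        probs = np.where(mask, self.probs, 0.0) / z
        return JointDistribution(self.nodes, self.assignments, probs)

    def marginal(self, query: tuple[str, ...] | list[str]) -> Factor:
        query = tuple(query)
        cols = [self.nodes.index(v) for v in query]
        values = np.zeros((2,) * len(query))
        np.add.at(values, tuple(self.assignments[:, c] for c in cols), self.probs)
        return Factor(query, values)

    def prob_of(self, assignment: dict[str, int]) -> float:
        mask = np.ones(len(self.probs), dtype=bool)
        for var, val in assignment.items():
            mask &= self.assignments[:, self.nodes.index(var)] == val
        return float(self.probs[mask].sum())

    def as_series(self) -> pd.Series:
        labels = ["".join(map(str, row)) for row in self.assignments]
        return pd.Series(self.probs, index=pd.Index(labels, name="".join(self.nodes)))
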
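"""Binary factors and exact inference by variable elimination.

A :class:`Factor` is a nonnegative table over a tuple of binary variables,
stored as an ndarray of shape ``(2,) * len(scope)``. Variable elimination
multiplies the CPD factors of a network, slices in the evidence, and sums
out every non-query, non-evidence variable in a fixed order (topological by
stage, then variable name). Exactness does not depend on the order; fixing
it makes intermediate factors deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import _topo_key


class ZeroProbabilityEvidence(ValueError):
    """Raised when the conditioning event has probability zero."""


class UndefinedCPD(ValueError):
    """Raised when inference touches a CPD entry never observed during fitting."""


@dataclass
class Factor:
    scope: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (2,) * len(self.scope):
            raise ValueError("factor shape does not match scope")

    def __mul__(self, other: "Factor") -> "Factor":
        scope = tuple(sorted(set(self.scope) | set(other.scope), key=_topo_key))
        return Factor(scope, self._expand(scope) * other._expand(scope))

    def _expand(self, scope: tuple[str, ...]) -> np.ndarray:
        """Broadcast values onto a superset scope (sorted)."""
        idx = [self.scope.index(v) if v in self.scope else None for v in scope]
        src = [i for i in idx if i is not None]
        arr = np.transpose(self.values, src)
        shape = tuple(2 if i is not None else 1 for i in idx)
        return arr.reshape(shape)

    def sum_out(self, var: str) -> "Factor":
        axis = self.scope.index(var)
        scope = tuple(v for v in self.scope if v != var)
        return Factor(scope, self.values.sum(axis=axis))

    def reduce(self, var: str, value: int) -> "Factor":
        axis = self.scope.index(var)
        scope = tuple(v for v in self.scope if v != var)
        return Factor(scope, np.take(self.values, value, axis=axis))

    def normalized(self) -> "Factor":
        z = self.values.sum()
        if not np.isfinite(z) or z <= 0:
            raise ZeroProbabilityEvidence("factor has zero total mass")
        return Factor(self.scope, self.values / z)

    def __getitem__(self, assignment: tuple[int, ...]) -> float:
        return float(self.values[assignment])


def cpd_factor(node: str, parents: tuple[str, ...], p1: np.ndarray) -> Factor:
    """Factor p(node | parents) with axes ordered ``parents + (node,)``."""
    p1 = np.asarray(p1, dtype=float)
    values = np.stack([1.0 - p1, p1], axis=-1)
    return Factor(parents + (node,), values)


def variable_elimination(
    factors: list[Factor],
    query: tuple[str, ...],
    evidence: dict[str, int] | None = None,
) -> Factor:
    """Exact posterior p(query | evidence) from a list of CPD factors.

    Returns a normalized :class:`Factor` whose scope is the query variables
    in topological order. Raises :class:`ZeroProbabilityEvidence` if the
    evidence has probability zero, and :class:`UndefinedCPD` if any factor
    contains NaN entries (unobserved parent configurations).
    """
    evidence = dict(evidence or {})
    query = tuple(sorted(set(query) - set(evidence), key=_topo_key))
    if not query:
        raise ValueError("query is empty after removing evidence variables")

    work: list[Factor] = []
    for f in factors:
        if np.isnan(f.values).any():
            raise UndefinedCPD(
                "factor over "
                f"{f.scope} has unobserved entries; fit with a pseudocount or "
                "enable a fill policy"
            )
        for var, val in evidence.items():
            if var in f.scope:
                f = f.reduce(var, val)
        work.append(f)

    all_vars = set().union(*(f.scope for f in work)) if work else set()
    hidden = sorted(all_vars - set(query), key=_topo_key)
    for var in hidden:
        involved = [f for f in work if var in f.scope]
        work = [f for f in work if var not in f.scope]
        if not involved:
            continue
        prod = involved[0]
        for f in involved[1:]:
            prod = prod * f
        work.append(prod.sum_out(var))

    result = Factor((), np.array(1.0))
    for f in work:
        result = result * f
    # align axes to topological query order
    perm = [result.scope.index(v) for v in query]
    return Factor(query, np.transpose(result.values, perm)).normalized()
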
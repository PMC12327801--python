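"""Network structures for the stage-indexed YAP/target dynamic Bayesian networks.

Nodes are binary variables named ``"<var><stage>"`` (e.g. ``"Y0"``, ``"S4"``)
over the five coarse-grained stages 8, 16E, 16L, 32E, 32L (``i = 0..4``).
Edges are restricted to the same or the previous stage, which makes every
candidate a (non-homogeneous) dynamic Bayesian network.

Candidate architectures for a pairwise (Y, G) model, G in {C, S}:

* ``M1`` — YAP chain plus contemporaneous edges ``Y_i -> G_i``.
* ``M2`` — M1 plus a target chain ``G_i -> G_{i+1}``.
* ``M3`` — YAP chain, target chain, and delayed edges ``Y_i -> G_{i+1}``.
* ``M4`` — union of M2 and M3 (both timescales).
* ``FUSED`` — two M3 models, (Y, C) and (Y, S), joined on the shared YAP chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

N_STAGES = 5
STAGE_NAMES = ("8", "16E", "16L", "32E", "32L")

PAIRWISE_MODELS = ("M1", "M2", "M3", "M4")
MODEL_NAMES = PAIRWISE_MODELS + ("FUSED",)


def node_name(var: str, stage: int) -> str:
    return f"{var}{stage}"


def node_var(node: str) -> str:
    return node[0]


def node_stage(node: str) -> int:
    return int(node[1:])


def _topo_key(node: str) -> tuple[int, int, str]:
    # Y precedes its targets within a slice so that contemporaneous
    # Y_i -> G_i edges respect the order.
    var = node_var(node)
    return (node_stage(node), 0 if var == "Y" else 1, var)


@dataclass(frozen=True)
class DBNStructure:
    """A named DAG over (variable, stage) nodes with stage-local edges."""

    name: str
    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    channels: tuple[str, ...] = field(default=("Y",))

    def __post_init__(self) -> None:
        nodes = set(self.nodes)
        for parent, child in self.edges:
            if parent not in nodes or child not in nodes:
                raise ValueError(f"edge ({parent}, {child}) references unknown node")
            dp, dc = node_stage(parent), node_stage(child)
            if dp not in (dc, dc - 1):
                raise ValueError(
                    f"edge ({parent}, {child}) crosses more than one stage"
                )

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of ``node`` in deterministic (stage, name) order."""
        pa = [p for p, c in self.edges if c == node]
        return tuple(sorted(pa, key=lambda n: (node_stage(n), n)))

    def topological_order(self) -> tuple[str, ...]:
        return tuple(sorted(self.nodes, key=_topo_key))

    @property
    def roots(self) -> tuple[str, ...]:
        return tuple(n for n in self.topological_order() if not self.parents(n))


def _chain(var: str) -> list[tuple[str, str]]:
    return [(node_name(var, i), node_name(var, i + 1)) for i in range(N_STAGES - 1)]


def _contemporaneous(g: str) -> list[tuple[str, str]]:
    return [(node_name("Y", i), node_name(g, i)) for i in range(N_STAGES)]


def _delayed(g: str) -> list[tuple[str, str]]:
    return [(node_name("Y", i), node_name(g, i + 1)) for i in range(N_STAGES - 1)]


def build_structure(name: str, channel: str = "G") -> DBNStructure:
    """Return the exact edge set of a named candidate architecture.

    Parameters
    ----------
    name
        One of ``M1``-``M4`` (pairwise) or ``FUSED`` (joint Y/C/S model).
    channel
        Target-variable letter for the pairwise models (``"C"``, ``"S"`` or
        the generic ``"G"``). Ignored for ``FUSED``.
    """
    name = name.upper()
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
    if name == "FUSED":
        channels = ("Y", "C", "S")
        nodes = tuple(node_name(v, i) for v in channels for i in range(N_STAGES))
        edges = _chain("Y") + _chain("C") + _delayed("C") + _chain("S") + _delayed("S")
        return DBNStructure(name, nodes, tuple(edges), channels)

    g = channel.upper()
    if g in ("Y",) or len(g) != 1:
        raise ValueError(f"invalid target channel {channel!r}")
    nodes = tuple(
        node_name(v, i) for v in ("Y", g) for i in range(N_STAGES)
    )
    edges: list[tuple[str, str]] = _chain("Y")
    if name == "M1":
        edges += _contemporaneous(g)
    elif name == "M2":
        edges += _contemporaneous(g) + _chain(g)
    elif name == "M3":
        edges += _chain(g) + _delayed(g)
    elif name == "M4":
        edges += _contemporaneous(g) + _chain(g) + _delayed(g)
    return DBNStructure(name, nodes, tuple(edges), ("Y", g))
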
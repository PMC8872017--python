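"""Genotype encoding of recurrent cells and its DAG phenotype.

A genotype ("chromosome") with N nodes carries:

* one activation gene per node, drawn from {tanh, relu, identity, sigmoid};
* one parent-connection gene per node after the first — node ``k`` (1-based,
  ``k >= 2``) selects a single predecessor in ``{1, ..., k-1}``, which makes
  the phenotype acyclic by construction;
* weight genes for *all* N(N-1)/2 possible edges plus the input and
  recurrent projections of node 1, whether or not an edge is selected.

The phenotype is the directed acyclic graph over selected edges; nodes with
no outgoing edge are terminal and their outputs are averaged to form the
cell output.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

ACTIVATIONS: tuple[str, ...] = ("tanh", "relu", "identity", "sigmoid")

#: reserved (non-edge) weight-gene keys for node 1's projections
INPUT_KEY = "input"
RECUR_KEY = "recur"

ENUMERATION_LIMIT = 10**6


class ChromosomeError(ValueError):
    """Malformed genotype."""


def edge_key(j: int, k: int) -> str:
    """Weight-gene key for the (1-based) ordered edge j -> k, j < k."""
    if not 1 <= j < k:
        raise ChromosomeError(f"invalid edge ({j}, {k})")
    return f"edge:{j}-{k}"


def all_edge_keys(n: int) -> list[str]:
    """Keys for all N(N-1)/2 possible edges, in lexicographic order."""
    return [edge_key(j, k) for j in range(1, n) for k in range(j + 1, n + 1)]


def weight_gene_keys(n: int) -> list[str]:
    """All weight-gene keys of an N-node chromosome, fixed order."""
    return [INPUT_KEY, RECUR_KEY] + all_edge_keys(n)


@dataclass
class Chromosome:
    """Genotype of one recurrent cell.

    ``parents[i]`` (0-based list index ``i``) is the 1-based predecessor of
    node ``i + 2`` and must lie in ``{1, ..., i + 1}``.
    """

    n: int
    activations: tuple[str, ...]
    parents: tuple[int, ...]
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    fitness: float | None = None
    id: int = -1

    def __post_init__(self) -> None:
        validate_genotype(self.n, self.activations, self.parents)

    def selected_edges(self) -> list[tuple[int, int]]:
        """The N-1 selected (parent, child) edges, 1-based."""
        return [(p, i + 2) for i, p in enumerate(self.parents)]

    def selected_weight_keys(self) -> list[str]:
        """Weight-gene keys actually used by the phenotype."""
        return [INPUT_KEY, RECUR_KEY] + [edge_key(j, k) for j, k in self.selected_edges()]

    def genotype(self) -> tuple[tuple[str, ...], tuple[int, ...]]:
        return (self.activations, self.parents)

    def copy(self) -> "Chromosome":
        return Chromosome(
            n=self.n,
            activations=self.activations,
            parents=self.parents,
            weights={k: v.copy() for k, v in self.weights.items()},
            fitness=self.fitness,
            id=self.id,
        )


def validate_genotype(n: int, activations: tuple[str, ...], parents: tuple[int, ...]) -> None:
    if n < 1:
        raise ChromosomeError(f"node count must be >= 1, got {n}")
    if len(activations) != n:
        raise ChromosomeError(f"expected {n} activation genes, got {len(activations)}")
    for a in activations:
        if a not in ACTIVATIONS:
            raise ChromosomeError(f"unknown activation {a!r}")
    if len(parents) != n - 1:
        raise ChromosomeError(f"expected {n - 1} parent genes, got {len(parents)}")
    for i, p in enumerate(parents):
        if not 1 <= p <= i + 1:
            raise ChromosomeError(f"parent gene {i} out of range: {p} not in 1..{i + 1}")


def init_weight(key: str, n_features: int, hidden: int, rng: np.random.Generator) -> np.ndarray:
    """Fresh random matrix for a weight gene (Glorot-scaled normal)."""
    if key == INPUT_KEY:
        shape: tuple[int, int] = (n_features, hidden)
    else:
        shape = (hidden, hidden)
    std = math.sqrt(2.0 / sum(shape))
    return rng.normal(0.0, std, size=shape)


def random_chromosome(
    n: int,
    rng: np.random.Generator,
    n_features: int = 40,
    hidden: int = 16,
    with_weights: bool = True,
) -> Chromosome:
    """Uniform random genotype; weight genes from the init distribution."""
    if n < 1:
        raise ChromosomeError(f"node count must be >= 1, got {n}")
    activations = tuple(ACTIVATIONS[i] for i in rng.integers(0, len(ACTIVATIONS), size=n))
    parents = tuple(int(rng.integers(1, i + 2)) for i in range(n - 1))
    weights: dict[str, np.ndarray] = {}
    if with_weights:
        for key in weight_gene_keys(n):
            weights[key] = init_weight(key, n_features, hidden, rng)
    return Chromosome(n=n, activations=activations, parents=parents, weights=weights)


def to_adjacency(chromosome: Chromosome) -> np.ndarray:
    """N x N matrix: diagonal holds activation indices, (j-1, k-1) = 1 for
    each selected edge j -> k.  Off-diagonal is strictly upper-triangular."""
    n = chromosome.n
    adj = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(chromosome.activations):
        adj[i, i] = ACTIVATIONS.index(a)
    for j, k in chromosome.selected_edges():
        adj[j - 1, k - 1] = 1
    return adj


@dataclass(frozen=True)
class CellDag:
    """Phenotype: nodes with activations, selected edges, terminal set."""

    n: int
    activations: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    parent_of: tuple[int, ...]  # parent_of[i] = 1-based parent of node i+2
    terminals: tuple[int, ...]  # 1-based, sorted


def build_dag(adjacency: np.ndarray) -> CellDag:
    """Realize the DAG from an adjacency matrix produced by to_adjacency."""
    adj = np.asarray(adjacency)
    n = adj.shape[0]
    if adj.shape != (n, n):
        raise ChromosomeError("adjacency must be square")
    if np.any(np.tril(adj, k=-1) != 0):
        raise ChromosomeError("cycle: adjacency has entries below the diagonal")
    activations = tuple(ACTIVATIONS[int(adj[i, i])] for i in range(n))
    edges: list[tuple[int, int]] = []
    parent_of: list[int] = []
    for k in range(2, n + 1):
        col = np.flatnonzero(adj[: k - 1, k - 1])
        if len(col) != 1:
            raise ChromosomeError(f"node {k} must have exactly one parent, got {len(col)}")
        j = int(col[0]) + 1
        edges.append((j, k))
        parent_of.append(j)
    out_degree = np.zeros(n, dtype=int)
    for j, _k in edges:
        out_degree[j - 1] += 1
    terminals = tuple(i + 1 for i in range(n) if out_degree[i] == 0)
    if not terminals:
        raise ChromosomeError("empty terminal set")
    return CellDag(
        n=n,
        activations=activations,
        edges=tuple(edges),
        parent_of=tuple(parent_of),
        terminals=terminals,
    )


def count_search_space(n: int, a: int = 4) -> int:
    """Exact number of genotypes: a**n * (n-1)!."""
    if n < 1 or a < 1:
        raise ValueError("n and a must be >= 1")
    return a**n * math.factorial(n - 1)


def enumerate_space(
    n: int, a: int = 4
) -> Iterator[tuple[tuple[str, ...], tuple[int, ...]]]:
    """Exhaustive, duplicate-free stream of (activations, parents) genotypes.

    Refuses spaces larger than ``ENUMERATION_LIMIT`` genotypes.
    """
    total = count_search_space(n, a)
    if total > ENUMERATION_LIMIT:
        raise ValueError(f"search space of size {total} exceeds enumeration limit")
    acts = ACTIVATIONS[:a]
    parent_ranges = [range(1, i + 2) for i in range(n - 1)]
    for activation_combo in itertools.product(acts, repeat=n):
        for parent_combo in itertools.product(*parent_ranges):
            yield (tuple(activation_combo), tuple(parent_combo))


def chromosome_to_json(chromosome: Chromosome, include_weights: bool = False) -> str:
    doc: dict = {
        "n": chromosome.n,
        "activations": list(chromosome.activations),
        "parents": list(chromosome.parents),
        "weight_keys": weight_gene_keys(chromosome.n),
        "fitness": chromosome.fitness,
        "id": chromosome.id,
    }
    if include_weights:
        doc["weights"] = {k: v.tolist() for k, v in chromosome.weights.items()}
    return json.dumps(doc, indent=2)


def chromosome_from_json(text: str) -> Chromosome:
    doc = json.loads(text)
    weights = {k: np.asarray(v, dtype=np.float64) for k, v in doc.get("weights", {}).items()}
    return Chromosome(
        n=int(doc["n"]),
        activations=tuple(doc["activations"]),
        parents=tuple(int(p) for p in doc["parents"]),
        weights=weights,
        fitness=doc.get("fitness"),
        id=int(doc.get("id", -1)),
    )


def write_edge_list(chromosome: Chromosome, path) -> None:
    """Adjacency export for visualization: one 'j k' line per selected edge."""
    with open(path, "w") as fh:
        for j, k in chromosome.selected_edges():
            fh.write(f"{j} {k}\n")
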
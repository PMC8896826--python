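"""Synthetic trees and binary phenotypes with controlled phylogenetic signal.

Trees come from a Yule (pure-birth) process: starting from a root
bifurcation, with k extant lineages the waiting time to the next split is
exponential with rate k*birth_rate, and the splitting lineage is chosen
uniformly.  The expected root-to-tip depth is sum_{k=2..n} 1/(k*birth_rate),
which makes the generator analytically checkable.

Binary outcomes are laid on the leaves under three models:

``clade_gain``
    a focal-containing clade whose size is closest to ``clade_fraction * n``
    is positive with probability ``p_in``, everything outside with
    ``p_out`` — a trait that tracks the tree, like oxygen-tolerant enzyme
    clades clustering near an aerotolerant host;
``distance_decay``
    P(positive) = 1 / (1 + exp((d - d0)/s)) with d the patristic distance
    from the focal leaf — signal without hard clade boundaries;
``random``
    iid Bernoulli(base) — no phylogenetic structure at all, the null
    regime.

Everything is deterministic given the seed, and outputs embed their
generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .association import correlation_ratio
from .tree import PhyloTree, distances_from, parse_newick, patristic_matrix

__all__ = [
    "TraitSimParams",
    "SimulatedScreen",
    "simulate_yule_tree",
    "simulate_trait",
    "eta_null_distribution",
]

_MODELS = ("clade_gain", "distance_decay", "random")


@dataclass
class TraitSimParams:
    model: str = "clade_gain"
    p_in: float = 0.95
    p_out: float = 0.05
    clade_fraction: float = 0.5
    d0: float = 2.0
    s: float = 0.5
    base: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown trait model {self.model!r}; choose from {_MODELS}")
        for name in ("p_in", "p_out", "base"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 < self.clade_fraction < 1):
            raise ValueError(f"clade_fraction must be in (0, 1), got {self.clade_fraction}")
        if self.s <= 0:
            raise ValueError(f"decay scale s must be > 0, got {self.s}")


@dataclass
class SimulatedScreen:
    tree: PhyloTree
    focal: str
    outcomes: dict[str, str]  # leaf label -> "+" or "-"
    params: TraitSimParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_strain": list(self.outcomes),
                "outcome": list(self.outcomes.values()),
            }
        )

    def to_tsv(self, path) -> None:
        frame = self.to_frame()
        frame.insert(2, "seed", self.params.seed)
        frame.insert(3, "model", self.params.model)
        frame.to_csv(path, sep="\t", index=False)


def simulate_yule_tree(n_leaves: int, birth_rate: float = 1.0, seed: int = 0) -> PhyloTree:
    """Pure-birth tree with ``n_leaves`` leaves, deterministic per seed."""
    if n_leaves < 2:
        raise ValueError(f"n_leaves must be >= 2, got {n_leaves}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be > 0, got {birth_rate}")
    rng = np.random.default_rng(seed)

    # node: [branch_length, children]; root splits at time 0 into 2 lineages
    root = [0.0, []]
    active: list[list] = [[0.0, []], [0.0, []]]
    root[1].extend(active)
    k = 2
    while k < n_leaves:
        dt = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node[0] += dt
        i = int(rng.integers(k))
        left, right = [0.0, []], [0.0, []]
        active[i][1].extend([left, right])
        active[i : i + 1] = [left, right]
        k += 1
    dt = rng.exponential(1.0 / (k * birth_rate))
    for node in active:
        node[0] += dt

    width = len(str(n_leaves))
    counter = iter(range(1, n_leaves + 1))

    def render(node) -> str:
        length, children = node
        if not children:
            return f"t{next(counter):0{width}d}:{length:.12g}"
        inner = ",".join(render(c) for c in children)
        return f"({inner}):{length:.12g}"

    newick = render(root) + ";"
    return parse_newick(newick)


def default_focal(tree: PhyloTree, clade_fraction: float = 0.5) -> str:
    """A sensible focal leaf for trait simulation.

    Returns the first leaf (tree order) of the proper internal clade whose
    size is closest to ``clade_fraction * n`` — i.e. a taxon sitting inside
    a major clade, like a host ortholog inside its family's dominant clade,
    so that ``clade_gain`` simulation is always well defined.
    """
    n = tree.n_leaves
    best: tuple[float, int, str] | None = None
    for node in tree.postorder_nodes():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = [leaf.taxon.label for leaf in node.leaf_iter()]
        key = (abs(len(leaves) - clade_fraction * n), len(leaves), leaves[0])
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError("tree has no proper internal clade")
    return best[2]


def _focal_clades(tree: PhyloTree, focal: str):
    """Proper internal clades containing the focal leaf, with leaf lists."""
    out = []
    for node in tree.postorder_nodes():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = [leaf.taxon.label for leaf in node.leaf_iter()]
        if focal in leaves:
            out.append(leaves)
    return out


def simulate_trait(tree: PhyloTree, focal: str, params: TraitSimParams) -> SimulatedScreen:
    """Draw a binary outcome per leaf under ``params.model``."""
    labels = tree.leaf_labels
    if focal not in labels:
        raise KeyError(f"focal leaf {focal!r} not in tree")
    rng = np.random.default_rng(params.seed)
    n = len(labels)

    if params.model == "clade_gain":
        clades = _focal_clades(tree, focal)
        if not clades:
            raise ValueError(
                "no proper internal clade contains the focal leaf (tree too small)"
            )
        target = params.clade_fraction * n
        clade = min(clades, key=lambda c: (abs(len(c) - target), len(c)))
        inside = set(clade)
        probs = np.array([params.p_in if lab in inside else params.p_out for lab in labels])
    elif params.model == "distance_decay":
        mat = patristic_matrix(tree)
        d = np.array(
            [0.0 if lab == focal else mat.distance(focal, lab) for lab in labels]
        )
        probs = 1.0 / (1.0 + np.exp((d - params.d0) / params.s))
    else:  # random
        probs = np.full(n, params.base)

    draws = rng.random(n) < probs
    outcomes = {lab: ("+" if hit else "-") for lab, hit in zip(labels, draws)}
    return SimulatedScreen(tree=tree, focal=focal, outcomes=outcomes, params=params)


@dataclass
class EtaNullResult:
    observed_eta: float
    null_etas: np.ndarray
    percentile: float  # empirical percentile of observed eta within the null
    n_skipped: int  # degenerate permutations (single category) skipped

    def to_dict(self) -> dict:
        return {
            "observed_eta": self.observed_eta,
            "percentile": self.percentile,
            "n_permutations": int(len(self.null_etas)),
            "n_skipped": self.n_skipped,
        }


def eta_null_distribution(
    tree: PhyloTree,
    focal: str,
    outcomes: dict[str, str],
    n_permutations: int = 500,
    seed: int = 0,
    include_focal: bool = True,
) -> EtaNullResult:
    """Permutation null of the correlation ratio.

    Recomputes eta after shuffling outcome labels over the leaves,
    keeping the distance vector (patristic distances from the focal leaf)
    fixed.  Degenerate shuffles -- impossible here since permutation
    preserves the label multiset, but guarded for robustness -- are
    skipped and counted.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    mat = patristic_matrix(tree)
    dist = distances_from(mat, focal)
    if include_focal:
        labels = [focal] + list(dist.index)
        values = np.concatenate([[0.0], dist.values])
    else:
        labels = list(dist.index)
        values = dist.values
    obs_labels = np.array([outcomes[lab] for lab in labels])
    observed = correlation_ratio(obs_labels, values).eta

    rng = np.random.default_rng(seed)
    null = []
    skipped = 0
    for _ in range(n_permutations):
        perm = rng.permutation(obs_labels)
        try:
            null.append(correlation_ratio(perm, values).eta)
        except ValueError:
            skipped += 1
    null_arr = np.array(null)
    pct = float(100.0 * np.mean(null_arr < observed)) if len(null_arr) else float("nan")
    return EtaNullResult(
        observed_eta=float(observed),
        null_etas=null_arr,
        percentile=pct,
        n_skipped=skipped,
    )
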
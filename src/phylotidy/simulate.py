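"""Birth-death tree simulation retaining extinct lineages.

A Gillespie simulation starting from a single lineage: with k extant
lineages the waiting time to the next event is exponential with rate
(lambda + mu) * k; the event is a speciation with probability
lambda / (lambda + mu), otherwise an extinction.  The simulation halts
the instant the extant count first reaches ``n_extant_stop``.  Extinct
lineages are retained as tips whose root-to-tip path ends before the
stopping time — this is what makes the resulting trees non-ultrametric
and hence compressible by the tidy layout.  Runs that go fully extinct
are discarded and re-run on the same random stream (survival
conditioning).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .tree import PhyloNode, PhyloTree

__all__ = ["BirthDeathParams", "simulate_birth_death", "is_ultrametric"]


@dataclass
class BirthDeathParams:
    """Birth-death simulation parameters.

    Attributes
    ----------
    speciation_rate:
        Per-lineage speciation rate lambda (> 0), per unit time.
    extinction_rate:
        Per-lineage extinction rate mu (>= 0), per unit time.
    n_extant_stop:
        Stop the instant this many lineages are simultaneously extant.
    seed:
        Seed for the random stream (None draws from OS entropy).
    """

    speciation_rate: float = 1.0
    extinction_rate: float = 0.0
    n_extant_stop: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.speciation_rate <= 0:
            raise ValueError("speciation_rate must be positive")
        if self.extinction_rate < 0:
            raise ValueError("extinction_rate must be >= 0")
        if self.n_extant_stop < 1:
            raise ValueError("n_extant_stop must be >= 1")


def _attempt(
    params: BirthDeathParams,
    rng: np.random.Generator,
    include_stem: bool,
    grace: str,
) -> Optional[PhyloNode]:
    lam = params.speciation_rate
    mu = params.extinction_rate
    total = lam + mu
    p_speciation = lam / total

    root = PhyloNode()
    t = 0.0
    # each extant lineage: (node, birth_time); node's branch length is set
    # when the lineage closes (speciation, extinction, or the stop time)
    extant: list[tuple[PhyloNode, float]] = [(root, 0.0)]
    first_split: Optional[PhyloNode] = None

    while extant:
        k = len(extant)
        if k >= params.n_extant_stop:
            if grace == "next-event":
                # observe the tree during the window in which the extant
                # count stands at the stop value: end at the time the next
                # event would occur (without executing it), so terminal
                # branches have positive length
                t += rng.exponential(1.0 / (total * k))
            break
        t += rng.exponential(1.0 / (total * k))
        idx = int(rng.integers(k))
        node, birth = extant.pop(idx)
        node.branch_length = t - birth
        if rng.random() < p_speciation:
            left = node.add_child(PhyloNode())
            right = node.add_child(PhyloNode())
            extant.append((left, t))
            extant.append((right, t))
            if first_split is None:
                first_split = node
        # else extinction: the node stays a tip ending before the stop time

    if not extant:
        return None  # full extinction; caller restarts
    for node, birth in extant:
        node.branch_length = t - birth

    if params.n_extant_stop == 1:
        # the stop condition is met before any event can occur
        root.branch_length = None
        return root
    assert first_split is not None
    if not include_stem:
        first_split.branch_length = None
        first_split.parent = None
        return first_split
    root.parent = None
    return root


def simulate_birth_death(
    params: BirthDeathParams,
    rng: Optional[np.random.Generator] = None,
    include_stem: bool = False,
    max_restarts: int = 10000,
    grace: str = "next-event",
) -> PhyloTree:
    """Simulate one birth-death tree, conditioned on reaching the stop count.

    Parameters
    ----------
    params:
        Rates, stopping count, and seed.
    rng:
        Random generator to draw from (overrides ``params.seed``); restarts
        after full extinction advance this stream rather than reseeding.
    include_stem:
        Keep the root stem (the lineage segment before the first
        speciation).  By default the returned tree is rooted at the first
        speciation so the drawing starts at a branching node.
    max_restarts:
        Cap on discarded fully-extinct runs.
    grace:
        ``"next-event"`` (default) ends the tree at the time the event
        after reaching the stop count would occur, so the final
        speciation's children get positive branch lengths (and trees
        without extinction are ultrametric with generic terminal
        branches); ``"none"`` ends it at the instant of the final
        speciation itself, leaving that pair with zero-length branches.

    Returns
    -------
    PhyloTree
        Tips are labeled t1, t2, ... in traversal order; extant tips all
        end at the stopping time, extinct tips strictly earlier.
    """
    if grace not in ("next-event", "none"):
        raise ValueError(f"unknown grace mode: {grace!r}")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    for _ in range(max_restarts + 1):
        root = _attempt(params, rng, include_stem, grace)
        if root is not None:
            tree = PhyloTree(root)
            for i, tip in enumerate(tree.tips(), start=1):
                tip.label = f"t{i}"
            return tree
    raise RuntimeError(
        f"no surviving run in {max_restarts + 1} attempts "
        f"(lambda={params.speciation_rate}, mu={params.extinction_rate})"
    )


def is_ultrametric(tree: PhyloTree, tol: float = 1e-9) -> bool:
    """True iff all root-to-tip path lengths are equal within ``tol``."""
    depth: dict[PhyloNode, float] = {}
    lo = hi = None
    for node in tree.preorder():
        d = node.length if node.parent is None else depth[node.parent] + node.length
        depth[node] = d
        if node.is_tip:
            lo = d if lo is None else min(lo, d)
            hi = d if hi is None else max(hi, d)
    assert lo is not None and hi is not None
    return hi - lo <= tol
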
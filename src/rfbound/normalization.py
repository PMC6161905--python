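"""Normalized distances.

The exact scheme divides the raw distance by the topology-aware worst case
w(T1, T2) = (m1-k1)+(m2-k2); the classic scheme divides by the global
maximum 2n-6 over all n-leaf tree pairs; the randomized scheme reproduces
the max-over-random-relabelings approximation of w that earlier software
used, mainly so its shortfall against the exact bound can be demonstrated.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Optional

from .tree_model import PhylogeneticTree, TreeStructureError
from .distances import tpd, cd, urcd, _check_comparable
from .worst_case import exact_bound

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizedDistance:
    raw: int
    bound: int
    value: Fraction  # in [0, 1]
    scheme: str  # exact | classic | randomized
    reps: Optional[int] = None
    seed: Optional[int] = None

    def __float__(self) -> float:
        return float(self.value)


def _raw(mode: str, t1: PhylogeneticTree, t2: PhylogeneticTree) -> int:
    if mode == "tpd":
        return tpd(t1, t2)
    if mode == "cd":
        return cd(t1, t2)
    if mode == "urcd":
        return urcd(t1, t2)[0]
    raise ValueError(f"unknown mode {mode!r}")


def normalized(
    t1: PhylogeneticTree, t2: PhylogeneticTree, mode: str = "tpd"
) -> NormalizedDistance:
    """Exact normalized distance raw / w(T1, T2).

    Two star topologies have raw = bound = 0; by convention the value is 0
    (they are indistinguishable at the split level).
    """
    raw = _raw(mode, t1, t2)
    bound = exact_bound(t1.topology, t2.topology, mode)
    if bound == 0:
        if raw == 0:
            logger.info("bound is 0 (both split sets empty); value 0 by convention")
            value = Fraction(0)
        else:
            # only reachable for urcd, where the formula can undershoot the
            # achievable distance by one
            logger.warning(
                "raw urcd %d exceeds zero formula bound; value 1 by convention",
                raw,
            )
            value = Fraction(1)
    else:
        value = Fraction(raw, bound)
    return NormalizedDistance(raw=raw, bound=bound, value=value, scheme="exact")


def classic_normalized(
    t1: PhylogeneticTree, t2: PhylogeneticTree
) -> NormalizedDistance:
    """Classic normalization tpd / (2n - 6), defined for n >= 4."""
    n = t1.n
    if n < 4:
        raise TreeStructureError(
            "classic normalization has divisor 2n-6 = 0 at n = 3; "
            "use the exact scheme"
        )
    raw = tpd(t1, t2)
    bound = 2 * n - 6
    return NormalizedDistance(
        raw=raw, bound=bound, value=Fraction(raw, bound), scheme="classic"
    )


def _relabeling(labeling: Dict[int, int], seed, rep: int) -> Dict[int, int]:
    # counter-based: permutation for rep r depends only on (seed, r), so the
    # max over reps is extensible without replaying earlier draws
    rng = random.Random(f"{seed}:{rep}")
    labels = sorted(labeling.values())
    shuffled = labels[:]
    rng.shuffle(shuffled)
    remap = dict(zip(labels, shuffled))
    return {leaf: remap[lab] for leaf, lab in labeling.items()}


def randomized_bound(
    t1: PhylogeneticTree,
    t2: PhylogeneticTree,
    mode: str = "tpd",
    reps: int = 1000,
    seed: Optional[int] = None,
) -> int:
    """Randomized approximation of the worst case: the maximum distance over
    ``reps`` uniform relabelings of T2's leaves (T1 fixed). Always <= the
    exact bound; can fall strictly short at small reps."""
    if mode not in ("tpd", "cd"):
        raise ValueError("randomized_bound supports modes 'tpd' and 'cd'")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    _check_comparable(t1, t2)
    best = 0
    for r in range(reps):
        shuffled = PhylogeneticTree(
            topology=t2.topology, labeling=_relabeling(t2.labeling, seed, r)
        )
        best = max(best, _raw(mode, t1, shuffled))
    return best
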
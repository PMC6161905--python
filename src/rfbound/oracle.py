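"""Exhaustive ground truth for small trees.

``brute_force_max`` fixes one tree's labeling (distances are invariant under
applying the same label permutation to both trees) and tries all n!
labelings of the other, returning the true worst case. ``sweep`` runs the
oracle against the closed-form bound and the constructive algorithm over
every pair of enumerated shapes. No automorphism pruning: at the n <= 8 cap
the plain factorial scan is cheap, and an oracle should be dumb.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .tree_model import (
    CapExceededError,
    PhylogeneticTree,
    TopologicalTree,
    enumerate_topologies,
    label_canonically,
    shape_stats,
)
from .distances import tpd, cd, urcd
from .worst_case import construct, exact_bound

ORACLE_CAP = 8


def _score(mode: str, t1: PhylogeneticTree, t2: PhylogeneticTree) -> int:
    if mode == "tpd":
        return tpd(t1, t2)
    if mode == "cd":
        return cd(t1, t2)
    if mode == "urcd":
        return urcd(t1, t2)[0]
    raise ValueError(f"unknown mode {mode!r}")


def brute_force_max(
    T1: TopologicalTree,
    T2: TopologicalTree,
    mode: str = "tpd",
    cap: int = ORACLE_CAP,
) -> Tuple[int, Tuple[Dict[int, int], Dict[int, int]]]:
    """Maximum distance over all labelings, by exhaustive enumeration.

    Returns ``(max_distance, (labeling1, labeling2))`` with one arg-max pair.
    """
    n = T1.n_leaves()
    if n != T2.n_leaves():
        raise ValueError("leaf-count mismatch")
    if n > cap:
        raise CapExceededError(f"n={n} exceeds oracle cap {cap}")

    t1 = label_canonically(T1)
    leaves2 = T2.leaves()
    best = -1
    best_lab: Optional[Dict[int, int]] = None
    for perm in itertools.permutations(range(1, n + 1)):
        lab2 = dict(zip(leaves2, perm))
        t2 = PhylogeneticTree(topology=T2, labeling=lab2)
        d = _score(mode, t1, t2)
        if d > best:
            best, best_lab = d, lab2
    return best, (dict(t1.labeling), best_lab)


@dataclass
class SweepRow:
    n: int
    shape1: int
    shape2: int
    m1: int
    k1: int
    m2: int
    k2: int
    brute: int
    formula: int
    constructed: int
    agree: bool


def sweep(
    n_max: int,
    mode: str = "tpd",
    n_min: int = 3,
    max_unifurcations: int = 0,
    cap: int = ORACLE_CAP,
) -> List[SweepRow]:
    """Oracle-vs-formula-vs-construction table over all ordered shape pairs.

    ``agree`` is True when brute max == formula == constructed distance.
    Ordered pairs are scanned (despite mathematical symmetry) to surface any
    asymmetry bug.
    """
    if n_max > cap:
        raise CapExceededError(f"n_max={n_max} exceeds oracle cap {cap}")
    rows: List[SweepRow] = []
    proper_only = max_unifurcations == 0
    for n in range(n_min, n_max + 1):
        if mode == "tpd":
            pool1 = pool2 = enumerate_topologies(
                n, rooted=False, proper_only=proper_only,
                max_unifurcations=max_unifurcations, cap=cap,
            )
        elif mode == "cd":
            pool1 = pool2 = enumerate_topologies(
                n, rooted=True, proper_only=proper_only,
                max_unifurcations=max_unifurcations, cap=cap,
            )
        elif mode == "urcd":
            pool1 = enumerate_topologies(
                n, rooted=False, proper_only=proper_only,
                max_unifurcations=max_unifurcations, cap=cap,
            )
            pool2 = enumerate_topologies(
                n, rooted=True, proper_only=proper_only,
                max_unifurcations=max_unifurcations, cap=cap,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for i1, T1 in enumerate(pool1):
            for i2, T2 in enumerate(pool2):
                s1, s2 = shape_stats(T1), shape_stats(T2)
                brute, _ = brute_force_max(T1, T2, mode, cap=cap)
                formula = exact_bound(T1, T2, mode)
                constructed = construct(T1, T2, mode).achieved
                rows.append(
                    SweepRow(
                        n=n,
                        shape1=i1,
                        shape2=i2,
                        m1=s1.m,
                        k1=s1.k,
                        m2=s2.m,
                        k2=s2.k,
                        brute=brute,
                        formula=formula,
                        constructed=constructed,
                        agree=(brute == formula == constructed),
                    )
                )
    return rows


def sweep_tsv(rows: List[SweepRow]) -> str:
    header = "n\tshape1\tshape2\tm1\tk1\tm2\tk2\tbrute\tformula\tconstructed\tagree"
    lines = [header]
    for r in rows:
        lines.append(
            f"{r.n}\t{r.shape1}\t{r.shape2}\t{r.m1}\t{r.k1}\t{r.m2}\t{r.k2}"
            f"\t{r.brute}\t{r.formula}\t{r.constructed}\t{str(r.agree).lower()}"
        )
    return "\n".join(lines)
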
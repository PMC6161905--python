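"""Robinson-Foulds-type distances.

* tpd -- tree partition distance between two unrooted trees: the size of
  the symmetric difference of their non-trivial bipartition sets.
* cd  -- cluster distance between two rooted trees: symmetric difference of
  their non-trivial cluster sets.
* urcd -- unrooted cluster distance between an unrooted tree T1 and a
  rooted tree T2: the minimum cd over all rootings of T1 (every edge of T1,
  leaf edges included, is a rooting candidate).
"""

from __future__ import annotations

from typing import Tuple

from .tree_model import Edge, PhylogeneticTree, TreeStructureError, root_on_edge
from .splits import bipartitions, clusters


class LabelMismatchError(ValueError):
    """The two trees do not carry the same label / taxon-name set."""


def _check_comparable(t1: PhylogeneticTree, t2: PhylogeneticTree) -> None:
    if set(t1.labeling.values()) != set(t2.labeling.values()):
        raise LabelMismatchError("trees carry different label sets")
    if t1.taxon_map and t2.taxon_map:
        if set(t1.taxon_map.values()) != set(t2.taxon_map.values()):
            raise LabelMismatchError("trees carry different taxon-name sets")
        # labels are assigned in lexicographic name order on parse, so equal
        # name sets imply aligned label/name pairs; guard anyway
        if t1.taxon_map != t2.taxon_map:
            raise LabelMismatchError(
                "label/taxon alignment differs between trees"
            )


def tpd(t1: PhylogeneticTree, t2: PhylogeneticTree) -> int:
    """Tree partition distance |P(T1) symmetric-difference P(T2)|."""
    if t1.topology.rooted or t2.topology.rooted:
        raise TreeStructureError("tpd requires two unrooted trees")
    _check_comparable(t1, t2)
    return len(bipartitions(t1) ^ bipartitions(t2))


def cd(t1: PhylogeneticTree, t2: PhylogeneticTree) -> int:
    """Cluster distance |Cl(T1) symmetric-difference Cl(T2)|."""
    if not (t1.topology.rooted and t2.topology.rooted):
        raise TreeStructureError("cd requires two rooted trees")
    _check_comparable(t1, t2)
    return len(clusters(t1) ^ clusters(t2))


def urcd(t1: PhylogeneticTree, t2: PhylogeneticTree) -> Tuple[int, Edge]:
    """Unrooted cluster distance: min over all rootings of T1 of the cluster
    distance to T2, plus the lexicographically smallest minimizing edge."""
    if t1.topology.rooted:
        raise TreeStructureError("urcd: first tree must be unrooted")
    if not t2.topology.rooted:
        raise TreeStructureError("urcd: second tree must be rooted")
    _check_comparable(t1, t2)
    cl2 = clusters(t2)
    best = None
    best_edge = None
    for e in t1.topology.edges():  # sorted: ties go to the smallest edge
        d = len(clusters(root_on_edge(t1, e)) ^ cl2)
        if best is None or d < best:
            best, best_edge = d, e
    return best, best_edge
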
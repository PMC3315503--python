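"""Clade-based functional classification of query tags.

Two calls are made per tag. The provisional call is simply the class of the
best database hit. The final call reads the joint phylogenetic tree: walk
from the tag's leaf toward the root to the smallest clade containing at
least one reference leaf, take the majority class of the reference leaves in
that clade, and accept it when the majority fraction reaches the support
threshold. Tags with weak support, or whose nearest reference is further (in
patristic distance) than the database's own within-class spread, are flagged
as putative novel lineages. This formalizes the manual tree inspection a
practitioner would do, while reporting support, nearest reference, and
distance so the automatic call can be audited or overridden.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Optional

import dendropy
import numpy as np

from .reference_db import taxonomy
from .search import HitRecord

DEFAULT_SUPPORT_THRESHOLD = 0.8
#: distance_threshold default: this percentile of within-class reference
#: patristic distances on the same tree
NOVELTY_DISTANCE_PERCENTILE = 95.0

UNCLASSIFIED = "unclassified"


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationResult:
    tag_id: str
    provisional_class: str
    final_class: str
    support: float
    nearest_reference_id: Optional[str]
    nearest_patristic_distance: Optional[float]
    novel_flag: bool
    secondary_metabolism: bool
    reclassified: bool = False


def classify_by_hit(hit: Optional[HitRecord], domain_type: str) -> str:
    """Provisional class = class of the best hit ('unclassified' if none)."""
    if hit is None:
        return UNCLASSIFIED
    names = {c.class_name for c in taxonomy(domain_type)}
    if hit.subject_class not in names:
        raise ClassifyError(f"hit subject class {hit.subject_class!r} not in taxonomy")
    return hit.subject_class


def _secondary_metabolism(final_class: str, domain_type: str) -> bool:
    if final_class == UNCLASSIFIED:
        return False
    for c in taxonomy(domain_type):
        if c.class_name == final_class:
            return c.secondary_metabolism
    return False


class TreeClassifier:
    """Annotates a rooted tree once, then classifies any number of tag leaves.

    ``reference_labels`` maps reference leaf label -> class name; all other
    leaves are treated as queries.
    """

    def __init__(
        self,
        rooted_tree: dendropy.Tree,
        reference_labels: dict[str, str],
        domain_type: str,
        support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
        distance_threshold: Optional[float] = None,
    ):
        self.tree = rooted_tree
        self.reference_labels = reference_labels
        self.domain_type = domain_type
        self.support_threshold = support_threshold
        self._leaves = {
            leaf.taxon.label: leaf for leaf in rooted_tree.leaf_node_iter()
        }
        missing = set(reference_labels) - set(self._leaves)
        if missing:
            raise ClassifyError(f"reference leaves missing from tree: {sorted(missing)}")
        if not reference_labels:
            raise ClassifyError("need at least one reference leaf")
        # per-node reference class counts (postorder accumulation)
        self._ref_counts: dict[int, Counter] = {}
        for node in rooted_tree.postorder_node_iter():
            counts: Counter = Counter()
            if node.is_leaf():
                lab = node.taxon.label
                if lab in reference_labels:
                    counts[reference_labels[lab]] += 1
            else:
                for child in node.child_nodes():
                    counts.update(self._ref_counts[id(child)])
            self._ref_counts[id(node)] = counts
        self._pdm = rooted_tree.phylogenetic_distance_matrix()
        self._taxa = {t.label: t for t in rooted_tree.taxon_namespace}
        if distance_threshold is None:
            distance_threshold = self._within_class_distance_percentile()
        self.distance_threshold = distance_threshold

    def _within_class_distance_percentile(self) -> float:
        by_class: dict[str, list[str]] = {}
        for lab, cls in self.reference_labels.items():
            by_class.setdefault(cls, []).append(lab)
        dists = []
        for members in by_class.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    dists.append(
                        self._pdm.patristic_distance(
                            self._taxa[members[i]], self._taxa[members[j]]
                        )
                    )
        if not dists:
            return float("inf")
        return float(np.percentile(dists, NOVELTY_DISTANCE_PERCENTILE))

    def _nearest_reference(self, tag_id: str) -> tuple[str, float]:
        t = self._taxa[tag_id]
        best = None
        for lab in sorted(self.reference_labels):
            d = self._pdm.patristic_distance(t, self._taxa[lab])
            if best is None or d < best[1]:
                best = (lab, d)
        return best

    def classify(self, tag_id: str) -> ClassificationResult:
        if tag_id not in self._leaves:
            raise ClassifyError(f"tag {tag_id!r} is not a leaf of the tree")
        node = self._leaves[tag_id]
        counts: Counter = Counter()
        while node is not None:
            counts = self._ref_counts[id(node)]
            if counts:
                break
            node = node.parent_node
        total = sum(counts.values())
        # deterministic majority: largest count, ties to alphabetical class
        cls, cnt = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        support = cnt / total
        final = cls if support >= self.support_threshold else UNCLASSIFIED
        nearest_id, nearest_d = self._nearest_reference(tag_id)
        novel = final == UNCLASSIFIED or nearest_d > self.distance_threshold
        return ClassificationResult(
            tag_id=tag_id,
            provisional_class=UNCLASSIFIED,
            final_class=final,
            support=support,
            nearest_reference_id=nearest_id,
            nearest_patristic_distance=nearest_d,
            novel_flag=novel,
            secondary_metabolism=_secondary_metabolism(final, self.domain_type),
        )


def classify_by_tree(
    rooted_tree: dendropy.Tree,
    tag_id: str,
    reference_labels: dict[str, str],
    domain_type: str,
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
    distance_threshold: Optional[float] = None,
) -> ClassificationResult:
    """One-shot wrapper around :class:`TreeClassifier` for a single tag."""
    clf = TreeClassifier(
        rooted_tree, reference_labels, domain_type, support_threshold, distance_threshold
    )
    return clf.classify(tag_id)


def reconcile(
    provisional: str, tree_result: ClassificationResult, domain_type: str
) -> ClassificationResult:
    """Final report uses the tree call; flag a reclassification when the tree
    call disagrees with a best-hit call and both are real classes."""
    reclassified = (
        provisional != UNCLASSIFIED
        and tree_result.final_class != UNCLASSIFIED
        and provisional != tree_result.final_class
    )
    return replace(
        tree_result, provisional_class=provisional, reclassified=reclassified
    )
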
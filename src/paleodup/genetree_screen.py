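"""Screening dated gene trees for duplication at the focal ancestor.

A gene tree is evidence of a duplication in the common ancestor of the
ingroup when it contains a node with exactly two ingroup-only daughter
clades, each spanning the deepest split of the ingroup -- here, each
containing at least one blue/white-fruited dogwood (BW) species and at
least one species of the BW sister clade -- with the outgroup attaching
outside both.  The age of that node dates the duplication; ages pooled
over many gene trees are fitted with the same mixture machinery used for
the Ks distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy

from . import cornus, wgd_mixture

__all__ = [
    "GeneTreeRecord",
    "DuplicationCall",
    "screen_tree",
    "outgroup_branch_filter",
    "collect_and_fit_dates",
]


@dataclass
class GeneTreeRecord:
    """A dated gene tree plus its leaf -> species mapping."""

    tree_id: str
    tree: dendropy.Tree
    species_of: dict  # leaf label -> species code

    @classmethod
    def from_newick(cls, tree_id: str, newick: str, species_of=None):
        tree = dendropy.Tree.get(data=newick, schema="newick")
        if species_of is None:
            species_of = {
                lf.taxon.label.replace(" ", "_"): lf.taxon.label.replace(" ", "_").split("_")[0]
                for lf in tree.leaf_node_iter()
            }
        return cls(tree_id=tree_id, tree=tree, species_of=species_of)


@dataclass(frozen=True)
class DuplicationCall:
    tree_id: str
    passes: bool
    age: float | None = None
    subclade_a: tuple = ()
    subclade_b: tuple = ()
    flags: tuple = ()


def _leaf_label(leaf) -> str:
    return leaf.taxon.label.replace(" ", "_")


def _node_age(node) -> float:
    """Age of a node in a chronogram = its distance down to any leaf."""
    ages = []
    for lf in node.leaf_iter():
        d = 0.0
        nd = lf
        while nd is not node:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        ages.append(d)
    return max(ages)


def _species_set(node, species_of) -> set:
    return {species_of[_leaf_label(lf)] for lf in node.leaf_iter()}


def screen_tree(
    record: GeneTreeRecord,
    ingroup=None,
    deep_group=None,
    outgroup: str = "ACH",
    min_dup_age: float | None = 68.0,
) -> DuplicationCall:
    """Apply the duplication-topology criterion to one dated gene tree.

    ``deep_group`` (default the BW dogwoods) and its ingroup complement
    define the deepest split; a passing node has two daughters that are
    ingroup-only and each contain >= 1 species from both sides.  When
    several nodes qualify, the oldest is reported (a WGD predates
    within-clade duplications).  A passing age below ``min_dup_age`` is
    flagged, not corrected.
    """
    ingroup = set(ingroup or cornus.CORNUS_SPECIES)
    deep_group = set(deep_group or cornus.BW_GROUP)
    other = ingroup - deep_group
    species_of = record.species_of

    tree_species = {species_of[_leaf_label(lf)] for lf in record.tree.leaf_node_iter()}
    if outgroup not in tree_species:
        return DuplicationCall(record.tree_id, False, flags=("no_outgroup",))
    if record.tree.seed_node.num_child_nodes() > 2 and len(tree_species) > 2:
        # an unrooted (trifurcating) tree cannot anchor the criterion
        raise ValueError(
            f"{record.tree_id}: tree appears unrooted; root on the outgroup first"
        )

    candidates = []
    for node in record.tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) != 2:
            continue
        sides = [_species_set(k, species_of) for k in kids]
        if any(not s <= ingroup for s in sides):
            continue
        if all(s & deep_group and s & other for s in sides):
            candidates.append((node, sides))
    if not candidates:
        return DuplicationCall(record.tree_id, False)

    aged = [( _node_age(node), node, sides) for node, sides in candidates]
    aged.sort(key=lambda x: -x[0])
    age, _node, sides = aged[0]
    flags = []
    if len(aged) > 1:
        flags.append("multiple_candidate_nodes")
    if min_dup_age is not None and age < min_dup_age:
        flags.append("age_below_fossil_minimum")
    return DuplicationCall(
        record.tree_id,
        True,
        age=age,
        subclade_a=tuple(sorted(sides[0])),
        subclade_b=tuple(sorted(sides[1])),
        flags=tuple(flags),
    )


def outgroup_branch_filter(
    record: GeneTreeRecord, far_outgroup: str = "DFE", factor: float = 2.0
) -> GeneTreeRecord:
    """Prune a far outgroup with an aberrantly long root-to-tip path.

    The far outgroup's leaves are removed when their tip-to-root path
    exceeds ``factor`` times the median path of the remaining taxa (strict
    inequality; exactly factor x is kept).  Other trees pass unchanged.
    """
    tree = record.tree
    far_leaves = [
        lf
        for lf in tree.leaf_node_iter()
        if record.species_of[_leaf_label(lf)] == far_outgroup
    ]
    if not far_leaves:
        return record

    def path_len(leaf):
        d = 0.0
        nd = leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        return d

    other = [
        path_len(lf)
        for lf in tree.leaf_node_iter()
        if record.species_of[_leaf_label(lf)] != far_outgroup
    ]
    if not other:
        return record
    other.sort()
    mid = len(other) // 2
    median = other[mid] if len(other) % 2 else 0.5 * (other[mid - 1] + other[mid])
    if median <= 0:
        return record
    worst = max(path_len(lf) for lf in far_leaves)
    if worst <= factor * median:
        return record

    keep = [
        lf.taxon
        for lf in tree.leaf_node_iter()
        if record.species_of[_leaf_label(lf)] != far_outgroup
    ]
    pruned = tree.extract_tree_with_taxa(taxa=keep)
    pruned.suppress_unifurcations()
    species_of = {
        lab: sp
        for lab, sp in record.species_of.items()
        if sp != far_outgroup
    }
    return GeneTreeRecord(tree_id=record.tree_id, tree=pruned, species_of=species_of)


def collect_and_fit_dates(
    calls,
    k_range=(1, 5),
    seed: int = 0,
    min_calls: int = 10,
    **fit_kwargs,
) -> wgd_mixture.MixtureFit:
    """Pool passing duplication ages and fit their distribution.

    The k range admits a single component because a clean WGD screen is
    expected to yield one age peak.  Returns the BIC-selected fit (myr
    scale); the dominant component is the one with the largest proportion.
    """
    ages = [c.age for c in calls if c.passes and c.age is not None]
    if len(ages) < min_calls:
        raise ValueError(
            f"only {len(ages)} passing duplication calls (< {min_calls})"
        )
    if max(ages) - min(ages) < 1e-9:
        warnings.warn("all duplication dates identical; degenerate fit")
    return wgd_mixture.select_model(
        ages, k_range=k_range, seed=seed, scale="myr", **fit_kwargs
    )


def dominant_component(fit: wgd_mixture.MixtureFit) -> wgd_mixture.MixtureComponent:
    return max(fit.components, key=lambda c: c.proportion)
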
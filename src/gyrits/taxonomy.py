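"""Monophyly evaluation and threshold-based species delimitation.

Trees are consumed, never inferred.  A group is monophyletic when some
edge of the (unrooted) tree bipartitions the tips exactly into the
group versus everything else; the support values annotated on that
defining edge (maximum-likelihood bootstrap percentage ``bp`` and/or
Bayesian posterior probability ``pp``) decide whether the group is
"well supported".  Candidate species are delimited on a p-distance
matrix by single-linkage clustering at a threshold (default 1.3%,
the species-level divergence conventional for gyrodactylid ITS):
sequences stay in one cluster iff they are connected by a chain of
pairwise distances less than or equal to the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import pandas as pd

from .distances import DistanceMatrix, group_distance_summary

DEFAULT_BP_MIN = 75.0
DEFAULT_PP_MIN = 0.95
SPECIES_THRESHOLD = 0.013


def parse_support_label(label, support_format: str = "auto"):
    """Split a node label into (bp, pp).

    Compound ``"99/1.0"`` labels carry bootstrap then posterior; a bare
    number is interpreted by magnitude under ``auto`` (values > 1 are
    bootstrap percentages), or forced with ``support_format`` ``"bp"``
    or ``"pp"``.
    """
    if label is None or label == "":
        return None, None
    label = str(label)
    if "/" in label:
        left, right = label.split("/", 1)
        try:
            return float(left), float(right)
        except ValueError:
            return None, None
    try:
        val = float(label)
    except ValueError:
        return None, None
    if support_format == "bp":
        return val, None
    if support_format == "pp":
        return None, val
    return (val, None) if val > 1.0 else (None, val)


class TreeView:
    """A support-annotated tree with optional designated outgroup tips."""

    def __init__(self, tree: dendropy.Tree, outgroup=(),
                 support_format: str = "auto"):
        self.tree = tree
        self.outgroup = frozenset(outgroup)
        self.support_format = support_format
        self._tips = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        if len(self._tips) != sum(1 for _ in tree.leaf_node_iter()):
            raise ValueError("duplicate tip labels")
        unknown = self.outgroup - self._tips
        if unknown:
            raise ValueError(f"outgroup tips not in tree: {sorted(unknown)}")

    @classmethod
    def from_newick(cls, source: str, outgroup=(), support_format="auto"):
        """Parse a Newick string (or path ending in .nwk/.tre/.tree)."""
        import os
        if os.path.exists(source):
            tree = dendropy.Tree.get(path=source, schema="newick",
                                     preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(data=source, schema="newick",
                                     preserve_underscores=True)
        return cls(tree, outgroup, support_format)

    @property
    def tips(self) -> frozenset:
        return self._tips

    def node_support(self, node):
        return parse_support_label(node.label, self.support_format)

    def _clades(self):
        """(node, frozenset of tip labels below node) for internal nodes."""
        below = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                below[node] = frozenset([node.taxon.label])
            else:
                s = frozenset()
                for ch in node.child_nodes():
                    s |= below[ch]
                below[node] = s
        return below


def is_monophyletic(tree: TreeView, tipset):
    """Does some edge bipartition the tips exactly into tipset vs rest?

    The test is unrooted: a group matching either side of an edge's
    bipartition is monophyletic.  When an outgroup is designated, the
    group must lie on the ingroup side (a "group" containing outgroup
    tips alongside ingroup tips is rejected).  Returns ``(bool, node)``
    where ``node`` is the child node of the defining edge (carrying its
    support label), or ``None``.
    """
    tipset = frozenset(tipset)
    unknown = tipset - tree.tips
    if unknown:
        raise ValueError(f"unknown tips: {sorted(unknown)}")
    if not tipset:
        raise ValueError("empty tipset")
    if tree.outgroup and tipset & tree.outgroup and tipset != tree.tips:
        if not tipset <= tree.outgroup:
            return False, None
    if tipset == tree.tips:
        return True, self_root(tree)
    below = tree._clades()
    complement = tree.tips - tipset
    complement_match = None
    for node, clade in below.items():
        if node is tree.tree.seed_node:
            continue
        if clade == tipset:
            # the node subtending the group carries the edge's support label
            return True, node
        if clade == complement and complement_match is None:
            complement_match = node
    if complement_match is not None:
        return True, complement_match
    return False, None


def self_root(tree: TreeView):
    return tree.tree.seed_node


@dataclass
class MonophylyResult:
    group: str
    status: str                      # monophyletic | non-monophyletic | singleton
    bp: float | None = None
    pp: float | None = None
    well_supported: bool = False
    uninformative: bool = False      # group == all tips
    offending_tips: tuple = ()


def _offending_tips(tree: TreeView, tipset):
    """Tips inside the smallest clade spanning the group but not in it."""
    taxa = [tree.tree.taxon_namespace.get_taxon(t) for t in tipset]
    tree.tree.is_rooted = True  # MRCA is taken relative to the seed node
    mrca = tree.tree.mrca(taxa=[t for t in taxa if t is not None])
    if mrca is None:
        return ()
    spanned = {lf.taxon.label for lf in mrca.leaf_iter()}
    return tuple(sorted(spanned - set(tipset)))


def evaluate_groups(tree: TreeView, groups: dict,
                    bp_min: float = DEFAULT_BP_MIN,
                    pp_min: float = DEFAULT_PP_MIN):
    """One MonophylyResult per group label in ``groups`` (tip -> group).

    A group is well supported iff it is monophyletic and its defining
    edge meets every *available* support threshold; a support type
    absent from the tree is ignored (with a note in the result).
    """
    by_group = {}
    for tip, g in groups.items():
        if not g:
            raise ValueError(f"empty group label for tip {tip}")
        by_group.setdefault(g, set()).add(tip)
    results = []
    for g in sorted(by_group):
        tipset = by_group[g]
        missing = tipset - tree.tips
        if missing:
            raise ValueError(f"group {g} has tips absent from tree: {sorted(missing)}")
        if len(tipset) == 1:
            results.append(MonophylyResult(g, "singleton"))
            continue
        mono, node = is_monophyletic(tree, tipset)
        if not mono:
            results.append(MonophylyResult(
                g, "non-monophyletic",
                offending_tips=_offending_tips(tree, tipset)))
            continue
        bp, pp = (tree.node_support(node) if node is not None else (None, None))
        checks = [ok for ok, present in
                  ((bp is not None and bp >= bp_min, bp is not None),
                   (pp is not None and pp >= pp_min, pp is not None))
                  if present]
        well = bool(checks) and all(checks)
        results.append(MonophylyResult(
            g, "monophyletic", bp=bp, pp=pp, well_supported=well,
            uninformative=(tipset == tree.tips)))
    return results


# ---------------------------------------------------------------------------
# species delimitation


def delimit_species(dm: DistanceMatrix, threshold: float = SPECIES_THRESHOLD,
                    allow_ml: bool = False):
    """Single-linkage clusters of ids at a p-distance threshold.

    Two ids share a cluster iff a chain of pairwise distances
    <= ``threshold`` connects them; a pair just above the threshold
    (e.g. 0.014 at the default 0.013) therefore splits.  Clusters are
    labelled by their lexicographically smallest member.  ML-scale
    matrices are rejected unless ``allow_ml`` is set, since the
    threshold is calibrated on the proportion scale.
    """
    if dm.method == "ml" and not allow_ml:
        raise ValueError("threshold is on the p-distance scale; "
                         "pass allow_ml=True to override")
    ids = list(dm.ids)
    parent = list(range(len(ids)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if dm.matrix[i, j] <= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    clusters = {}
    for i, name in enumerate(ids):
        clusters.setdefault(find(i), []).append(name)
    out = {}
    for members in clusters.values():
        members = sorted(members)
        out[members[0]] = members
    return out


def lineage_report(tree: TreeView, groups: dict, dm: DistanceMatrix,
                   bp_min: float = DEFAULT_BP_MIN,
                   pp_min: float = DEFAULT_PP_MIN):
    """Combined per-group monophyly + distance summary.

    Returns ``(table, inter_table)``: per group its monophyly status,
    defining-edge support and intra-group mean distance; per group pair
    the inter-group mean.  Output is invariant to tip input order.
    """
    results = evaluate_groups(tree, groups, bp_min, pp_min)
    intra, inter = group_distance_summary(dm, groups)
    rows = []
    for r in results:
        rows.append({
            "group": r.group, "status": r.status,
            "bp": r.bp, "pp": r.pp,
            "well_supported": r.well_supported,
            "offending_tips": ";".join(r.offending_tips),
            "intra_mean_distance": (round(intra[r.group], 4)
                                    if r.group in intra else None),
        })
    table = pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
    inter_rows = [{"group_1": a, "group_2": b,
                   "inter_mean_distance": round(v, 4)}
                  for (a, b), v in sorted((tuple(sorted(k)), v)
                                          for k, v in inter.items())]
    inter_table = pd.DataFrame(inter_rows)
    return table, inter_table
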
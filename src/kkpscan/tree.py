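"""Outgroup rooting and clade annotation of an externally built kinase tree.

Tree inference itself (alignment, trimming, maximum likelihood search) is
out of scope; this module consumes a Newick tree of PfkA-like kinases,
reroots it on a configured outgroup (e.g. three eukaryotic Ser/Thr
kinases), and labels the broad clades from user-supplied reference leaves:
each reference set is extended to the maximal subtree containing no other
clade's references and no outgroup leaf.
"""

from __future__ import annotations

from typing import Iterable, Union

import dendropy

CLADE_OUTGROUP = "outgroup"
CLADE_UNASSIGNED = "unassigned"


class MonophylyError(ValueError):
    """Reference leaves of different clades are nested within one another."""


def _load(tree: Union[str, dendropy.Tree]) -> dendropy.Tree:
    if not isinstance(tree, dendropy.Tree):
        if "(" in tree:
            tree = dendropy.Tree.get(data=tree, schema="newick")
        else:
            tree = dendropy.Tree.get(path=tree, schema="newick")
    tree.is_rooted = True
    return tree


def _leaf_names(node) -> set[str]:
    return {lf.taxon.label for lf in node.leaf_iter()}


def reroot_on_outgroup(tree: Union[str, dendropy.Tree],
                       outgroup_leaves: Iterable[str]) -> dendropy.Tree:
    """Reroot on the edge above the smallest clade holding all outgroup
    leaves; preserves the leaf set and every unrooted bipartition."""
    tree = _load(tree)
    outgroup = set(outgroup_leaves)
    names = {t.label for t in tree.taxon_namespace}
    missing = outgroup - names
    if missing:
        raise KeyError(f"outgroup leaves absent from tree: {sorted(missing)}")
    if names == outgroup:
        return tree
    node = tree.mrca(taxa=[t for t in tree.taxon_namespace
                           if t.label in outgroup])
    if node is tree.seed_node:
        # outgroup straddles the current root: root on the ingroup side
        node = tree.mrca(taxa=[t for t in tree.taxon_namespace
                               if t.label not in outgroup])
        if node is tree.seed_node:
            raise MonophylyError(
                "outgroup is not separable from the ingroup on this topology"
            )
    length = node.edge.length
    tree.reroot_at_edge(
        node.edge,
        length1=None if length is None else length / 2.0,
        length2=None if length is None else length / 2.0,
        update_bipartitions=False,
    )
    return tree


def annotate_tree(
    tree: Union[str, dendropy.Tree],
    outgroup_leaves: Iterable[str],
    clade_reference_leaves: dict[str, Iterable[str]],
) -> dict[str, str]:
    """Reroot on the outgroup and assign each leaf a clade label.

    ``clade_reference_leaves`` maps a clade label (e.g. ``'I'``, ``'II'``,
    ``'III'``) to one or more reference leaf names.  Each clade becomes the
    maximal subtree that contains all its references but no other clade's
    references and no outgroup leaf.  Leaves outside every clade are
    ``'unassigned'``; outgroup leaves are exactly the configured set.
    """
    outgroup = set(outgroup_leaves)
    refs = {label: set(leaves) for label, leaves in
            clade_reference_leaves.items()}
    tree = reroot_on_outgroup(tree, outgroup)
    all_names = {t.label for t in tree.taxon_namespace}
    for label, leaves in refs.items():
        missing = leaves - all_names
        if missing:
            raise KeyError(
                f"clade {label!r} reference leaves absent: {sorted(missing)}"
            )
        overlap = leaves & outgroup
        if overlap:
            raise ValueError(
                f"clade {label!r} references overlap the outgroup: "
                f"{sorted(overlap)}"
            )

    assignment = {name: CLADE_UNASSIGNED for name in all_names}
    for name in outgroup:
        assignment[name] = CLADE_OUTGROUP

    foreign = {label: outgroup.union(*(r for l, r in refs.items() if l != label))
               for label in refs}
    for label in sorted(refs):
        node = tree.mrca(taxa=[t for t in tree.taxon_namespace
                               if t.label in refs[label]])
        leaves = _leaf_names(node)
        bad = leaves & (foreign[label] - outgroup)
        if bad:
            raise MonophylyError(
                f"clade {label!r} references are nested with other clades' "
                f"references: {sorted(bad)}"
            )
        if leaves & outgroup:
            raise MonophylyError(
                f"clade {label!r} references span the outgroup: "
                f"{sorted(leaves & outgroup)}"
            )
        while node.parent_node is not None:
            parent_leaves = _leaf_names(node.parent_node)
            if parent_leaves & foreign[label]:
                break
            node = node.parent_node
        for name in _leaf_names(node):
            assignment[name] = label
    return assignment


def assignment_to_itol(assignment: dict[str, str],
                       colors: dict[str, str] | None = None) -> str:
    """Render a clade assignment as an iTOL DATASET_COLORSTRIP block."""
    palette = colors or {
        "I": "#1b9e77", "II": "#d95f02", "III": "#7570b3",
        CLADE_OUTGROUP: "#666666", CLADE_UNASSIGNED: "#cccccc",
    }
    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        "DATASET_LABEL\tKKP clades",
        "COLOR\t#000000",
        "DATA",
    ]
    for leaf in sorted(assignment):
        clade = assignment[leaf]
        lines.append(f"{leaf}\t{palette.get(clade, '#cccccc')}\t{clade}")
    return "\n".join(lines) + "\n"
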
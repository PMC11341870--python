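"""Protein-identity family grouping of KKP clusters.

Clusters whose component proteins (PfkA-like, PfkB-like, PfpC-like) are
highly similar — by default a mean-of-three pairwise amino-acid identity
above 90% — are grouped into families by single linkage, which is how
horizontally transferred, near-identical modules surface as one family
across distant hosts.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .align import global_align_affine, percent_identity
from .model import Family

PROTEIN_GAP_OPEN = -10.0
PROTEIN_GAP_EXTEND = -1.0
DEFAULT_THRESHOLD = 90.0
COMPONENTS = ("pfkA", "pfkB", "pfpC")


def pairwise_protein_identity(
    a: str,
    b: str,
    denominator: str = "columns",
) -> float:
    """Percent amino-acid identity from a global BLOSUM62 affine-gap
    alignment.  Default denominator is alignment columns (gap columns count
    against identity); ``denominator='shorter'`` divides by the shorter
    ungapped length instead."""
    if not a or not b:
        raise ValueError("protein sequences must be non-empty")
    # canonical pair order: tie-broken gap placement can otherwise give
    # marginally different column counts for (a, b) vs (b, a)
    if b < a:
        a, b = b, a
    res = global_align_affine(
        a, b, gap_open=PROTEIN_GAP_OPEN, gap_extend=PROTEIN_GAP_EXTEND,
        band=-1, alphabet="protein",
    )
    return percent_identity(res, denominator)


def identity_matrix(
    proteins: dict[str, dict[str, str]],
    denominator: str = "columns",
) -> pd.DataFrame:
    """Long-form component-wise identity table over all cluster pairs.

    ``proteins`` maps cluster_id -> {component -> sequence} with components
    pfkA/pfkB/pfpC.  Returns one row per unordered pair with the three
    component identities and their mean; the diagonal is implicit (100).
    """
    ids = sorted(proteins)
    rows = []
    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            comp = {}
            for c in COMPONENTS:
                sa, sb = proteins[ci].get(c), proteins[cj].get(c)
                comp[c] = (pairwise_protein_identity(sa, sb, denominator)
                           if sa and sb else np.nan)
            vals = [v for v in comp.values() if not np.isnan(v)]
            rows.append({
                "cluster_a": ci, "cluster_b": cj,
                **{f"identity_{c}": comp[c] for c in COMPONENTS},
                "identity_mean": float(np.mean(vals)) if vals else np.nan,
                "identity_min": float(np.min(vals)) if vals else np.nan,
            })
    return pd.DataFrame(rows, columns=[
        "cluster_a", "cluster_b",
        *[f"identity_{c}" for c in COMPONENTS],
        "identity_mean", "identity_min",
    ])


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def cluster_families(
    matrix: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    linkage_stat: str = "identity_mean",
    member_lengths: Optional[dict[str, int]] = None,
) -> list[Family]:
    """Single-linkage families: connected components of the graph with an
    edge wherever ``linkage_stat`` (mean of the three component identities
    by default, or ``identity_min``) exceeds ``threshold``.

    Families are numbered deterministically by their smallest member id;
    the representative is the member with the longest total protein length
    (``member_lengths``), ties broken by id.
    """
    members = sorted(set(matrix["cluster_a"]) | set(matrix["cluster_b"]))
    uf = _UnionFind(members)
    for _, row in matrix.iterrows():
        if row[linkage_stat] > threshold:
            uf.union(row["cluster_a"], row["cluster_b"])
    groups: dict[str, list[str]] = {}
    for m in members:
        groups.setdefault(uf.find(m), []).append(m)
    families = []
    for i, root in enumerate(sorted(groups), 1):
        mem = sorted(groups[root])
        if member_lengths:
            rep = max(mem, key=lambda m: (member_lengths.get(m, 0), ),
                      default=mem[0])
            # longest total aa wins; ties resolved by smallest id
            best = max(member_lengths.get(m, 0) for m in mem)
            rep = min(m for m in mem if member_lengths.get(m, 0) == best)
        else:
            rep = mem[0]
        families.append(Family(family_id=f"F{i:04d}", members=mem,
                               representative=rep))
    return families


def families_to_frame(families: list[Family]) -> pd.DataFrame:
    rows = [
        {"family_id": f.family_id, "cluster_id": m,
         "representative": str(m == f.representative)}
        for f in families for m in f.members
    ]
    return pd.DataFrame(rows, columns=["family_id", "cluster_id",
                                       "representative"])
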
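"""Random clade extraction and primary/secondary node matching.

Clade replicates are internal nodes of the primary tree subtending at least
a minimum number of tips, sampled uniformly without replacement (distinct
clade roots; nesting/overlap is permitted — disjointness is impossible in
general).  Because topology is fixed everywhere, nodes are matched across
analyses by their frozen descendant-tip sets, which is a bijection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dating import NodeSummary
from .seqsim import Alignment
from .treesim import TimeTree

__all__ = ["CladeReplicate", "extract_random_clades", "restrict_alignment", "match_nodes"]


@dataclass
class CladeReplicate:
    """One secondary-study replicate: a clade of the primary tree."""

    replicate_id: int
    root_key: frozenset
    subtree: TimeTree  # true ages, original time scale
    n_tips: int
    primary_root: NodeSummary | None = None  # primary-posterior summary of the clade root


def extract_random_clades(
    tree: TimeTree, n_clades: int, min_tips: int, seed,
    primary_summaries: dict | None = None,
) -> list[CladeReplicate]:
    """Sample ``n_clades`` distinct clade roots with >= ``min_tips`` tips.

    Eligibility is over all internal nodes (root included); sampling is
    uniform without replacement.  When ``primary_summaries`` (a mapping
    ``clade key -> NodeSummary``) is given, each replicate carries the
    primary posterior summary of its root.
    """
    eligible = [v for v in tree.internal_nodes if len(tree.clades[v]) >= min_tips]
    if len(eligible) < n_clades:
        raise ValueError(
            f"only {len(eligible)} clades with >= {min_tips} tips are available, "
            f"need {n_clades}"
        )
    rng = np.random.default_rng(seed)
    # sample over keys sorted deterministically, so the draw does not depend
    # on internal traversal/indexing order
    eligible = sorted(eligible, key=lambda v: (len(tree.clades[v]), min(tree.clades[v])))
    chosen = rng.choice(len(eligible), size=n_clades, replace=False)
    out = []
    for rid, idx in enumerate(chosen):
        v = int(eligible[int(idx)])
        key = tree.clades[v]
        sub = tree.subtree(v)
        out.append(
            CladeReplicate(
                replicate_id=rid,
                root_key=key,
                subtree=sub,
                n_tips=sub.n_tips,
                primary_root=None if primary_summaries is None else primary_summaries[key],
            )
        )
    return out


def restrict_alignment(alignment: Alignment, tip_set) -> Alignment:
    """Rows for exactly ``tip_set`` (sorted order), all sites retained."""
    missing = set(tip_set) - set(alignment.labels)
    if missing:
        raise ValueError(f"taxa not in alignment: {sorted(missing)}")
    labels = sorted(tip_set)
    return alignment.restrict(labels)


def match_nodes(primary_summaries: dict, secondary_summaries: dict) -> list[tuple]:
    """Pair each secondary node summary with its primary counterpart.

    Both arguments map clade keys to :class:`NodeSummary`.  Returns
    ``[(primary, secondary), ...]``, one pair per secondary node, in a
    deterministic (sorted-key) order.  A secondary key absent from the
    primary mapping indicates topology drift and is an error.
    """
    pairs = []
    for key in sorted(secondary_summaries, key=lambda k: (len(k), sorted(k))):
        if key not in primary_summaries:
            raise ValueError(f"secondary clade has no primary counterpart: {sorted(key)[:4]}")
        pairs.append((primary_summaries[key], secondary_summaries[key]))
    return pairs
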
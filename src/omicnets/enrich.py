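"""Pathway overrepresentation analysis: GMT gene-set I/O, hypergeometric
tests with sample odds ratios and BH FDR, and collapsing of leaf pathways
into their depth-1 "slim" parent terms to reduce the number of tested,
overlapping sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeometric_ora",
    "collapse_to_parents",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Gene sets keyed by set id, each a (name, frozen member set) pair,
    with an optional acyclic child -> parent map over set ids."""

    sets: dict[str, tuple[str, frozenset[str]]]
    parents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sid, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {sid!r} has no members")
        # reject cycles in the parent map
        for start in self.parents:
            node, hops = start, 0
            while node in self.parents:
                node = self.parents[node]
                hops += 1
                if hops > len(self.parents):
                    raise ValueError("parent map contains a cycle")

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (one set per line: id, description, members,
    tab-separated). Duplicate members within a set are stored once with a
    warning; a line with fewer than 3 fields is a parse error."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sid, desc, members = fields[0], fields[1], fields[2:]
            if len(set(members)) < len(members):
                log.warning("%s:%d: duplicate members in set %s deduplicated",
                            path, lineno, sid)
            sets[sid] = (desc, frozenset(members))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write a collection to GMT (members in sorted order for stable
    round-trips)."""
    with open(path, "w") as fh:
        for sid in collection.sets:
            desc, members = collection.sets[sid]
            fh.write("\t".join([sid, desc, *sorted(members)]) + "\n")


def hypergeometric_ora(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Overrepresentation of ``query`` in each gene set against ``universe``.

    Sets are intersected with the universe first. For overlap ``k``, set size
    ``K``, query size ``n`` and universe size ``N``, the p-value is the upper
    hypergeometric tail ``P(X >= k)``; the odds ratio is the sample
    (cross-product) OR of the 2x2 table with Haldane 0.5 correction on zero
    cells. Sets with ``k < min_overlap`` are excluded from the BH family.
    Returns a table sorted by q then p."""
    if not query:
        raise ValueError("query must not be empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_u, n_q = len(universe), len(query)
    rows = []
    for sid in collection.sets:
        name, members = collection.sets[sid]
        inter = members & universe
        if not inter:
            continue
        k = len(inter & query)
        big_k = len(inter)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_u, big_k, n_q))
        a, b = k, n_q - k
        c, d = big_k - k, n_u - n_q - (big_k - k)
        if min(a, b, c, d) == 0:
            a, b, c, d = (x + 0.5 for x in (a, b, c, d))
        rows.append((sid, name, k, big_k, n_q, n_u, (a * d) / (b * c), p))
    out = pd.DataFrame(
        rows,
        columns=["set_id", "name", "k", "K", "n", "N", "odds_ratio", "p"],
    ).set_index("set_id")
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["q", "p"])
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def collapse_to_parents(collection: GeneSetCollection) -> GeneSetCollection:
    """Collapse each set into its top-level parent term ("slim" sets).

    Every set's members are merged into its top-most ancestor in the
    child -> parent map (sets with no parent stand for themselves), so the
    many small leaf pathways disappear into broad parent terms and no set in
    the output has a parent in the output. An ancestor referenced by the
    parent map but absent from the collection is an error naming the node."""
    if not collection.parents:
        return GeneSetCollection(sets=dict(collection.sets))

    def top_ancestor(sid: str) -> str:
        node = sid
        while node in collection.parents:
            node = collection.parents[node]
        return node

    merged: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for sid, (name, members) in collection.sets.items():
        target = top_ancestor(sid)
        if target not in collection.sets:
            raise ValueError(f"ancestor {target!r} of {sid!r} is not in the collection")
        merged.setdefault(target, set()).update(members)
        names.setdefault(target, collection.sets[target][0])
    out_sets = {
        sid: (names[sid], frozenset(members)) for sid, members in merged.items()
    }
    for sid in out_sets:
        assert collection.parents.get(sid) not in out_sets
    return GeneSetCollection(sets=out_sets)
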
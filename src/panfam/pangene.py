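"""Cross-cultivar ortho-grouping and core/dispensable/unique classification.

Family members from different cultivars are paired by reciprocal best hits
(RBH) on local-alignment score, the RBH graph is clustered by single-linkage
connected components (split so that each cultivar contributes at most one
member per group), and each group is classified by its presence count:
present in all n cultivars -> core, in exactly one -> unique, otherwise
dispensable. Groups are numbered by the median chromosomal rank of their
members, so shared groups get stable family-wide numbers.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .align import local_score, smith_waterman
from .family_scan import FamilyMember


@dataclass
class OrthoGroup:
    """A cross-cultivar cluster with its presence vector and pan-class."""

    group_id: str
    members: list[tuple[str, str]]  # (cultivar, member name)
    presence: dict[str, bool] = field(default_factory=dict)
    pan_class: str = ""

    @property
    def presence_count(self) -> int:
        return sum(self.presence.values())


def reciprocal_best_hits(proteome_a: Mapping[str, str], proteome_b: Mapping[str, str],
                         scoring=None) -> list[tuple[str, str]]:
    """RBH pairs between two proteomes on Smith–Waterman score.

    (a, b) is kept iff b is a's best-scoring hit in B and a is b's best in A;
    score ties are broken by alignment identity, then by id. Either proteome
    empty yields an empty list.
    """
    if not proteome_a or not proteome_b:
        return []
    scores: dict[tuple[str, str], tuple[float, float]] = {}
    for ida, sa in proteome_a.items():
        for idb, sb in proteome_b.items():
            aln = smith_waterman(sa, sb, scoring=scoring)
            scores[(ida, idb)] = (aln.score, aln.identity)

    def best_partner(own: str, others: Sequence[str], forward: bool) -> str:
        def key(o):
            s = scores[(own, o)] if forward else scores[(o, own)]
            return (-s[0], -s[1], o)
        return min(others, key=key)

    b_ids, a_ids = list(proteome_b), list(proteome_a)
    pairs = []
    for ida in a_ids:
        idb = best_partner(ida, b_ids, forward=True)
        if best_partner(idb, a_ids, forward=False) == ida:
            pairs.append((ida, idb))
    return pairs


def build_orthogroups(members: Mapping[str, list[FamilyMember]],
                      rbh_pairs: Mapping[tuple[str, str], list[tuple[str, str]]],
                      cultivars: Sequence[str] | None = None) -> list[OrthoGroup]:
    """Single-linkage components of the RBH graph over all cultivar pairs.

    ``members`` maps cultivar -> FamilyMember list (member names are node ids,
    unique across cultivars); ``rbh_pairs`` maps (cultivarA, cultivarB) ->
    RBH name pairs. A component with two members from one cultivar is split
    greedily: nodes are re-assigned so each cultivar appears at most once per
    group, extra members seeding new groups.
    """
    cultivars = list(cultivars or members.keys())
    owner = {m.name: cv for cv, ms in members.items() for m in ms}
    rank: dict[str, int] = {}
    for cv, ms in members.items():
        for i, m in enumerate(sorted(ms, key=lambda m: m.gene.sort_key())):
            rank[m.name] = i + 1

    parent = {name: name for name in owner}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for pairs in rbh_pairs.values():
        for a, b in pairs:
            # guard the one-member-per-cultivar invariant at link time
            comp_a = {n for n in owner if find(n) == find(a)}
            cultivars_b = {owner[n] for n in owner if find(n) == find(b)}
            if {owner[n] for n in comp_a} & cultivars_b:
                continue
            union(a, b)

    components: dict[str, list[str]] = {}
    for name in owner:
        components.setdefault(find(name), []).append(name)

    groups = []
    for names in components.values():
        med = statistics.median(rank[n] for n in names)
        groups.append((med, sorted(names)))
    groups.sort(key=lambda t: (t[0], t[1]))
    out = []
    for k, (_, names) in enumerate(groups, start=1):
        presence = {cv: False for cv in cultivars}
        for n in names:
            presence[owner[n]] = True
        out.append(OrthoGroup(
            group_id=f"FAM{k}",
            members=sorted((owner[n], n) for n in names),
            presence=presence,
        ))
    return out


def classify_pan(groups: list[OrthoGroup], n_cultivars: int) -> list[OrthoGroup]:
    """Label each group core (present in all), unique (exactly one) or
    dispensable (anything in between). Order of cultivars is irrelevant."""
    if n_cultivars < 2:
        raise ValueError("pan-classification requires at least 2 cultivars")
    for g in groups:
        count = g.presence_count
        if count == 0:
            raise ValueError(f"group {g.group_id} has no members")
        if count == n_cultivars:
            g.pan_class = "core"
        elif count == 1:
            g.pan_class = "unique"
        else:
            g.pan_class = "dispensable"
    return groups


def classify_presence_pattern(presence: Mapping[str, Sequence[bool]],
                              n_cultivars: int) -> dict[str, str]:
    """Classify a raw presence/absence pattern (group id -> presence flags)."""
    out = {}
    for gid, flags in presence.items():
        g = OrthoGroup(group_id=gid, members=[],
                       presence={str(i): bool(v) for i, v in enumerate(flags)})
        classify_pan([g], n_cultivars)
        out[gid] = g.pan_class
    return out


def pan_class_counts(groups: list[OrthoGroup]) -> dict[str, int]:
    counts = {"core": 0, "dispensable": 0, "unique": 0}
    for g in groups:
        counts[g.pan_class] += 1
    return counts


def orthogroups_table(groups: list[OrthoGroup], cultivars: Sequence[str]) -> pd.DataFrame:
    """TSV-ready table: group_id, pan_class, one column per cultivar."""
    rows = []
    for g in groups:
        row = {"group_id": g.group_id, "pan_class": g.pan_class}
        named = dict(g.members)
        for cv in cultivars:
            row[cv] = named.get(cv, "-")
        rows.append(row)
    return pd.DataFrame(rows, columns=["group_id", "pan_class", *cultivars])
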
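"""Novel-clade discovery from sharing patterns of off-tree derived variants.

Derived variants with no branch on the reference haplotree are grouped by
compatible carrier sets into new clades, ordered into a nested (perfect
phylogeny) hierarchy, and grafted onto the tree below the carriers' shared
terminal haplogroup.  This is the procedure that turns "nine SNPs shared by
three samples and absent from the database" into a named branch.

The Y chromosome does not recombine, so in the absence of recurrent mutation
every variant marks one clade and carrier sets must be pairwise nested or
disjoint.  Missing data is pervasive at ancient-DNA coverage: an unknown
('?') state is a joker that never vetoes clade membership — only a confident
ancestral call inside a candidate clade conflicts with it.  Recurrent
mutation, if present, is resolved defensively by greedily dropping the
fewest-carrier variants until the remainder is compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import pandas as pd

from .haplotree import HaploTree, Variant
from .observations import GenotypeMatrix
from .placement import Placement

__all__ = [
    "NovelVariant",
    "Clade",
    "CladePartition",
    "collect_novel_variants",
    "partition_clades",
    "attach_clades",
    "four_gamete_check",
]


@dataclass(frozen=True)
class NovelVariant:
    """An off-tree derived variant and the cohort partition it induces."""

    variant: Variant
    carriers: FrozenSet[str]
    noncarriers: FrozenSet[str]
    unknown: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError(f"novel variant {self.variant} has no carriers")
        if (self.carriers & self.noncarriers) or (self.carriers & self.unknown) \
                or (self.noncarriers & self.unknown):
            raise ValueError("carrier/noncarrier/unknown sets must be disjoint")


@dataclass
class Clade:
    """One inferred clade: member samples and the variants supporting it."""

    name: str
    parent: Optional[str]  # parent clade name, or None for top-level
    members: FrozenSet[str]
    variants: List[NovelVariant] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


@dataclass
class CladePartition:
    clades: List[Clade] = field(default_factory=list)
    dropped_variants: List[Tuple[NovelVariant, str]] = field(default_factory=list)

    def is_laminar(self) -> bool:
        """Pairwise nested-or-disjoint membership over all clades."""
        for i, a in enumerate(self.clades):
            for b in self.clades[i + 1:]:
                inter = a.members & b.members
                if inter and not (a.members <= b.members or b.members <= a.members):
                    return False
        return True

    def report(self) -> pd.DataFrame:
        rows = []
        for c in self.clades:
            rows.append(
                {
                    "name": c.name,
                    "parent": c.parent or "-",
                    "n_members": c.n_members,
                    "members": ",".join(sorted(c.members)),
                    "n_variants": c.n_variants,
                    "variants": ",".join(
                        "/".join(v.variant.names) for v in c.variants
                    ),
                }
            )
        return pd.DataFrame(rows)


def collect_novel_variants(matrix: GenotypeMatrix, tree: HaploTree) -> List[NovelVariant]:
    """Variants in the matrix that are derived somewhere and absent from the tree.

    Absence is keyed on (chrom, pos, der): a site on the tree whose derived
    allele differs would still be novel, but a tree variant is never re-discovered.
    """
    tree_keys = {v.key for v in tree.variants()}
    out: List[NovelVariant] = []
    samples = matrix.samples
    for col_idx, v in enumerate(matrix.variants):
        if v.key in tree_keys:
            continue
        column = matrix.table.iloc[:, col_idx]
        carriers = frozenset(s for s, c in zip(samples, column) if c == "1")
        if not carriers:
            continue
        noncarriers = frozenset(s for s, c in zip(samples, column) if c == "0")
        unknown = frozenset(samples) - carriers - noncarriers
        out.append(NovelVariant(v, carriers, noncarriers, unknown))
    return out


def _incompatible(a: NovelVariant, b: NovelVariant) -> bool:
    """Rooted three-gamete test over confident states.

    With the ancestral state known, two characters are incompatible when
    samples exist carrying (1,1), (1,0) and (0,1): the carrier sets then
    overlap without nesting.
    """
    return bool(
        (a.carriers & b.carriers)
        and (a.carriers & b.noncarriers)
        and (b.carriers & a.noncarriers)
    )


def _drop_for_compatibility(
    variants: List[NovelVariant],
) -> Tuple[List[NovelVariant], List[Tuple[NovelVariant, str]]]:
    """Greedily drop fewest-carrier variants until no incompatible pair remains."""
    kept = list(variants)
    dropped: List[Tuple[NovelVariant, str]] = []
    while True:
        conflict_counts = {i: 0 for i in range(len(kept))}
        any_conflict = False
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                if _incompatible(kept[i], kept[j]):
                    conflict_counts[i] += 1
                    conflict_counts[j] += 1
                    any_conflict = True
        if not any_conflict:
            return kept, dropped
        # among variants in >=1 conflict, drop the one with fewest carriers
        # (recurrent mutations look private); ties broken by position.
        worst = min(
            (i for i, c in conflict_counts.items() if c > 0),
            key=lambda i: (len(kept[i].carriers), -conflict_counts[i], kept[i].variant.pos),
        )
        dropped.append((kept[worst], "incompatible"))
        kept.pop(worst)


def partition_clades(
    novel_variants: Sequence[NovelVariant], min_support: int = 1
) -> CladePartition:
    """Group compatible variants into nested clades.

    Two variants support the same clade when neither has a confident carrier
    inside the other's confident noncarriers; clade membership is the union
    of the group's carriers (unknowns never veto).  Groups are then ordered
    into a laminar hierarchy by containment of carrier sets.  Clades backed
    by fewer than ``min_support`` variants are dissolved into their parent.
    """
    if not novel_variants:
        return CladePartition()

    variants, dropped = _drop_for_compatibility(list(novel_variants))

    # The pairwise test cannot see conflicts that only emerge once carrier
    # sets are unioned within groups, so building may still yield crossing
    # member sets on adversarial input; in that case drop the fewest-carrier
    # variant of an offending clade pair and rebuild.
    while True:
        groups, members, parent_idx = _build_groups(variants)
        offender = _find_crossing(groups, members)
        if offender is None:
            break
        dropped.append((offender, "incompatible"))
        variants = [v for v in variants if v is not offender]
        if not variants:
            return CladePartition(dropped_variants=dropped)

    # min_support: dissolve under-supported clades (children re-parent upward)
    keep = [len(g["variants"]) >= min_support for g in groups]
    for i, g in enumerate(groups):
        if not keep[i]:
            for v in g["variants"]:
                dropped.append((v, "below_min_support"))

    def resolved_parent(i: int) -> Optional[int]:
        p = parent_idx[i]
        while p is not None and not keep[p]:
            p = parent_idx[p]
        return p

    kept_indices = [i for i in range(len(groups)) if keep[i]]
    name_of = {i: f"NOVEL-{rank + 1}" for rank, i in enumerate(kept_indices)}
    clades = []
    for i in kept_indices:
        p = resolved_parent(i)
        clades.append(
            Clade(
                name=name_of[i],
                parent=name_of[p] if p is not None else None,
                members=frozenset(members[i]),
                variants=sorted(groups[i]["variants"], key=lambda v: v.variant.pos),
            )
        )
    return CladePartition(clades=clades, dropped_variants=dropped)


def _build_groups(variants: Sequence[NovelVariant]):
    """Cluster variants into could-be-equal groups and order them laminarly.

    Groups are seeded largest-carrier-set-first; a variant joins the first
    group whose confident states it does not contradict.  Each group then
    nests under the smallest earlier (hence not smaller) group whose
    confident noncarriers its members avoid and whose members it overlaps;
    members of nested groups propagate upward so a sample unobserved at the
    parent's variants still counts as a parent member.
    """
    order = sorted(
        range(len(variants)),
        key=lambda i: (-len(variants[i].carriers), variants[i].variant.pos),
    )
    groups: List[Dict] = []  # {"carriers": set, "noncarriers": set, "variants": [...]}
    for i in order:
        v = variants[i]
        for g in groups:
            if not (v.carriers & g["noncarriers"]) and not (v.noncarriers & g["carriers"]):
                g["carriers"] |= v.carriers
                g["noncarriers"] |= v.noncarriers
                g["variants"].append(v)
                break
        else:
            groups.append(
                {
                    "carriers": set(v.carriers),
                    "noncarriers": set(v.noncarriers),
                    "variants": [v],
                }
            )

    groups.sort(key=lambda g: (-len(g["carriers"]), g["variants"][0].variant.pos))
    members: List[set] = [set(g["carriers"]) for g in groups]
    parent_idx: List[Optional[int]] = [None] * len(groups)
    for i in range(len(groups)):
        best: Optional[int] = None
        for j in range(i):  # parents only among earlier (>=-size) groups
            if (members[i] & members[j]) and not (members[i] & groups[j]["noncarriers"]):
                if members[j] == members[i]:
                    continue
                if best is None or len(members[best]) > len(members[j]):
                    best = j
        parent_idx[i] = best
        k = best
        while k is not None:  # acyclic: parent indexes strictly decrease
            members[k] |= members[i]
            k = parent_idx[k]
    return groups, members, parent_idx


def _find_crossing(groups: List[Dict], members: List[set]) -> Optional[NovelVariant]:
    """Fewest-carrier variant of the first clade pair that overlaps without
    nesting, or None when the family is laminar."""
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            inter = members[i] & members[j]
            if inter and not (members[i] <= members[j] or members[j] <= members[i]):
                pool = groups[i]["variants"] + groups[j]["variants"]
                return min(pool, key=lambda v: (len(v.carriers), v.variant.pos))
    return None


def attach_clades(
    tree: HaploTree,
    partition: CladePartition,
    placements: Sequence[Placement],
    names: Optional[Dict[str, str]] = None,
) -> HaploTree:
    """Graft discovered clades onto the reference tree (mutates and returns it).

    All clade members must share one terminal haplogroup in ``placements``;
    nested clades become nested nodes below it.  ``names`` optionally maps
    auto-names (``NOVEL-1``...) to curated haplogroup labels (e.g. ``R-ARP``).
    """
    if not partition.clades:
        return tree
    names = names or {}
    terminal_of = {p.sample: p.terminal for p in placements}

    all_members = set().union(*(c.members for c in partition.clades))
    terminals = {terminal_of[s] for s in all_members if s in terminal_of}
    missing = sorted(all_members - set(terminal_of))
    if missing:
        raise ValueError(f"clade members without a placement: {missing}")
    if len(terminals) != 1:
        raise ValueError(
            f"clade members span multiple backbone terminals: {sorted(terminals)}"
        )
    attach_at = terminals.pop()

    # parent-first order: top-level clades (largest) before their children
    by_name = {c.name: c for c in partition.clades}
    done: Dict[str, str] = {}  # clade name -> tree node name

    def ensure(c: Clade) -> str:
        if c.name in done:
            return done[c.name]
        if c.parent is None:
            parent_node = attach_at
        else:
            parent_node = ensure(by_name[c.parent])
        label = names.get(c.name, c.name)
        tree.add_child(parent_node, label, [v.variant for v in c.variants])
        done[c.name] = label
        return label

    for c in sorted(partition.clades, key=lambda c: -c.n_members):
        ensure(c)
    return tree


def four_gamete_check(matrix: GenotypeMatrix) -> List[Tuple[str, str]]:
    """All site pairs showing four gametes (00,01,10,11) among fully observed samples.

    An empty list is the perfect-phylogeny certificate for the matrix.
    """
    table = matrix.table
    cols = list(table.columns)
    bad: List[Tuple[str, str]] = []
    arr = table.to_numpy()
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            gametes = set()
            for row in arr:
                a, b = row[i], row[j]
                if a == "?" or b == "?":
                    continue
                gametes.add((a, b))
                if len(gametes) == 4:
                    bad.append((cols[i], cols[j]))
                    break
    return bad
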
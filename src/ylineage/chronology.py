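"""SNP-count molecular clock: dating haplotree nodes inside a callable mask.

The Y chromosome accumulates roughly one new SNP per lineage per fixed
interval of time (100-150 years per SNP for the callable region used here),
so the age of a split is proportional to the number of SNPs separating it
from the present.  Only SNPs inside a callable-region mask (the ~10 Mb of
the Y where variants are reliably ascertained) are counted; the mask is a
first-class input because age estimates hinge directly on which SNPs are
admitted.

Two calibration modes are supported:

``anchor_path``
    A node of independently known age (the anchor) fixes the years-per-SNP
    rate: rate = anchor_age / D, with D the SNP distance from the anchor to
    the present (mean over descendant tips, rho-statistic style, or a single
    designated tip path).  Every node age is then rate x its own mean SNP
    distance to its tips.

``fixed_interval``
    No anchor; each node's age is bracketed by k x mu_min and k x mu_max.

Each node carries two quantities: its *split age* (coalescence time of its
descendants — SNP distance strictly below the node) and its *appearance age*
(split age plus the node's own branch, i.e. when the lineage leading to it
diverged; for a sampled leaf this dates the haplogroup's defining mutations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple, Union

import pandas as pd
from intervaltree import IntervalTree

from .haplotree import HaploNode, HaploTree, Variant, path_to_root

__all__ = [
    "RegionMask",
    "ClockConfig",
    "DatedTree",
    "mask_variants",
    "branch_snp_counts",
    "estimate_rate_from_anchor",
    "date_nodes",
    "write_dated_newick",
]


class RegionMask:
    """Callable-region mask: sorted, non-overlapping 0-based half-open intervals."""

    def __init__(self, intervals: Sequence[Tuple[str, int, int]]) -> None:
        self._trees: Dict[str, IntervalTree] = {}
        norm: List[Tuple[str, int, int]] = []
        for chrom, start, end in intervals:
            if end <= start or start < 0:
                raise ValueError(f"bad interval {chrom}:{start}-{end}")
            norm.append((chrom, int(start), int(end)))
        norm.sort()
        for chrom, start, end in norm:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for t in self._trees.values():
            before = sum(iv.end - iv.begin for iv in t)
            t.merge_overlaps()
            after = sum(iv.end - iv.begin for iv in t)
            if before != after:
                raise ValueError("mask intervals overlap")
        self.intervals: List[Tuple[str, int, int]] = [
            (chrom, iv.begin, iv.end)
            for chrom in sorted(self._trees)
            for iv in sorted(self._trees[chrom])
        ]

    @property
    def total_length(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """Membership of a 1-based position in the 0-based half-open mask."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlaps_point(pos_1based - 1))

    @classmethod
    def from_bed(cls, source: Union[str, TextIO]) -> "RegionMask":
        """Read BED3 (extra columns ignored)."""
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        intervals = []
        for lineno, raw in enumerate(text.splitlines(), 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: expected >=3 columns")
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
        return cls(intervals)

    def to_bed(self) -> str:
        return "".join(f"{c}\t{s}\t{e}\n" for c, s, e in self.intervals)


def mask_variants(
    variants: Sequence[Variant], mask: RegionMask
) -> Tuple[List[Variant], List[Variant]]:
    """Split variants into (in_mask, out_mask) by half-open interval test."""
    inside, outside = [], []
    for v in variants:
        (inside if mask.contains(v.chrom, v.pos) else outside).append(v)
    return inside, outside


def branch_snp_counts(tree: HaploTree, mask: Optional[RegionMask] = None) -> Dict[str, int]:
    """Per-branch count of defining variants inside the mask (all, if no mask)."""
    counts: Dict[str, int] = {}
    for node in tree.iter_nodes():
        if mask is None:
            counts[node.name] = len(node.defining_variants)
        else:
            counts[node.name] = sum(
                1 for v in node.defining_variants if mask.contains(v.chrom, v.pos)
            )
    return counts


@dataclass(frozen=True)
class ClockConfig:
    """Clock calibration settings.

    anchor_node / anchor_age
        Haplogroup of independently known age (years before present) used in
        ``anchor_path`` mode.
    snp_interval
        (mu_min, mu_max) years per SNP for ``fixed_interval`` mode.
    averaging
        ``mean_over_tips`` (rho-style) or ``single_path`` (one designated
        tip, ``path_tip``) for SNP distances.
    """

    anchor_node: Optional[str] = None
    anchor_age: float = 4100.0
    snp_interval: Tuple[float, float] = (100.0, 150.0)
    rate_mode: str = "anchor_path"
    averaging: str = "mean_over_tips"
    path_tip: Optional[str] = None

    def __post_init__(self) -> None:
        lo, hi = self.snp_interval
        if lo > hi:
            raise ValueError("snp_interval must satisfy mu_min <= mu_max")
        if self.anchor_age <= 0:
            raise ValueError("anchor_age must be positive")
        if self.rate_mode not in ("anchor_path", "fixed_interval"):
            raise ValueError("rate_mode must be 'anchor_path' or 'fixed_interval'")
        if self.averaging not in ("mean_over_tips", "single_path"):
            raise ValueError("averaging must be 'mean_over_tips' or 'single_path'")


@dataclass
class NodeAge:
    node: str
    k_branch: int
    k_mean: float
    age: float
    age_low: float
    age_high: float
    appearance: float
    appearance_low: float
    appearance_high: float


@dataclass
class DatedTree:
    tree: HaploTree
    ages: Dict[str, NodeAge]
    rate: Optional[float] = None  # years per SNP under anchor_path

    def age_of(self, name: str) -> float:
        return self.ages[name].age

    def appearance_of(self, name: str) -> float:
        return self.ages[name].appearance

    def table(self) -> pd.DataFrame:
        rows = [
            {
                "node": a.node,
                "k_branch": a.k_branch,
                "k_mean": round(a.k_mean, 4),
                "age": round(a.age, 1),
                "age_low": round(a.age_low, 1),
                "age_high": round(a.age_high, 1),
                "appearance": round(a.appearance, 1),
                "appearance_low": round(a.appearance_low, 1),
                "appearance_high": round(a.appearance_high, 1),
            }
            for a in (self.ages[n.name] for n in self.tree.iter_nodes())
        ]
        return pd.DataFrame(rows)


def _tip_distances(tree: HaploTree, counts: Dict[str, int]) -> Dict[str, List[int]]:
    """For each node, SNP distances (sum of branch counts strictly below) to
    every descendant tip."""
    dists: Dict[str, List[int]] = {}

    def visit(node: HaploNode) -> List[int]:
        if node.is_leaf:
            dists[node.name] = [0]
            return [0]
        acc: List[int] = []
        for child in node.children:
            below = visit(child)
            k = counts.get(child.name, 0)
            acc.extend(d + k for d in below)
        dists[node.name] = acc
        return acc

    visit(tree.root)
    return dists


def _single_path_distance(
    tree: HaploTree, counts: Dict[str, int], node_name: str, tip_name: str
) -> Optional[int]:
    """SNP distance from node to a designated descendant tip, or None if the
    tip does not descend from the node."""
    path = path_to_root(tree, tip_name)
    names = [n.name for n in path]
    if node_name not in names:
        return None
    i = names.index(node_name)
    return sum(counts.get(n, 0) for n in names[i + 1:])


def estimate_rate_from_anchor(
    tree: HaploTree, counts: Dict[str, int], config: ClockConfig
) -> float:
    """Years per SNP from the anchor node's age and its SNP distance to the present."""
    if config.anchor_node is None:
        raise ValueError("anchor_path mode requires anchor_node")
    if config.anchor_node not in tree.by_name:
        raise KeyError(f"anchor node {config.anchor_node!r} not in tree")
    if config.averaging == "single_path":
        tip = config.path_tip
        if tip is None:
            leaves = [
                leaf.name
                for leaf in tree.leaves()
                if _single_path_distance(tree, counts, config.anchor_node, leaf.name)
                is not None
            ]
            if len(leaves) != 1:
                raise ValueError(
                    "single_path averaging needs path_tip when the anchor has "
                    f"multiple descendant tips ({leaves})"
                )
            tip = leaves[0]
        d = _single_path_distance(tree, counts, config.anchor_node, tip)
        if d is None:
            raise ValueError(f"tip {tip!r} does not descend from anchor")
        D = float(d)
    else:
        D = float(pd.Series(_tip_distances(tree, counts)[config.anchor_node]).mean())
    if D == 0:
        raise ValueError("anchor has zero SNP distance to its tips; cannot calibrate")
    return config.anchor_age / D


def date_nodes(
    tree: HaploTree, counts: Dict[str, int], config: ClockConfig
) -> DatedTree:
    """Assign split and appearance ages (years BP) to every node.

    Split ages are clamped non-increasing from root to tips; the clamp can
    only fire when tip distances are non-monotone across sibling subtrees
    (heterogeneous sampling), never on clean ultrametric input.
    """
    dists = _tip_distances(tree, counts)

    def k_mean(name: str) -> float:
        if config.averaging == "single_path" and config.path_tip is not None:
            d = _single_path_distance(tree, counts, name, config.path_tip)
            if d is not None:
                return float(d)
        ds = dists[name]
        return sum(ds) / len(ds)

    ages: Dict[str, NodeAge] = {}
    rate: Optional[float] = None
    if config.rate_mode == "anchor_path":
        rate = estimate_rate_from_anchor(tree, counts, config)
        for node in tree.iter_nodes():
            k = k_mean(node.name)
            kb = counts.get(node.name, 0)
            age = rate * k
            ages[node.name] = NodeAge(
                node=node.name,
                k_branch=kb,
                k_mean=k,
                age=age,
                age_low=age,
                age_high=age,
                appearance=age + rate * kb,
                appearance_low=age + rate * kb,
                appearance_high=age + rate * kb,
            )
    else:
        mu_min, mu_max = config.snp_interval
        mu_mid = 0.5 * (mu_min + mu_max)
        for node in tree.iter_nodes():
            k = k_mean(node.name)
            kb = counts.get(node.name, 0)
            ages[node.name] = NodeAge(
                node=node.name,
                k_branch=kb,
                k_mean=k,
                age=k * mu_mid,
                age_low=k * mu_min,
                age_high=k * mu_max,
                appearance=(k + kb) * mu_mid,
                appearance_low=(k + kb) * mu_min,
                appearance_high=(k + kb) * mu_max,
            )

    # clamp: child split age never exceeds parent split age
    for node in tree.iter_nodes():
        if node.parent is None:
            continue
        pa = ages[node.parent.name]
        a = ages[node.name]
        if a.age > pa.age:
            a.age = pa.age
        if a.age_low > pa.age_low:
            a.age_low = pa.age_low
        if a.age_high > pa.age_high:
            a.age_high = pa.age_high

    return DatedTree(tree=tree, ages=ages, rate=rate)


def _newick_name(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_dated_newick(dated: DatedTree, path: str) -> None:
    """Newick with branch lengths in years and ``[&age=...]`` node comments."""
    if dated.tree.root is None or dated.tree.n_nodes == 0:  # defensive
        raise ValueError("cannot serialize an empty dated tree")

    ages = dated.ages

    def render(node: HaploNode) -> str:
        label = f"{_newick_name(node.name)}[&age={ages[node.name].age:.1f}]"
        if node.parent is not None:
            blen = max(ages[node.parent.name].age - ages[node.name].age, 0.0)
            suffix = f":{blen:.1f}"
        else:
            suffix = ""
        if node.is_leaf:
            return label + suffix
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){label}{suffix}"

    with open(path, "w") as fh:
        fh.write(render(dated.tree.root) + ";\n")
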
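"""Reference Y haplotree: nodes, branch-defining variants, parsing and serialization.

A haplotree is a rooted tree of haplogroup names (e.g. ``R-Y2633``) whose
branches carry the SNPs that define them.  A sample carrying the derived
allele of a branch's variants belongs to that clade or below it.  Trees are
read from a simple tab-separated text format (one node per line) and can be
re-emitted in the same format or as newick for interoperability with standard
tree viewers.

Variants are keyed by ``(chrom, pos, der)``; a SNP known under several names
(ISOGG vs FamilyTree aliases) is a single :class:`Variant` carrying all its
names, never two entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, TextIO, Tuple, Union

__all__ = [
    "Variant",
    "HaploNode",
    "HaploTree",
    "HaploTreeError",
    "parse_haplotree",
    "serialize_haplotree",
    "path_to_root",
    "validate_tree",
    "to_newick",
]

VALID_BASES = frozenset("ACGT")


class HaploTreeError(ValueError):
    """Raised for malformed haplotree input (duplicate names, cycles, ...)."""


@dataclass(frozen=True)
class Variant:
    """A haplogroup-defining SNP.

    Parameters
    ----------
    chrom : str
        Contig label (``chrY`` for all real inputs).
    pos : int
        1-based position on the stated reference build.
    anc, der : str
        Ancestral and derived base; must differ and be canonical A/C/G/T.
    names : tuple of str
        One or more SNP labels (e.g. ``("Z2123",)`` or alias pairs).
    """

    chrom: str
    pos: int
    anc: str
    der: str
    names: Tuple[str, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise HaploTreeError(f"variant position must be >= 1, got {self.pos}")
        if self.anc not in VALID_BASES or self.der not in VALID_BASES:
            raise HaploTreeError(
                f"variant alleles must be A/C/G/T, got {self.anc!r}->{self.der!r}"
            )
        if self.anc == self.der:
            raise HaploTreeError(f"ancestral and derived allele identical at {self.pos}")
        if not self.names:
            raise HaploTreeError(f"variant at {self.pos} has no name")

    @property
    def key(self) -> Tuple[str, int, str]:
        """Identity key ``(chrom, pos, der)``."""
        return (self.chrom, self.pos, self.der)

    @property
    def site(self) -> Tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_deamination_pair(self) -> bool:
        """True when the anc->der change matches post-mortem damage (C>T or G>A)."""
        return (self.anc, self.der) in (("C", "T"), ("G", "A"))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{'/'.join(self.names)}({self.chrom}:{self.pos}{self.anc}>{self.der})"


@dataclass
class HaploNode:
    """A haplogroup on the tree; the branch above it carries ``defining_variants``."""

    name: str
    parent: Optional["HaploNode"] = None
    defining_variants: Tuple[Variant, ...] = ()
    children: List["HaploNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"HaploNode({self.name!r}, {len(self.defining_variants)} variants)"


class HaploTree:
    """Rooted haplotree with name and site indexes.

    Attributes
    ----------
    root : HaploNode
    by_name : dict mapping haplogroup name -> node
    by_site : dict mapping (chrom, pos) -> (node, Variant)
    """

    def __init__(self, root: HaploNode) -> None:
        self.root = root
        self.by_name: Dict[str, HaploNode] = {}
        self.by_site: Dict[Tuple[str, int], Tuple[HaploNode, Variant]] = {}
        self._reindex()

    def _reindex(self) -> None:
        self.by_name.clear()
        self.by_site.clear()
        seen_keys: Dict[Tuple[str, int, str], str] = {}
        for node in self.iter_nodes():
            if node.name in self.by_name:
                raise HaploTreeError(f"duplicate node name {node.name!r}")
            self.by_name[node.name] = node
            for v in node.defining_variants:
                if v.key in seen_keys:
                    raise HaploTreeError(
                        f"variant {v} assigned to both {seen_keys[v.key]!r} "
                        f"and {node.name!r}"
                    )
                seen_keys[v.key] = node.name
                self.by_site[v.site] = (node, v)

    def iter_nodes(self) -> Iterable[HaploNode]:
        """Pre-order traversal from the root; raises on cycles."""
        seen = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if id(node) in seen:
                raise HaploTreeError(f"cycle detected at node {node.name!r}")
            seen.add(id(node))
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> List[HaploNode]:
        return [n for n in self.iter_nodes() if n.is_leaf]

    @property
    def n_nodes(self) -> int:
        return len(self.by_name)

    def variants(self) -> List[Variant]:
        """All defining variants in pre-order."""
        return [v for n in self.iter_nodes() for v in n.defining_variants]

    def add_child(
        self,
        parent_name: str,
        name: str,
        variants: Iterable[Variant] = (),
        *,
        reparent_children: Iterable[str] = (),
    ) -> HaploNode:
        """Insert a new node below ``parent_name``.

        ``reparent_children`` lists existing children of the parent that
        should be moved underneath the new node (used when a discovered clade
        splits an existing branch point).
        """
        parent = self.by_name[parent_name]
        node = HaploNode(name=name, parent=parent, defining_variants=tuple(variants))
        moved = [c for c in parent.children if c.name in set(reparent_children)]
        parent.children = [c for c in parent.children if c.name not in set(reparent_children)]
        for c in moved:
            c.parent = node
            node.children.append(c)
        parent.children.append(node)
        self._reindex()
        return node


def _parse_variant_spec(spec: str, chrom: str, recno: int) -> Variant:
    parts = spec.split(":")
    if len(parts) != 4:
        raise HaploTreeError(
            f"record {recno}: variant spec {spec!r} is not pos:anc:der:names"
        )
    pos_s, anc, der, names_s = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise HaploTreeError(f"record {recno}: bad position {pos_s!r}") from None
    names = tuple(n for n in names_s.split("/") if n)
    try:
        return Variant(chrom=chrom, pos=pos, anc=anc.upper(), der=der.upper(), names=names)
    except HaploTreeError as e:
        raise HaploTreeError(f"record {recno}: {e}") from None


def parse_haplotree(source: Union[str, TextIO], *, chrom: str = "chrY") -> HaploTree:
    """Parse the tab-separated haplotree format.

    One node per line: ``name<TAB>parent_or_-<TAB>variant,variant,...`` where
    each variant spec is ``pos:anc:der:name1/name2``.  ``#`` starts a comment;
    a ``#chrom=NAME`` directive overrides the contig label for subsequent
    records.  Parents may be declared after their children.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = source

    records: List[Tuple[int, str, Optional[str], Tuple[Variant, ...]]] = []
    cur_chrom = chrom
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#chrom="):
            cur_chrom = line.split("=", 1)[1].strip()
            continue
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise HaploTreeError(f"record {lineno}: expected >=2 tab-separated fields")
        name = fields[0].strip()
        parent = fields[1].strip()
        parent_name = None if parent in ("-", "") else parent
        variants: Tuple[Variant, ...] = ()
        if len(fields) >= 3 and fields[2].strip():
            variants = tuple(
                _parse_variant_spec(s.strip(), cur_chrom, lineno)
                for s in fields[2].split(",")
                if s.strip()
            )
        records.append((lineno, name, parent_name, variants))

    if not records:
        raise HaploTreeError("empty tree file")

    nodes: Dict[str, HaploNode] = {}
    for recno, name, _, variants in records:
        if name in nodes:
            raise HaploTreeError(f"record {recno}: duplicate node name {name!r}")
        nodes[name] = HaploNode(name=name, defining_variants=variants)

    roots = []
    for recno, name, parent_name, _ in records:
        node = nodes[name]
        if parent_name is None:
            roots.append(name)
            continue
        if parent_name not in nodes:
            raise HaploTreeError(
                f"record {recno}: parent {parent_name!r} of {name!r} not declared"
            )
        parent = nodes[parent_name]
        node.parent = parent
        parent.children.append(node)

    if len(roots) != 1:
        raise HaploTreeError(f"expected exactly one root, found {len(roots)}: {roots}")

    tree = HaploTree(nodes[roots[0]])
    if tree.n_nodes != len(nodes):
        unreachable = sorted(set(nodes) - set(tree.by_name))
        raise HaploTreeError(f"unreachable nodes (cycle or orphan subtree): {unreachable}")
    return tree


def serialize_haplotree(tree: HaploTree) -> str:
    """Emit the tree in the tab-separated haplotree format (round-trips parse)."""
    lines = []
    for node in tree.iter_nodes():
        parent = node.parent.name if node.parent is not None else "-"
        specs = ",".join(
            f"{v.pos}:{v.anc}:{v.der}:{'/'.join(v.names)}" for v in node.defining_variants
        )
        lines.append(f"{node.name}\t{parent}\t{specs}")
    return "\n".join(lines) + "\n"


def path_to_root(tree: HaploTree, node_name: str) -> List[HaploNode]:
    """Return the node list root..node (inclusive) for ``node_name``."""
    if node_name not in tree.by_name:
        raise KeyError(f"unknown haplogroup {node_name!r}")
    path = []
    node: Optional[HaploNode] = tree.by_name[node_name]
    while node is not None:
        path.append(node)
        node = node.parent
    path.reverse()
    return path


@dataclass(frozen=True)
class TreeIssue:
    severity: str  # "warning" | "error"
    node: str
    message: str


def validate_tree(tree: HaploTree) -> List[TreeIssue]:
    """Structural QC: variant-free nodes (warning), duplicate sites (error).

    Unreachable nodes and duplicate (chrom,pos,der) keys are already fatal at
    construction; this reports the softer issues a curator should review.
    """
    issues: List[TreeIssue] = []
    site_owners: Dict[Tuple[str, int], List[str]] = {}
    for node in tree.iter_nodes():
        if not node.defining_variants and node is not tree.root:
            issues.append(
                TreeIssue("warning", node.name, "structural node with no defining variants")
            )
        for v in node.defining_variants:
            site_owners.setdefault(v.site, []).append(node.name)
    for site, owners in site_owners.items():
        if len(owners) > 1:
            issues.append(
                TreeIssue(
                    "error",
                    owners[0],
                    f"position {site[0]}:{site[1]} defined on multiple branches: {owners}",
                )
            )
    return issues


def _newick_escape(name: str) -> str:
    if any(c in name for c in " (),:;'"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(tree: HaploTree) -> str:
    """Names-only newick rendering of the topology."""

    def render(node: HaploNode) -> str:
        if node.is_leaf:
            return _newick_escape(node.name)
        inner = ",".join(render(c) for c in node.children)
        return f"({inner}){_newick_escape(node.name)}"

    return render(tree.root) + ";"
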
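"""Tree-guided haplogroup placement for low-coverage samples.

Starting at the root, a sample descends into a child branch when at least
one of the branch's defining variants is called derived and derived calls
outnumber ancestral ones on that branch.  Descent stops when no child is
supported, or when two children are supported with an equal derived fraction
(an ambiguity the caller must inspect, not a coin flip).  Siblings of the
chosen branch with confident ancestral calls are recorded as excluded — the
evidence that rules lineages out is as informative as the evidence that
rules them in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .haplotree import HaploNode, HaploTree
from .observations import ANCESTRAL, CONFLICT, DERIVED, AlleleCall

__all__ = ["BranchSupport", "Placement", "score_branch", "place_sample", "placement_report"]

CallMap = Dict[Tuple[str, int, str], AlleleCall]


@dataclass(frozen=True)
class BranchSupport:
    """Tally of a sample's calls over one branch's defining variants."""

    node: HaploNode
    n_defining: int
    n_observed: int
    n_derived: int
    n_ancestral: int
    n_conflict: int

    @property
    def derived_fraction(self) -> float:
        return self.n_derived / self.n_observed if self.n_observed else 0.0

    @property
    def supported(self) -> bool:
        """Descent rule: at least one derived call, and derived beats ancestral."""
        return self.n_derived >= 1 and self.n_derived > self.n_ancestral


@dataclass
class Placement:
    """Result of walking one sample down the haplotree."""

    sample: str
    terminal: str
    path: List[BranchSupport]
    excluded_siblings: List[Tuple[str, int]] = field(default_factory=list)
    ambiguous_children: List[str] = field(default_factory=list)
    fraction_path_observed: float = 0.0
    conflicts_on_path: int = 0

    @property
    def ambiguous(self) -> bool:
        return bool(self.ambiguous_children)


def score_branch(calls: CallMap, node: HaploNode) -> BranchSupport:
    """Tally derived/ancestral/conflict calls over the branch's variants."""
    n_def = len(node.defining_variants)
    n_obs = n_der = n_anc = n_conf = 0
    for v in node.defining_variants:
        call = calls.get(v.key)
        if call is None:
            continue
        if call.state == DERIVED:
            n_der += 1
            n_obs += 1
        elif call.state == ANCESTRAL:
            n_anc += 1
            n_obs += 1
        elif call.state == CONFLICT:
            n_conf += 1
            n_obs += 1
    return BranchSupport(node, n_def, n_obs, n_der, n_anc, n_conf)


def _subtree_has_support(calls: CallMap, node: HaploNode) -> bool:
    """Any strict descendant branch with direct derived support."""
    stack = list(node.children)
    while stack:
        n = stack.pop()
        if score_branch(calls, n).supported:
            return True
        stack.extend(n.children)
    return False


def place_sample(tree: HaploTree, calls: CallMap, sample: str = "sample") -> Placement:
    """Assign the deepest supported haplogroup for one sample.

    A child branch with no observed calls at all (typically a structural node
    without defining variants) is transparent: descent passes through it when
    exactly one such child's subtree carries derived support, since the branch
    itself can neither confirm nor exclude.  An all-missing sample places at
    the root with fraction_path_observed 0.
    """
    node = tree.root
    path: List[BranchSupport] = [score_branch(calls, node)]
    excluded: List[Tuple[str, int]] = []
    ambiguous: List[str] = []

    while True:
        scored = [score_branch(calls, c) for c in node.children]
        supported = [s for s in scored if s.supported]
        if not supported:
            # transparent descent through unobserved branches
            passable = [
                s for s in scored
                if s.n_observed == 0 and _subtree_has_support(calls, s.node)
            ]
            if len(passable) == 1:
                for s in scored:
                    if s is not passable[0] and s.n_ancestral >= 1:
                        excluded.append((s.node.name, s.n_ancestral))
                path.append(passable[0])
                node = passable[0].node
                continue
            if len(passable) > 1:
                ambiguous = [s.node.name for s in passable]
            for s in scored:
                if s.n_ancestral >= 1:
                    excluded.append((s.node.name, s.n_ancestral))
            break
        best_frac = max(s.derived_fraction for s in supported)
        best = [s for s in supported if s.derived_fraction == best_frac]
        if len(best) > 1:
            ambiguous = [s.node.name for s in best]
            for s in scored:
                if s.n_ancestral >= 1 and s.node.name not in set(ambiguous):
                    excluded.append((s.node.name, s.n_ancestral))
            break
        chosen = best[0]
        for s in scored:
            if s.node is not chosen.node and s.n_ancestral >= 1:
                excluded.append((s.node.name, s.n_ancestral))
        path.append(chosen)
        node = chosen.node

    n_def = sum(s.n_defining for s in path)
    n_obs = sum(s.n_observed for s in path)
    return Placement(
        sample=sample,
        terminal=node.name,
        path=path,
        excluded_siblings=excluded,
        ambiguous_children=ambiguous,
        fraction_path_observed=(n_obs / n_def) if n_def else 0.0,
        conflicts_on_path=sum(s.n_conflict for s in path),
    )


def placement_report(
    placements: List[Placement],
    aliases: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """One row per sample: terminal haplogroup, optional alias, path and QC.

    ``aliases`` maps terminal shorthand to an alternative nomenclature string
    (e.g. ISOGG longhand) when one is configured.
    """
    if not placements:
        raise ValueError("placement_report requires at least one placement")
    aliases = aliases or {}
    rows = []
    for p in placements:
        rows.append(
            {
                "sample": p.sample,
                "terminal_name": p.terminal,
                "terminal_aliases": aliases.get(p.terminal, ""),
                "path": ">".join(s.node.name for s in p.path),
                "fraction_path_observed": round(p.fraction_path_observed, 4),
                "conflicts": p.conflicts_on_path,
                "ambiguity_flag": ";".join(p.ambiguous_children),
            }
        )
    return pd.DataFrame(rows)
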
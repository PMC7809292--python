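"""Generative model for every pipeline input.

Simulates a dated patrilineal genealogy, drops Poisson mutations on its
branches inside a callable mask (one SNP per ``snp_interval_mu`` years, the
molecular-clock assumption the dating stage inverts), and renders per-sample
sequencing evidence with the failure modes of ancient DNA: Poisson read
depth down to fractions of 1x, per-read sequencing error, and post-mortem
deamination damage (C reads flipping to T, G reads to A, per read at C/G
sites).  Hiding chosen clades from the emitted reference tree recreates the
novel-haplogroup discovery scenario: their variants are then off-tree and
must be rediscovered from sharing patterns.

All randomness flows through one ``numpy`` generator seeded from
``SimConfig.seed``; a fixed seed gives bit-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chronology import RegionMask
from .haplotree import HaploNode, HaploTree, Variant, serialize_haplotree
from .observations import BASES, ObservationMap, SiteObservation

__all__ = [
    "GenealogyNode",
    "SimConfig",
    "SimTruth",
    "simulate_genealogy",
    "simulate_variants",
    "simulate_observations",
    "simulate_sex_counts",
    "make_reference_tree",
    "truth_to_haplotree",
    "simulate_cohort",
    "write_cohort",
    "write_readcount_tsv",
    "write_vcf",
]

# transition partner for each base (deamination-independent mutation bias)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class GenealogyNode:
    """Node of the true dated genealogy (ages in years before present)."""

    name: str
    age: float
    parent: Optional["GenealogyNode"] = None
    children: List["GenealogyNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> List["GenealogyNode"]:
        return [n for n in self.walk() if n.is_leaf]


def _default_mask() -> RegionMask:
    # 100 kb toy callable region; real analyses use the ~10 Mb Y callable set
    return RegionMask([("chrY", 1_000_000, 1_100_000)])


@dataclass(frozen=True)
class SimConfig:
    """Full generative model configuration.

    n_tips / root_age
        Random genealogy shape: number of sampled male lineages and the age
        of their common ancestor (default 4500 years, the time depth of the
        clades this pipeline is aimed at).
    snp_interval_mu
        Years per SNP on a lineage (default 120, midpoint of the 100-150
        range quoted for the Y callable region).
    mean_depth
        Mean read depth per site; per-sample overrides via ``depths`` mimic
        the 0.17-7x spread of real ancient cohorts.
    seq_error_rate / damage_rate
        Per-read error and per-read C>T / G>A deamination probability.
    missing_rate
        Extra per-site dropout beyond Poisson depth-0.
    hidden_clades
        Genealogy node names withheld from the emitted reference tree.
    """

    n_tips: int = 10
    root_age: float = 4500.0
    genealogy: Optional[GenealogyNode] = None
    snp_interval_mu: float = 120.0
    mask: RegionMask = field(default_factory=_default_mask)
    mean_depth: float = 5.0
    depths: Optional[Dict[str, float]] = None
    seq_error_rate: float = 0.001
    damage_rate: float = 0.1
    missing_rate: float = 0.0
    base_quality: float = 37.0
    hidden_clades: Tuple[str, ...] = ()
    female_fraction: float = 0.0
    sex_total_reads: int = 2000
    xx_y_error: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.seq_error_rate, self.damage_rate, self.missing_rate,
                  self.female_fraction, self.xx_y_error):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.root_age <= 0:
            raise ValueError("root_age must be positive")
        if self.n_tips < 2:
            raise ValueError("need at least two tips")


@dataclass
class SimTruth:
    """Ground truth paired with the emitted observation files."""

    genealogy: GenealogyNode
    branch_variants: Dict[str, List[Variant]]  # node name -> variants on its branch
    sample_of_tip: Dict[str, str]  # tip name -> sample name
    true_haplogroup: Dict[str, str]  # sample -> tip (terminal haplogroup) name
    true_sex: Dict[str, str]  # sample -> "XY" | "XX"
    config: SimConfig

    @property
    def samples(self) -> List[str]:
        return [self.sample_of_tip[t.name] for t in self.genealogy.leaves()]

    def variants_on_path(self, tip_name: str) -> List[Variant]:
        node = next(n for n in self.genealogy.walk() if n.name == tip_name)
        out: List[Variant] = []
        while node is not None:
            out.extend(self.branch_variants.get(node.name, []))
            node = node.parent
        return out

    def all_variants(self) -> List[Variant]:
        return [v for vs in self.branch_variants.values() for v in vs]


def simulate_genealogy(config: SimConfig, rng: Optional[np.random.Generator] = None) -> GenealogyNode:
    """Random binary-splitting dated genealogy (or the explicit one, unchanged).

    The root splits at ``root_age``; the remaining n_tips-2 split times are
    uniform on (0, root_age); each split subdivides a uniformly chosen open
    lineage.  All tips are sampled at the present (age 0).
    """
    if config.genealogy is not None:
        return config.genealogy
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_tips
    times = sorted(rng.uniform(0.0, config.root_age, size=n - 2), reverse=True)

    root = GenealogyNode("ANC-1", config.root_age)
    open_lineages: List[GenealogyNode] = [root, root]  # daughter slots
    next_anc = 2
    for t in times:
        i = int(rng.integers(len(open_lineages)))
        parent = open_lineages.pop(i)
        node = GenealogyNode(f"ANC-{next_anc}", t, parent=parent)
        next_anc += 1
        parent.children.append(node)
        open_lineages.extend([node, node])
    for i, parent in enumerate(open_lineages, start=1):
        tip = GenealogyNode(f"TIP-{i}", 0.0, parent=parent)
        parent.children.append(tip)
    return root


def _draw_positions(mask: RegionMask, n: int, rng: np.random.Generator,
                    taken: set) -> List[int]:
    """n distinct 1-based positions uniform over the mask, avoiding ``taken``."""
    if n == 0:
        return []
    if mask.total_length - len(taken) < n:
        raise ValueError("mask too small for the requested number of variants")
    # cumulative interval lengths for uniform draws across intervals
    lengths = np.array([e - s for _, s, e in mask.intervals])
    cum = np.cumsum(lengths)
    out: List[int] = []
    while len(out) < n:
        r = int(rng.integers(cum[-1]))
        idx = int(np.searchsorted(cum, r, side="right"))
        chrom, start, _ = mask.intervals[idx]
        offset = r - (cum[idx - 1] if idx else 0)
        pos = start + offset + 1  # 1-based
        if pos not in taken:
            taken.add(pos)
            out.append(pos)
    return out


def simulate_variants(
    genealogy: GenealogyNode,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[Variant]]:
    """Poisson mutations per branch: count ~ Poisson(branch_years / mu).

    Positions are collision-free across the whole tree; derived alleles are
    transitions with probability 2/3 (a 2:1 Ts:Tv bias).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    taken: set = set()
    out: Dict[str, List[Variant]] = {}
    for node in genealogy.walk():
        if node.parent is None:
            continue
        years = node.parent.age - node.age
        k = 0 if not np.isfinite(config.snp_interval_mu) else int(
            rng.poisson(years / config.snp_interval_mu)
        )
        positions = _draw_positions(config.mask, k, rng, taken)
        variants = []
        for pos in positions:
            anc = BASES[int(rng.integers(4))]
            if rng.random() < 2.0 / 3.0:
                der = TRANSITION[anc]
            else:
                choices = [b for b in BASES if b != anc and b != TRANSITION[anc]]
                der = choices[int(rng.integers(2))]
            variants.append(
                Variant(chrom="chrY", pos=pos, anc=anc, der=der, names=(f"SIM{pos}",))
            )
        out[node.name] = variants
    return out


def simulate_observations(
    truth: SimTruth,
    config: Optional[SimConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, ObservationMap]:
    """Render per-sample site observations over every simulated variant site.

    Per site: depth ~ Poisson(sample mean depth); each read reports the true
    allele, miscalled uniformly with ``seq_error_rate``, then deaminated
    (C->T / G->A) with ``damage_rate``; whole sites drop out with
    ``missing_rate`` (on top of Poisson depth 0, which also yields no record).
    """
    config = config or truth.config
    rng = rng or np.random.default_rng(config.seed + 2)
    all_variants = truth.all_variants()
    out: Dict[str, ObservationMap] = {}
    for tip in truth.genealogy.leaves():
        sample = truth.sample_of_tip[tip.name]
        depth_mean = (config.depths or {}).get(sample, config.mean_depth)
        derived_keys = {v.key for v in truth.variants_on_path(tip.name)}
        obs: ObservationMap = {}
        for v in all_variants:
            if config.missing_rate and rng.random() < config.missing_rate:
                continue
            depth = int(rng.poisson(depth_mean))
            if depth == 0:
                continue
            true_base = v.der if v.key in derived_keys else v.anc
            counts = {b: 0 for b in BASES}
            for _ in range(depth):
                base = true_base
                if config.seq_error_rate and rng.random() < config.seq_error_rate:
                    others = [b for b in BASES if b != base]
                    base = others[int(rng.integers(3))]
                if config.damage_rate:
                    if base == "C" and rng.random() < config.damage_rate:
                        base = "T"
                    elif base == "G" and rng.random() < config.damage_rate:
                        base = "A"
                counts[base] += 1
            meanq = {b: (config.base_quality if counts[b] else 0.0) for b in BASES}
            obs[(v.chrom, v.pos)] = SiteObservation(
                chrom=v.chrom, pos=v.pos, ref=v.anc, counts=counts, meanq=meanq
            )
        out[sample] = obs
    return out


def simulate_sex_counts(
    true_sex: str,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[int, int]:
    """X/Y read counts: XY samples split sex-chromosome reads evenly between
    the haploid X and Y; XX samples put them all on X bar an error floor."""
    rng = rng or np.random.default_rng(config.seed + 3)
    n = config.sex_total_reads
    if true_sex == "XY":
        nX = int(rng.poisson(n / 2))
        nY = int(rng.poisson(n / 2))
    elif true_sex == "XX":
        nX = int(rng.poisson(n))
        nY = int(rng.poisson(n * config.xx_y_error))
    else:
        raise ValueError(f"unknown sex {true_sex!r}")
    return nX, nY


def truth_to_haplotree(
    genealogy: GenealogyNode, branch_variants: Dict[str, List[Variant]]
) -> HaploTree:
    """Convert the dated genealogy to a HaploTree carrying its branch variants."""

    def build(gn: GenealogyNode, parent: Optional[HaploNode]) -> HaploNode:
        node = HaploNode(
            name=gn.name,
            parent=parent,
            defining_variants=tuple(branch_variants.get(gn.name, [])),
        )
        for c in gn.children:
            node.children.append(build(c, node))
        return node

    return HaploTree(build(genealogy, None))


def make_reference_tree(truth: SimTruth, hidden_clades: Sequence[str] = ()) -> HaploTree:
    """Reference tree with the hidden clades spliced out.

    A hidden node's children re-parent to its parent and its defining
    variants vanish from the tree — exactly the situation in which those
    variants later surface as novel.
    """
    names = {n.name for n in truth.genealogy.walk()}
    for h in hidden_clades:
        if h not in names:
            raise KeyError(f"unknown clade {h!r}")
        if h == truth.genealogy.name:
            raise ValueError("cannot hide the root")
    hidden = set(hidden_clades)

    def build(gn: GenealogyNode, parent: Optional[HaploNode]) -> List[HaploNode]:
        if gn.name in hidden:
            out: List[HaploNode] = []
            for c in gn.children:
                out.extend(build(c, parent))
            return out
        node = HaploNode(
            name=gn.name,
            parent=parent,
            defining_variants=tuple(truth.branch_variants.get(gn.name, [])),
        )
        for c in gn.children:
            node.children.extend(build(c, node))
        return [node]

    roots = build(truth.genealogy, None)
    assert len(roots) == 1
    return HaploTree(roots[0])


def simulate_cohort(config: SimConfig) -> Tuple[SimTruth, Dict[str, ObservationMap]]:
    """Run the full generative model: genealogy, variants, observations, sexes."""
    rng = np.random.default_rng(config.seed)
    genealogy = simulate_genealogy(config, rng)
    branch_variants = simulate_variants(genealogy, config, rng)
    tips = genealogy.leaves()
    sample_of_tip = {t.name: f"smp_{t.name}" for t in tips}
    true_haplogroup = {sample_of_tip[t.name]: t.name for t in tips}
    true_sex = {
        sample_of_tip[t.name]: ("XX" if rng.random() < config.female_fraction else "XY")
        for t in tips
    }
    truth = SimTruth(
        genealogy=genealogy,
        branch_variants=branch_variants,
        sample_of_tip=sample_of_tip,
        true_haplogroup=true_haplogroup,
        true_sex=true_sex,
        config=config,
    )
    observations = simulate_observations(truth, config, rng)
    return truth, observations


def write_readcount_tsv(obs: ObservationMap, path: str) -> None:
    with open(path, "w") as fh:
        for (chrom, pos) in sorted(obs):
            o = obs[(chrom, pos)]
            depth = o.depth
            cols = "\t".join(
                f"{b}:{o.count(b)}:{o.quality(b):.1f}" for b in BASES
            )
            fh.write(f"{chrom}\t{pos}\t{o.ref}\t{depth}\t{cols}\n")


def write_vcf(
    obs: ObservationMap, variants: Sequence[Variant], path: str, sample: str
) -> None:
    """VCF 4.2 with per-sample AD over the given variant sites (anc as REF)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrY>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        o = obs.get(v.site)
        if o is None:
            continue
        n_ref, n_alt = o.count(v.anc), o.count(v.der)
        if n_alt > n_ref:
            gt = "1"
        elif n_ref > 0:
            gt = "0"
        else:
            gt = "."
        q = max(o.quality(v.anc), o.quality(v.der))
        lines.append(
            f"{v.chrom}\t{v.pos}\t{'/'.join(v.names)}\t{v.anc}\t{v.der}"
            f"\t{q:.0f}\tPASS\t.\tGT:AD\t{gt}:{n_ref},{n_alt}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_cohort(config: SimConfig, outdir: str) -> SimTruth:
    """Emit every pipeline input for a simulated cohort under ``outdir``.

    Files: reference_tree.tsv (hidden clades removed), truth_tree.tsv,
    mask.bed, obs/<sample>.readcount.tsv, obs/<sample>.vcf, profiles.tsv,
    truth.tsv.
    """
    os.makedirs(os.path.join(outdir, "obs"), exist_ok=True)
    truth, observations = simulate_cohort(config)
    rng = np.random.default_rng(config.seed + 4)

    ref_tree = make_reference_tree(truth, config.hidden_clades)
    full_tree = truth_to_haplotree(truth.genealogy, truth.branch_variants)
    with open(os.path.join(outdir, "reference_tree.tsv"), "w") as fh:
        fh.write(serialize_haplotree(ref_tree))
    with open(os.path.join(outdir, "truth_tree.tsv"), "w") as fh:
        fh.write(serialize_haplotree(full_tree))
    with open(os.path.join(outdir, "mask.bed"), "w") as fh:
        fh.write(config.mask.to_bed())

    all_vars = truth.all_variants()
    prof_lines = ["sample\tnX\tnY\ty_haplogroup\tmt_haplogroup"]
    truth_lines = ["sample\ttrue_haplogroup\ttrue_sex"]
    for tip in truth.genealogy.leaves():
        sample = truth.sample_of_tip[tip.name]
        obs = observations[sample]
        write_readcount_tsv(obs, os.path.join(outdir, "obs", f"{sample}.readcount.tsv"))
        write_vcf(obs, all_vars, os.path.join(outdir, "obs", f"{sample}.vcf"), sample)
        sex = truth.true_sex[sample]
        nX, nY = simulate_sex_counts(sex, config, rng)
        y_label = tip.name if sex == "XY" else "-"
        mt_label = f"MT-{tip.name}"
        prof_lines.append(f"{sample}\t{nX}\t{nY}\t{y_label}\t{mt_label}")
        truth_lines.append(f"{sample}\t{truth.true_haplogroup[sample]}\t{sex}")
    with open(os.path.join(outdir, "profiles.tsv"), "w") as fh:
        fh.write("\n".join(prof_lines) + "\n")
    with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
        fh.write("\n".join(truth_lines) + "\n")
    return truth
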
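"""End-to-end orchestration: observations -> placement -> clade discovery ->
chronology -> sex & kinship, driven by a single YAML config.

Stages are isolated per sample where possible: a corrupt observation file
fails that sample (recorded in the report) without aborting the cohort.
Reports are plain tab-separated tables plus one JSON summary whose body is
byte-identical across reruns of the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import yaml

from . import __version__
from .chronology import (
    ClockConfig,
    DatedTree,
    RegionMask,
    branch_snp_counts,
    date_nodes,
    write_dated_newick,
)
from .clades import (
    CladePartition,
    attach_clades,
    collect_novel_variants,
    partition_clades,
)
from .haplotree import HaploTree, Variant, parse_haplotree, serialize_haplotree
from .observations import (
    BASES,
    CallPolicy,
    ObservationMap,
    call_sample,
    genotype_matrix,
    read_observations,
)
from .placement import Placement, place_sample, placement_report
from .sexkin import (
    SexThresholds,
    UniparentalProfile,
    assign_sex,
    cohort_kinship_report,
)

logger = logging.getLogger("ylineage")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "discover_extra_variants"]


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    tree: str
    observations: Dict[str, str]  # sample -> path (readcount tsv or vcf)
    outdir: str
    mask: Optional[str] = None
    profiles: Optional[str] = None
    policy: CallPolicy = field(default_factory=CallPolicy)
    clock: Optional[ClockConfig] = None
    sex_thresholds: SexThresholds = field(default_factory=SexThresholds)
    min_support: int = 1
    clade_names: Dict[str, str] = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "policy" in kwargs and kwargs["policy"] is not None:
            kwargs["policy"] = CallPolicy(**kwargs["policy"])
        if "clock" in kwargs and kwargs["clock"] is not None:
            clock = dict(kwargs["clock"])
            if "snp_interval" in clock:
                clock["snp_interval"] = tuple(clock["snp_interval"])
            kwargs["clock"] = ClockConfig(**clock)
        if "sex_thresholds" in kwargs and kwargs["sex_thresholds"] is not None:
            kwargs["sex_thresholds"] = SexThresholds(**kwargs["sex_thresholds"])
        return cls(**kwargs)

    def validate(self) -> None:
        if not self.observations:
            raise ValueError("config lists no samples under 'observations'")
        if not os.path.exists(self.tree):
            raise FileNotFoundError(f"tree file not found: {self.tree}")
        for sample, path in self.observations.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"observations for {sample!r} not found: {path}")
        for attr in ("mask", "profiles"):
            p = getattr(self, attr)
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(f"{attr} file not found: {p}")

    def digest(self) -> str:
        # outdir and log level do not affect results, so they stay out of the
        # provenance digest: the same analysis in two directories is one run
        payload = {
            k: (vars(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in vars(self).items()
            if k not in ("outdir", "log_level")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    placements: List[Placement]
    partition: Optional[CladePartition]
    augmented_tree: HaploTree
    dated: Optional[DatedTree]
    sample_errors: Dict[str, str]
    outdir: str
    provenance: Dict[str, str]


def discover_extra_variants(
    observations: Dict[str, ObservationMap],
    tree: HaploTree,
    min_alt_reads: int = 1,
) -> List[Variant]:
    """Candidate off-tree variants from the cohort's observed sites.

    A site absent from the tree becomes a candidate when any non-reference
    base is seen; the alternate allele is the non-reference base with the
    highest summed count across samples (biallelic reduction).
    """
    pooled: Dict[Tuple[str, int], Dict[str, int]] = {}
    refs: Dict[Tuple[str, int], str] = {}
    for obs in observations.values():
        for key, o in obs.items():
            if key in tree.by_site:
                continue
            acc = pooled.setdefault(key, {b: 0 for b in BASES})
            for b in BASES:
                acc[b] += o.count(b)
            refs.setdefault(key, o.ref)
    out: List[Variant] = []
    for key in sorted(pooled):
        ref = refs[key]
        if ref not in BASES:
            continue
        alts = {b: c for b, c in pooled[key].items() if b != ref and c >= min_alt_reads}
        if not alts:
            continue
        alt = max(sorted(alts), key=lambda b: alts[b])
        out.append(
            Variant(chrom=key[0], pos=key[1], anc=ref, der=alt, names=(f"NOV{key[1]}",))
        )
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write reports under ``config.outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    tree = parse_haplotree(open(config.tree).read())
    logger.info("loaded tree with %d nodes, %d variants", tree.n_nodes, len(tree.by_site))

    observations: Dict[str, ObservationMap] = {}
    errors: Dict[str, str] = {}
    for sample, path in sorted(config.observations.items()):
        try:
            observations[sample] = read_observations(path, sample=sample)
        except Exception as e:  # per-sample isolation
            logger.warning("sample %s failed to load: %s", sample, e)
            errors[sample] = str(e)

    tree_variants = tree.variants()
    extra = discover_extra_variants(observations, tree)
    all_variants = tree_variants + extra
    samples = sorted(observations)
    calls = {
        s: call_sample(observations[s], all_variants, config.policy) for s in samples
    }
    placements = [place_sample(tree, calls[s], sample=s) for s in samples]
    matrix = genotype_matrix(samples, all_variants, calls)

    novel = collect_novel_variants(matrix, tree)
    partition = partition_clades(novel, min_support=config.min_support) if novel else None
    if partition and partition.clades:
        attach_clades(tree, partition, placements, names=config.clade_names)
        # re-place against the augmented tree so terminals include new clades
        placements = [place_sample(tree, calls[s], sample=s) for s in samples]

    dated = None
    if config.clock is not None:
        mask = RegionMask.from_bed(config.mask) if config.mask else None
        counts = branch_snp_counts(tree, mask)
        dated = date_nodes(tree, counts, config.clock)

    # ---- reports -------------------------------------------------------
    out = config.outdir
    placement_report(placements).to_csv(
        os.path.join(out, "placements.tsv"), sep="\t", index=False
    )
    if partition:
        partition.report().to_csv(os.path.join(out, "clades.tsv"), sep="\t", index=False)
    with open(os.path.join(out, "augmented_tree.tsv"), "w") as fh:
        fh.write(serialize_haplotree(tree))
    if dated is not None:
        dated.table().to_csv(os.path.join(out, "node_ages.tsv"), sep="\t", index=False)
        write_dated_newick(dated, os.path.join(out, "dated_tree.nwk"))

    if config.profiles is not None:
        import pandas as pd

        prof_df = pd.read_csv(config.profiles, sep="\t", dtype=str)
        sex_rows = []
        profiles = []
        for _, row in prof_df.iterrows():
            call = assign_sex(float(row["nX"]), float(row["nY"]), config.sex_thresholds)
            sex_rows.append(
                {
                    "sample": row["sample"],
                    "nX": row["nX"],
                    "nY": row["nY"],
                    "Ry": round(call.Ry, 4),
                    "classification": call.classification,
                }
            )
            y = row.get("y_haplogroup")
            y = None if (y is None or y in ("-", "")) else y
            profiles.append(
                UniparentalProfile(
                    sample=row["sample"], mt_haplogroup=row["mt_haplogroup"], y_haplogroup=y
                )
            )
        pd.DataFrame(sex_rows).to_csv(os.path.join(out, "sex.tsv"), sep="\t", index=False)
        if len(profiles) >= 2:
            cohort_kinship_report(profiles).to_csv(
                os.path.join(out, "kinship.tsv"), sep="\t", index=False
            )

    provenance = {
        "config_digest": config.digest(),
        "seed": str(config.seed),
        "version": __version__,
    }
    summary = {
        "n_samples": len(samples),
        "n_sample_errors": len(errors),
        "sample_errors": errors,
        "n_novel_variants": len(novel),
        "n_novel_clades": len(partition.clades) if partition else 0,
        "terminals": {p.sample: p.terminal for p in placements},
        "provenance": provenance,
    }
    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return RunReport(
        placements=placements,
        partition=partition,
        augmented_tree=tree,
        dated=dated,
        sample_errors=errors,
        outdir=out,
        provenance=provenance,
    )
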
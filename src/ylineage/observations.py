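"""Per-site sequencing evidence and ancient-DNA-aware allele calling.

Input is either a readcount-style tab-separated table (per-base depth and
mean quality at each interrogated position) or a VCF with per-sample allelic
depths.  Each haplogroup-defining site is reduced to one of four states —
derived / ancestral / missing / conflict — under an explicit
:class:`CallPolicy`.  Ancient genomes in this setting run as low as ~0.2x
coverage, so single-read calls must be admissible; the optional strict damage
mode compensates by demanding extra depth for derived calls that look like
post-mortem cytosine deamination (C>T / G>A).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .haplotree import HaploTree, Variant

__all__ = [
    "SiteObservation",
    "CallPolicy",
    "AlleleCall",
    "ObservationError",
    "read_observations",
    "read_readcount_tsv",
    "read_vcf_observations",
    "call_state",
    "call_sample",
    "genotype_matrix",
    "MISSING",
    "DERIVED",
    "ANCESTRAL",
    "CONFLICT",
]

BASES = ("A", "C", "G", "T")

DERIVED = "derived"
ANCESTRAL = "ancestral"
MISSING = "missing"
CONFLICT = "conflict"


class ObservationError(ValueError):
    """Malformed observation input."""


@dataclass(frozen=True)
class SiteObservation:
    """Base counts and mean base qualities at one position for one sample."""

    chrom: str
    pos: int
    ref: str
    counts: Dict[str, int]
    meanq: Dict[str, float]

    def __post_init__(self) -> None:
        for b in BASES:
            if self.counts.get(b, 0) < 0:
                raise ObservationError(f"negative count at {self.chrom}:{self.pos}")

    @property
    def depth(self) -> int:
        return sum(self.counts.get(b, 0) for b in BASES)

    def count(self, base: str) -> int:
        return self.counts.get(base, 0)

    def quality(self, base: str) -> float:
        return self.meanq.get(base, 0.0)


@dataclass(frozen=True)
class CallPolicy:
    """Thresholds reducing a :class:`SiteObservation` to an allele state.

    min_depth
        Minimum reads supporting the called allele (default 1 — sub-1x
        genomes contribute single-read calls).
    min_quality
        Minimum mean base quality of the called allele.
    min_major_fraction
        Fraction of (anc+der) reads the called allele must reach; in (0.5, 1].
    damage_mode
        ``"off"`` or ``"strict"``; strict degrades would-be derived C>T / G>A
        calls with depth below ``min_depth_damage`` to missing.
    """

    min_depth: int = 1
    min_quality: float = 20.0
    min_major_fraction: float = 0.7
    damage_mode: str = "off"
    min_depth_damage: int = 2

    def __post_init__(self) -> None:
        if not (0.5 < self.min_major_fraction <= 1.0):
            raise ValueError("min_major_fraction must be in (0.5, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.damage_mode not in ("off", "strict"):
            raise ValueError("damage_mode must be 'off' or 'strict'")


@dataclass(frozen=True)
class AlleleCall:
    """State of one haplogroup-defining variant in one sample."""

    variant: Variant
    state: str  # derived | ancestral | missing | conflict
    depth_support: int = 0
    fraction: float = 0.0


ObservationMap = Dict[Tuple[str, int], SiteObservation]


def read_readcount_tsv(path: str) -> ObservationMap:
    """Parse the readcount table: chrom, pos, ref, depth, then per-base
    ``BASE:count:meanq`` columns for A, C, G, T."""
    out: ObservationMap = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ObservationError(f"{path}:{lineno}: expected >=8 fields")
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise ObservationError(f"{path}:{lineno}: bad position {pos_s!r}") from None
            counts: Dict[str, int] = {}
            meanq: Dict[str, float] = {}
            for col in fields[4:8]:
                parts = col.split(":")
                if len(parts) != 3 or parts[0].upper() not in BASES:
                    raise ObservationError(
                        f"{path}:{lineno}: bad base column {col!r} (want BASE:count:meanq)"
                    )
                base = parts[0].upper()
                try:
                    counts[base] = int(parts[1])
                    meanq[base] = float(parts[2])
                except ValueError:
                    raise ObservationError(f"{path}:{lineno}: bad numbers in {col!r}") from None
            key = (chrom, pos)
            if key in out:
                raise ObservationError(f"{path}:{lineno}: duplicate position {chrom}:{pos}")
            out[key] = SiteObservation(chrom=chrom, pos=pos, ref=ref, counts=counts, meanq=meanq)
    return out


def read_vcf_observations(path: str, sample: Optional[str] = None) -> ObservationMap:
    """Read per-site allelic depths for one sample from a VCF.

    Requires a per-sample ``AD`` FORMAT field; multi-allelic records must be
    split upstream and are rejected.  Qualities default to the record QUAL
    (or 30 when absent) for covered alleles — VCF does not carry per-allele
    mean base quality.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = vcf.samples
    if not samples:
        raise ObservationError(f"{path}: VCF has no sample columns")
    if sample is None:
        idx = 0
    else:
        if sample not in samples:
            raise ObservationError(f"{path}: sample {sample!r} not in VCF ({samples})")
        idx = samples.index(sample)

    out: ObservationMap = {}
    for rec in vcf:
        if len(rec.ALT) > 1:
            raise ObservationError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} — split upstream"
            )
        try:
            ad = rec.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            raise ObservationError(f"{path}: record {rec.CHROM}:{rec.POS} lacks FORMAT/AD")
        row = ad[idx]
        ref = rec.REF.upper()
        alt = rec.ALT[0].upper() if rec.ALT else None
        counts = {b: 0 for b in BASES}
        if ref in BASES:
            counts[ref] = max(int(row[0]), 0)
        if alt in BASES and len(row) > 1:
            counts[alt] = max(int(row[1]), 0)
        q = float(rec.QUAL) if rec.QUAL is not None else 30.0
        meanq = {b: (q if counts[b] > 0 else 0.0) for b in BASES}
        key = (rec.CHROM, rec.POS)
        if key in out:
            raise ObservationError(f"{path}: duplicate position {rec.CHROM}:{rec.POS}")
        out[key] = SiteObservation(rec.CHROM, rec.POS, ref=ref, counts=counts, meanq=meanq)
    return out


def read_observations(path: str, fmt: str = "auto", sample: Optional[str] = None) -> ObservationMap:
    """Dispatch on format: ``readcount_tsv``, ``vcf`` or ``auto`` (by suffix)."""
    if fmt == "auto":
        fmt = "vcf" if os.fspath(path).endswith((".vcf", ".vcf.gz")) else "readcount_tsv"
    if fmt == "readcount_tsv":
        return read_readcount_tsv(path)
    if fmt == "vcf":
        return read_vcf_observations(path, sample=sample)
    raise ValueError(f"unknown observation format {fmt!r}")


def call_state(
    obs: Optional[SiteObservation], variant: Variant, policy: CallPolicy
) -> AlleleCall:
    """Reduce one site to derived/ancestral/missing/conflict.

    The competition is between the variant's ancestral and derived alleles
    only; reads on other bases are treated as noise and ignored in the
    fraction but do not veto a call.
    """
    if obs is None:
        return AlleleCall(variant, MISSING)

    n_anc = obs.count(variant.anc)
    n_der = obs.count(variant.der)
    # quality gate: an allele with poor mean quality contributes nothing
    if n_anc > 0 and obs.quality(variant.anc) < policy.min_quality:
        n_anc = 0
    if n_der > 0 and obs.quality(variant.der) < policy.min_quality:
        n_der = 0
    total = n_anc + n_der
    if total == 0:
        return AlleleCall(variant, MISSING)

    frac_der = n_der / total
    frac_anc = n_anc / total
    if frac_der >= policy.min_major_fraction and n_der >= policy.min_depth:
        if (
            policy.damage_mode == "strict"
            and variant.is_deamination_pair
            and n_der < policy.min_depth_damage
        ):
            return AlleleCall(variant, MISSING, depth_support=n_der, fraction=frac_der)
        return AlleleCall(variant, DERIVED, depth_support=n_der, fraction=frac_der)
    if frac_anc >= policy.min_major_fraction and n_anc >= policy.min_depth:
        return AlleleCall(variant, ANCESTRAL, depth_support=n_anc, fraction=frac_anc)
    if n_anc > 0 and n_der > 0:
        return AlleleCall(variant, CONFLICT, depth_support=max(n_anc, n_der),
                          fraction=max(frac_anc, frac_der))
    # a single under-depth allele (min_depth > 1 configurations)
    return AlleleCall(variant, MISSING, depth_support=total, fraction=max(frac_anc, frac_der))


def call_sample(
    observations: ObservationMap,
    variants: Iterable[Variant],
    policy: CallPolicy,
) -> Dict[Tuple[str, int, str], AlleleCall]:
    """Call every variant for one sample, keyed by (chrom, pos, der)."""
    return {
        v.key: call_state(observations.get(v.site), v, policy) for v in variants
    }


@dataclass
class GenotypeMatrix:
    """Samples x variants matrix over {'1','0','?'} plus conflict bookkeeping."""

    table: pd.DataFrame  # index: sample, columns: variant key strings
    variants: List[Variant] = field(default_factory=list)
    n_conflicts: Dict[str, int] = field(default_factory=dict)

    @property
    def samples(self) -> List[str]:
        return list(self.table.index)


_STATE_TO_CODE = {DERIVED: "1", ANCESTRAL: "0", MISSING: "?", CONFLICT: "?"}


def variant_column(v: Variant) -> str:
    return f"{v.chrom}:{v.pos}:{v.anc}>{v.der}"


def genotype_matrix(
    samples: List[str],
    variants: List[Variant],
    calls_per_sample: Dict[str, Dict[Tuple[str, int, str], AlleleCall]],
) -> GenotypeMatrix:
    """Assemble the binary character matrix placement and clade discovery run on.

    Conflict calls map to '?' like missing, but are counted per sample as a
    contamination-like signal.
    """
    cols = [variant_column(v) for v in variants]
    rows = []
    n_conf: Dict[str, int] = {}
    for s in samples:
        calls = calls_per_sample.get(s, {})
        row = []
        conf = 0
        for v in variants:
            call = calls.get(v.key)
            if call is None:
                row.append("?")
            else:
                row.append(_STATE_TO_CODE[call.state])
                if call.state == CONFLICT:
                    conf += 1
        rows.append(row)
        n_conf[s] = conf
    table = pd.DataFrame(rows, index=list(samples), columns=cols, dtype="object")
    return GenotypeMatrix(table=table, variants=list(variants), n_conflicts=n_conf)
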
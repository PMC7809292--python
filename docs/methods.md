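# Methods

## Setting

The package infers patrilineal structure from very low coverage sequencing
data. Its unit of evidence is a single haplogroup-defining SNP observed in a
single sample: per-base read counts and mean base qualities at one position.
Everything downstream — placement on a reference haplotree, discovery of new
clades, coalescence dating, sex assignment — is assembled from these per-site
states plus a handful of cohort-level combinatorics. The pipeline's stages
run in the order observations → placement → clade discovery → chronology →
sex/kinship, and the synthetic-data generator can produce every input.

## Allele calling

Each site is reduced to derived / ancestral / missing / conflict under a
`CallPolicy`:

| parameter | default | unit | rationale |
|---|---|---|---|
| `min_depth` | 1 | reads | genomes at 0.2× must contribute single-read calls |
| `min_quality` | 20 | phred (mean per allele) | standard post-rescaling floor |
| `min_major_fraction` | 0.7 | fraction of anc+der reads | a 50/50 site is contamination-like, not a call |
| `damage_mode` | `off` | — | `strict` demands `min_depth_damage` (2) reads for derived C→T/G→A calls |

Only the variant's two alleles compete; reads on the other bases are ignored
as noise rather than treated as a veto. Conflict (both alleles present, no
qualifying majority) is kept distinct from missing so placement can surface
contamination-like signals. The competition denominator is anc+der reads,
which makes the call monotone in derived evidence — adding derived reads can
never demote a derived call (a property the test suite checks by hypothesis).

The damage gate is deliberately crude: it does not model fragment-end
position or damage probability, it simply refuses to trust a single C→T or
G→A read. That is the operational decision that matters at 0.2–2×: such
calls are exactly where post-mortem deamination manufactures false derived
states.

## Placement

Descent rule: a child branch is supported iff it has ≥ 1 derived call and
more derived than ancestral calls; among several supported children the
higher derived fraction (derived / observed) wins; an exact tie stops
descent and is reported as ambiguity, because resolving it is a curator's
job, not a coin flip. Siblings and stop-point children with ≥ 1 ancestral
call are reported as excluded — at these coverages the ancestral calls that
rule branches *out* carry much of the information.

One extension beyond the basic rule: a child branch with *no observed calls
at all* is transparent, and descent passes through it when exactly one such
child's subtree carries derived support. Without this, a structural node
(zero defining variants) or a short branch that happened to accumulate no
SNPs would block placement below it no matter how much derived evidence
exists further down; with it, placement on clean complete data provably
reaches the generating terminal. Transparent branches still count as
unobserved in the path-QC fraction.

## Clade discovery

Input: off-tree variants, each partitioning the cohort into carriers,
confident non-carriers, and unknowns. Assumptions: no recombination (Y),
and — to first order — no recurrent mutation, so true carrier sets form a
laminar family (pairwise nested or disjoint).

The algorithm:

1. Drop variants failing the rooted three-gamete test pairwise (carriers of
   both, plus carriers of each inside the other's non-carriers), greedily
   removing fewest-carrier variants first; recurrent mutations tend to look
   private.
2. Cluster the rest into could-be-equal groups: a variant joins a group when
   none of its carriers are confident non-carriers of the group and vice
   versa. Unknowns are jokers. Groups are seeded largest-first.
3. Order groups into a laminar forest by containment; members of nested
   groups propagate upward, so a sample unobserved at every parent-level
   variant still counts as a parent member through its child membership.
   This is what lets a 2× genome that missed most clade-defining sites keep
   its clade assignment: only a confident ancestral call inside the clade
   can evict it.
4. Conflicts that only materialise after carrier-set unioning (invisible to
   the pairwise test) are resolved by a final loop that drops the
   fewest-carrier variant of an offending clade pair and rebuilds, so the
   output is always laminar even on adversarial input.
5. Clades with fewer than `min_support` variants (default 1 — a genuinely
   private lineage can rest on one sample's SNPs) dissolve into their
   parent.

Identifiability caveat: when every state that distinguishes a parent clade
from a nested child is unknown, the assignment of a variant between them is
ambiguous in principle; the recovery tests therefore mask under conditions
(one fully observed member per clade and per nested-pair difference) where
the generating partition is provably the unique answer.

Discovered clades are grafted below the single terminal haplogroup shared by
all members (members on different backbone branches are an error, not a
merge), with auto-names `NOVEL-1…` unless curated names are supplied.

## Chronology

SNP-count clock: one new SNP per lineage per μ years, with μ ∈ [100, 150]
for the ~10 Mb callable region; only in-mask SNPs are counted (`k_b` per
branch). Mask coordinates are 0-based half-open (BED); variant positions are
1-based; the membership test converts explicitly because a silent off-by-one
here is the classic failure mode.

Two modes:

* `anchor_path`: rate = anchor_age / D, with D the SNP distance from the
  anchor to the present — mean over descendant tips (rho-style, the default)
  or a single designated tip path (`single_path`, which reproduces printed
  single-lineage arithmetic). Node age = rate × the node's own tip distance.
  The calibration identity age(anchor) = anchor_age holds exactly.
* `fixed_interval`: age ∈ [k·μ_min, k·μ_max], point estimate at the
  midpoint; no anchor needed.

Each node carries both a *split age* (SNP distance strictly below the node)
and an *appearance age* (split age plus the node's own branch): a sampled
leaf haplogroup has split age 0 but a meaningful appearance age — e.g. a
9-SNP private branch at μ = 100 appeared ≈ 900 years ago. Ages are clamped
non-increasing from root to tips; the clamp can only fire when tip SNP
distances are non-monotone across sibling subtrees (heterogeneous sampling
or sequencing depth), never on clean data. Uncertainty is reported only as
the μ-interval envelope — there is no Poisson CI and no rate heterogeneity
model, by design.

## Sex and kinship

R_y = n_Y/(n_X+n_Y) with thresholds t_male = 0.075, t_female = 0.016
(configuration, not constants). The statistic is scale-invariant, so
published average chromosome coverages substitute for raw read counts — a
documented approximation that ignores the two chromosomes' different
mappable lengths, which cancel only approximately.

Kinship verdicts are pure exclusion logic over uniparental labels
(mother–child, full sibling, father–son, paternal grandfather–grandson,
same paternal/maternal lineage), with father-side relationships
inapplicable unless both samples carry a Y label. Label comparison is
string equality on the terminal assigned clade; harmonising a deep call
with a shallow call of the same lineage is placement's job, upstream.

## Synthetic data

The generator emulates the study design the pipeline targets:

* a dated binary genealogy (root split at `root_age`, default 4500 years —
  the time depth of the clades of interest; other splits uniform in time),
* Poisson branch mutations at `snp_interval_mu` (default 120 years/SNP, the
  interval midpoint), placed collision-free and uniformly in the mask, with
  a 2:1 transition bias,
* per-site read depth ~ Poisson(`mean_depth`), per-read error
  (`seq_error_rate`, default 10⁻³), per-read C→T/G→A damage (`damage_rate`,
  default 0.1 — the order of magnitude seen in unrepaired ancient libraries
  after quality rescaling), optional extra site dropout,
* X/Y read counts: an XY sample splits sex-chromosome reads evenly between
  the haploid X and Y; an XX sample puts them on X bar an error floor,
* `hidden_clades`: named nodes spliced out of the emitted reference tree so
  their variants become off-tree — the novel-haplogroup discovery scenario.

The default simulation mask is a 100 kb toy region rather than 10 Mb so
end-to-end tests run in seconds; scale is a config knob and nothing in the
code depends on the mask's size. All randomness flows through one seeded
generator; a fixed seed gives bit-identical files.

What the generator does **not** model: fragment-end damage profiles (damage
is uniform per read at C/G sites), contamination from other individuals,
mapping bias, reference bias, indels, and coalescent population dynamics
(the genealogy is a fixed tree, not a population sample). Passing tests on
synthetic data therefore demonstrate the pipeline's combinatorics and
calibration arithmetic, not robustness to every artefact of real ancient
libraries.

Test problem sizes were chosen to keep the full suite under a minute while
leaving the statistical checks meaningful: 100-sample cohorts for placement
recovery, 100 replicates for dating unbiasedness (2 SE), 500 replicates for
the Poisson goodness-of-fit, exhaustive oracle comparison up to 6 samples ×
12 variants.

## Known limitations

* Placement is rule-based, not probabilistic: no likelihoods, no
  contamination deconvolution, no posterior over terminals.
* Clade discovery resolves homoplasy greedily (fewest carriers first); with
  substantial recurrent mutation the drop set is not guaranteed minimal.
* The clock treats SNP counts as exact; branches with few SNPs have large
  Poisson noise that the μ-envelope does not capture.
* VCF ingestion requires per-sample allelic depths (FORMAT/AD) and
  biallelic records; readcount tables are the richer input (they keep all
  four base counts).
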
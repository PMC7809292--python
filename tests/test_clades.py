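import itertools

import numpy as np
import pandas as pd
import pytest

from ylineage.clades import (
    NovelVariant,
    attach_clades,
    collect_novel_variants,
    four_gamete_check,
    partition_clades,
)
from ylineage.haplotree import Variant, parse_haplotree, path_to_root
from ylineage.observations import GenotypeMatrix
from ylineage.placement import Placement

from conftest import variant_specs


def nv(pos, carriers, noncarriers, unknown=()):
    return NovelVariant(
        Variant("chrY", pos, "A", "G", (f"S{pos}",)),
        frozenset(carriers),
        frozenset(noncarriers),
        frozenset(unknown),
    )


def matrix_from_rows(samples, variants, rows):
    table = pd.DataFrame(
        [list(r) for r in rows], index=samples,
        columns=[f"{v.chrom}:{v.pos}:{v.anc}>{v.der}" for v in variants],
        dtype="object",
    )
    return GenotypeMatrix(table=table, variants=list(variants))


# ---------------------------------------------------------------------------
# exhaustive oracle: enumerate every laminar clade assignment consistent with
# the confident states, by backtracking over candidate member subsets
# ---------------------------------------------------------------------------

def enumerate_laminar_assignments(variants, samples):
    all_subsets = [
        frozenset(c)
        for r in range(1, len(samples) + 1)
        for c in itertools.combinations(sorted(samples), r)
    ]
    options = [
        [S for S in all_subsets if v.carriers <= S and not (S & v.noncarriers)]
        for v in variants
    ]
    results = []

    def backtrack(i, assigned):
        if i == len(variants):
            results.append(tuple(assigned))
            return
        for S in options[i]:
            if all(S <= T or T <= S or not (S & T) for T in assigned):
                backtrack(i + 1, assigned + [S])

    backtrack(0, [])
    return results


def random_laminar_cohort(rng, n_samples, n_variants):
    """Random sample hierarchy plus variants assigned to its clades."""
    samples = [f"s{i}" for i in range(n_samples)]
    # random binary hierarchy via recursive splits
    clades = [frozenset(samples)]

    def split(group):
        if len(group) < 2 or rng.random() < 0.3:
            return
        members = sorted(group)
        k = int(rng.integers(1, len(members)))
        left, right = frozenset(members[:k]), frozenset(members[k:])
        for part in (left, right):
            clades.append(part)
            split(part)

    split(frozenset(samples))
    assignment = [clades[int(rng.integers(len(clades)))] for _ in range(n_variants)]
    variants = []
    for i, clade in enumerate(assignment):
        variants.append(nv(1000 + i, clade, frozenset(samples) - clade))
    return samples, variants, assignment


class TestCollectNovel:
    def test_tree_sites_are_never_novel(self, backbone_tree):
        vs = backbone_tree.variants()[:2]
        m = matrix_from_rows(["a", "b"], vs, ["11", "10"])
        assert collect_novel_variants(m, backbone_tree) == []

    def test_shared_off_tree_sites_collected(self, backbone_tree):
        vs = [Variant("chrY", 9000 + i, "A", "G", (f"N{i}",)) for i in range(9)]
        rows = ["1" * 9, "1" * 9, "1" * 9, "0" * 9]
        m = matrix_from_rows(["bela", "hu52", "serb", "bash"], vs, rows)
        novel = collect_novel_variants(m, backbone_tree)
        assert len(novel) == 9
        assert all(v.carriers == {"bela", "hu52", "serb"} for v in novel)
        assert all(v.noncarriers == {"bash"} for v in novel)

    def test_zero_carrier_sites_excluded(self, backbone_tree):
        vs = [Variant("chrY", 9000, "A", "G", ("N0",))]
        m = matrix_from_rows(["a", "b"], vs, ["0", "?"])
        assert collect_novel_variants(m, backbone_tree) == []


class TestPartition:
    def test_royal_cohort_pattern(self):
        """Sharing pattern of the 51-sample cohort: 17 SNPs carried by all,
        6 by the 48 Bashkirs, 9 by the two dynasty members plus the Serbian,
        9 private to the Serbian -> four nested clades 51/48/3/1."""
        bashkirs = {f"bash{i}" for i in range(48)}
        arpads = {"bela", "hu52", "serb"}
        cohort = bashkirs | arpads
        pos = itertools.count(1000)
        variants = (
            [nv(next(pos), cohort, set()) for _ in range(17)]
            + [nv(next(pos), bashkirs, cohort - bashkirs) for _ in range(6)]
            + [nv(next(pos), arpads, cohort - arpads) for _ in range(9)]
            + [nv(next(pos), {"serb"}, cohort - {"serb"}) for _ in range(9)]
        )
        part = partition_clades(variants)
        stats = sorted((c.n_members, c.n_variants) for c in part.clades)
        assert stats == [(1, 9), (3, 9), (48, 6), (51, 17)]
        assert part.is_laminar()
        by_members = {c.n_members: c for c in part.clades}
        assert by_members[48].parent == by_members[51].name
        assert by_members[3].parent == by_members[51].name
        assert by_members[1].parent == by_members[3].name
        assert not part.dropped_variants

    def test_universal_variants_form_one_clade(self):
        variants = [nv(1000 + i, {"a", "b", "c"}, set()) for i in range(5)]
        part = partition_clades(variants)
        assert len(part.clades) == 1
        assert part.clades[0].n_variants == 5
        assert part.clades[0].members == {"a", "b", "c"}

    def test_empty_input(self):
        part = partition_clades([])
        assert part.clades == [] and part.dropped_variants == []

    def test_unknowns_never_veto_membership(self):
        """A low-coverage sample missing most clade sites still joins through
        the sites it was observed at."""
        variants = [
            nv(1000, {"bela", "serb"}, {"x"}, {"hu52"}),
            nv(1001, {"hu52", "serb"}, {"x"}, {"bela"}),
            nv(1002, {"serb"}, {"x"}, {"bela", "hu52"}),
        ]
        part = partition_clades(variants)
        assert len(part.clades) == 1
        assert part.clades[0].members == {"bela", "hu52", "serb"}

    def test_homoplasy_dropped_greedily(self):
        variants = [
            nv(1000, {"a", "b"}, {"c", "d"}),
            nv(1001, {"c", "d"}, {"a", "b"}),
            nv(1002, {"b", "c"}, {"a", "d"}),  # recurrent mutation
        ]
        part = partition_clades(variants)
        assert len(part.dropped_variants) == 1
        dropped, reason = part.dropped_variants[0]
        assert dropped.variant.pos == 1002 and reason == "incompatible"
        assert {c.members for c in part.clades} == {frozenset("ab"), frozenset("cd")}

    def test_min_support_dissolves_weak_clades(self):
        variants = [nv(1000, {"a", "b", "c"}, {"d"}), nv(1001, {"a", "b", "c"}, {"d"}),
                    nv(1002, {"a"}, {"b", "c", "d"})]
        part = partition_clades(variants, min_support=2)
        assert len(part.clades) == 1
        assert any(r == "below_min_support" for _, r in part.dropped_variants)

    def test_output_always_laminar_on_random_noise(self):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(8)]
        for _ in range(25):
            variants = []
            for i in range(10):
                states = rng.integers(0, 3, size=8)  # 0,1,? at random (homoplasy likely)
                carriers = {s for s, st in zip(samples, states) if st == 1}
                if not carriers:
                    continue
                nonc = {s for s, st in zip(samples, states) if st == 0}
                unk = set(samples) - carriers - nonc
                variants.append(nv(1000 + i, carriers, nonc, unk))
            if variants:
                assert partition_clades(variants).is_laminar()


class TestOracleEquivalence:
    def test_fully_observed_matches_exhaustive_search(self):
        """On homoplasy-free fully observed cohorts (<=6 samples, <=12
        variants) the partition equals the generating clades and is among the
        laminar assignments found by exhaustive subset search."""
        rng = np.random.default_rng(42)
        for rep in range(20):
            n_s = int(rng.integers(3, 7))
            n_v = int(rng.integers(2, 13))
            samples, variants, assignment = random_laminar_cohort(rng, n_s, n_v)
            part = partition_clades(variants)
            # recovered grouping == generating grouping
            got = {}
            for c in part.clades:
                for v in c.variants:
                    got[v.variant.pos] = frozenset(c.members)
            want = {v.variant.pos: clade for v, clade in zip(variants, assignment)}
            assert got == want
            # and it is one of the oracle's valid laminar assignments
            valid = enumerate_laminar_assignments(variants, samples)
            ours = tuple(got[v.variant.pos] for v in variants)
            assert ours in valid

    def test_masked_cohort_recovers_generating_clades(self):
        """Random masking (unknowns) leaving each clade one fully observed
        carrier and each member one observed site per clade still yields the
        exact generating partition."""
        rng = np.random.default_rng(43)
        for rep in range(15):
            n_s = int(rng.integers(4, 7))
            n_v = int(rng.integers(3, 13))
            samples, variants, assignment = random_laminar_cohort(rng, n_s, n_v)
            # group variants by generating clade
            groups = {}
            for v, clade in zip(variants, assignment):
                groups.setdefault(clade, []).append(v)
            # mask ~30% of confident states, then repair the guarantees:
            # keep fully observed one member per clade and one member of
            # every nested-pair difference D\C, so each variant retains the
            # confident states distinguishing its clade from the others
            masked = []
            protected = {min(clade) for clade in groups}
            for c in groups:
                for d in groups:
                    if c < d:
                        protected.add(min(d - c))
            for v, clade in zip(variants, assignment):
                carriers, nonc, unk = set(v.carriers), set(v.noncarriers), set()
                for s in list(carriers | nonc):
                    if s in protected:
                        continue
                    if rng.random() < 0.3:
                        (carriers if s in carriers else nonc).discard(s)
                        unk.add(s)
                masked.append(nv(v.variant.pos, carriers or {min(clade)},
                                 nonc, unk - (carriers or {min(clade)})))
            # each member observed at >=1 site of its clade
            repaired = []
            for clade, vs in groups.items():
                idxs = [variants.index(v) for v in vs]
                for s in clade:
                    if all(s not in masked[i].carriers for i in idxs):
                        i = idxs[0]
                        m = masked[i]
                        masked[i] = nv(m.variant.pos, set(m.carriers) | {s},
                                       m.noncarriers, set(m.unknown) - {s})
            part = partition_clades(masked)
            got = {
                (frozenset(c.members), frozenset(v.variant.pos for v in c.variants))
                for c in part.clades
            }
            want = {
                (clade, frozenset(v.variant.pos for v in vs))
                for clade, vs in groups.items()
            }
            assert got == want


class TestAttach:
    def _partition_17_6_9_9(self):
        bashkirs = {f"bash{i}" for i in range(48)}
        arpads = {"bela", "hu52", "serb"}
        cohort = bashkirs | arpads
        pos = itertools.count(1000)
        variants = (
            [nv(next(pos), cohort, set()) for _ in range(17)]
            + [nv(next(pos), bashkirs, cohort - bashkirs) for _ in range(6)]
            + [nv(next(pos), arpads, cohort - arpads) for _ in range(9)]
            + [nv(next(pos), {"serb"}, cohort - {"serb"}) for _ in range(9)]
        )
        return partition_clades(variants), cohort

    def test_grafts_nested_topology_below_terminal(self):
        tree = parse_haplotree(
            "R-Y2632\t-\t" + variant_specs(100, 1) + "\nR-Y2633\tR-Y2632\t" + variant_specs(200, 1)
        )
        part, cohort = self._partition_17_6_9_9()
        placements = [Placement(sample=s, terminal="R-Y2633", path=[]) for s in cohort]
        names = {"NOVEL-1": "R-SUR51", "NOVEL-2": "R-BASH", "NOVEL-3": "R-ARP",
                 "NOVEL-4": "R-UVD"}
        attach_clades(tree, part, placements, names=names)
        assert [n.name for n in path_to_root(tree, "R-UVD")] == [
            "R-Y2632", "R-Y2633", "R-SUR51", "R-ARP", "R-UVD"
        ]
        assert {c.name for c in tree.by_name["R-SUR51"].children} == {"R-BASH", "R-ARP"}
        assert len(tree.by_name["R-SUR51"].defining_variants) == 17
        assert len(tree.by_name["R-UVD"].defining_variants) == 9

    def test_empty_partition_leaves_tree_unchanged(self, backbone_tree):
        from ylineage.clades import CladePartition

        before = set(backbone_tree.by_name)
        attach_clades(backbone_tree, CladePartition(), [])
        assert set(backbone_tree.by_name) == before

    def test_members_on_different_terminals_rejected(self):
        tree = parse_haplotree("A\t-\t10:A:C:x\nB\tA\t20:A:C:y\nC\tA\t30:A:C:z")
        part = partition_clades([nv(1000, {"s1", "s2"}, set())])
        placements = [
            Placement(sample="s1", terminal="B", path=[]),
            Placement(sample="s2", terminal="C", path=[]),
        ]
        with pytest.raises(ValueError, match="multiple backbone terminals"):
            attach_clades(tree, part, placements)


class TestFourGametes:
    def test_clean_matrix_passes(self):
        vs = [Variant("chrY", 1000 + i, "A", "G", (f"N{i}",)) for i in range(3)]
        m = matrix_from_rows(["a", "b", "c"], vs, ["111", "110", "100"])
        assert four_gamete_check(m) == []

    def test_recurrent_mutation_detected(self):
        vs = [Variant("chrY", 1000 + i, "A", "G", (f"N{i}",)) for i in range(2)]
        m = matrix_from_rows(["a", "b", "c", "d"], vs, ["11", "10", "01", "00"])
        pairs = four_gamete_check(m)
        assert len(pairs) == 1

    def test_unknowns_do_not_count_as_gametes(self):
        vs = [Variant("chrY", 1000 + i, "A", "G", (f"N{i}",)) for i in range(2)]
        m = matrix_from_rows(["a", "b", "c", "d"], vs, ["11", "10", "01", "?0"])
        assert four_gamete_check(m) == []

    def test_single_site_trivially_compatible(self):
        vs = [Variant("chrY", 1000, "A", "G", ("N0",))]
        m = matrix_from_rows(["a", "b"], vs, ["1", "0"])
        assert four_gamete_check(m) == []
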
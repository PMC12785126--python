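"""Venn intersection, up/down tallies, cis target calls, enrichment."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from adipolnc.diffexp import Contrast, call_degs, run_contrast
from adipolnc.integration import (
    CisTargetCall,
    assign_cis_target,
    enrich,
    hypergeom_upper_tail,
    intersect_contrasts,
    updown_table,
)
from adipolnc.models import GenomeAnnotation
from adipolnc.synthetic_data import simulate_nb_counts

from test_annotation_io import make_transcript


class TestIntersectContrasts:
    def test_worked_example(self):
        venn = intersect_contrasts(
            {"x": {"a", "b", "c"}, "y": {"b", "c"}, "z": {"c"}}
        )
        assert venn.common == {"c"}
        assert venn.union_size == 3
        assert venn.regions[frozenset({"x"})] == {"a"}
        assert venn.regions[frozenset({"x", "y"})] == {"b"}
        assert venn.regions[frozenset({"x", "y", "z"})] == {"c"}

    def test_identical_sets(self):
        s = {"p", "q"}
        venn = intersect_contrasts({"x": set(s), "y": set(s)})
        assert venn.common == s
        assert venn.region_sizes() == {frozenset({"x", "y"}): 2}

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            intersect_contrasts({"x": {"a"}})

    def test_matches_brute_force_membership_enumeration(self):
        rng = np.random.default_rng(31)
        universe = [f"g{i}" for i in range(60)]
        for _ in range(20):
            sets = {
                name: {g for g in universe if rng.random() < 0.4}
                for name in ("A", "B", "C")
            }
            if any(len(s) == 0 for s in sets.values()):
                continue
            venn = intersect_contrasts(sets)
            union = set().union(*sets.values())
            assert venn.union_size == len(union)
            for g in union:
                key = frozenset(n for n, s in sets.items() if g in s)
                assert g in venn.regions[key]
            assert all(venn.common <= s for s in sets.values())


class TestUpdownTable:
    def result_frame(self, directions):
        frame = pd.DataFrame(
            {
                "significant": [d != "ns" for d in directions],
                "direction": list(directions),
            },
            index=[f"f{i}" for i in range(len(directions))],
        )
        return frame.astype({"significant": bool})

    def test_empty_results(self):
        table = updown_table({"c1": self.result_frame([])})
        assert table.loc["c1", "n_up"] == 0
        assert table.loc["c1", "n_down"] == 0

    def test_up_down_partition_sums_to_significant(self):
        res = self.result_frame(["up", "up", "down", "ns"])
        table = updown_table({"c": res}, lncrna_ids={"f0"})
        assert table.loc["c", "n_up"] == 2
        assert table.loc["c", "n_down"] == 1
        assert table.loc["c", "n_up_lncrna"] == 1
        assert (
            table.loc["c", "n_up"] + table.loc["c", "n_down"]
            == res["significant"].sum()
        )

    def test_swapping_contrast_orientation_swaps_counts(self):
        rng = np.random.default_rng(4)
        lfc = np.zeros(500)
        lfc[:40] = 3.0
        lfc[40:60] = -3.0
        counts = simulate_nb_counts(rng, 500, [3, 3], dispersion=0.1, lfc=lfc)
        c = Contrast("fwd", tuple(counts.columns[:3]), tuple(counts.columns[3:]))
        fwd = run_contrast(counts, c)
        rev = run_contrast(counts, c.swapped())
        t = updown_table({"fwd": fwd, "fwd_swapped": rev})
        assert t.loc["fwd", "n_up"] == t.loc["fwd_swapped", "n_down"]
        assert t.loc["fwd", "n_down"] == t.loc["fwd_swapped", "n_up"]

    def test_recovers_planted_updown_counts(self):
        # 30 up- and 20 down-regulated features with large planted effects
        # on well-expressed features, so recovery is unambiguous
        rng = np.random.default_rng(19)
        lfc = np.zeros(800)
        lfc[:30] = 3.0
        lfc[30:50] = -3.0
        counts = simulate_nb_counts(
            rng, 800, [3, 3], dispersion=0.05, log_mean=6.0, log_sd=0.5, lfc=lfc
        )
        c = Contrast("p", tuple(counts.columns[:3]), tuple(counts.columns[3:]))
        res = run_contrast(counts, c)
        planted_lncrnas = set(counts.index[:50])
        table = updown_table({"p": res}, lncrna_ids=planted_lncrnas)
        assert table.loc["p", "n_up_lncrna"] == 30
        assert table.loc["p", "n_down_lncrna"] == 20


def gene(gid, start, end, strand="+", chrom="chr1"):
    return make_transcript(
        gid + "_t", [(start, end)], strand=strand, chrom=chrom, status="coding"
    )


class TestAssignCisTarget:
    def test_downstream_antisense_configuration(self):
        # coding gene on + spanning 10,000-20,000; lncRNA on - at
        # 21,000-22,000: the Hsd17b12-style geometry
        coding = GenomeAnnotation([gene("G", 10_000, 20_000, "+")])
        lnc = make_transcript("L", [(21_000, 22_000)], strand="-")
        call = assign_cis_target(lnc, coding)
        assert call.relative_position == "downstream"
        assert call.relative_strand == "antisense"
        assert call.distance == 1000

    def test_upstream_sense_configuration(self):
        # lncRNA on + at 5,000-6,000 before a + gene: Sfswap-style
        coding = GenomeAnnotation([gene("G", 10_000, 20_000, "+")])
        lnc = make_transcript("L", [(5_000, 6_000)], strand="+")
        call = assign_cis_target(lnc, coding)
        assert call.relative_position == "upstream"
        assert call.relative_strand == "sense"
        assert call.distance == 4000

    def test_minus_strand_gene_flips_positional_labels(self):
        coding = GenomeAnnotation([gene("G", 10_000, 20_000, "-")])
        right = make_transcript("L", [(21_000, 22_000)], strand="-")
        assert assign_cis_target(right, coding).relative_position == "upstream"
        left = make_transcript("L2", [(5_000, 6_000)], strand="-")
        assert assign_cis_target(left, coding).relative_position == "downstream"

    def test_overlapping_call(self):
        coding = GenomeAnnotation([gene("G", 10_000, 20_000)])
        lnc = make_transcript("L", [(15_000, 15_500)], strand="-")
        call = assign_cis_target(lnc, coding)
        assert call.relative_position == "overlapping"
        assert call.distance == 0

    def test_out_of_window_returns_none(self):
        coding = GenomeAnnotation([gene("G", 500_000, 510_000)])
        lnc = make_transcript("L", [(0, 1000)])
        assert assign_cis_target(lnc, coding, max_distance=100_000) is None

    def test_translation_invariance(self):
        shift = 37_000
        coding1 = GenomeAnnotation([gene("G", 10_000, 20_000, "+")])
        coding2 = GenomeAnnotation(
            [gene("G", 10_000 + shift, 20_000 + shift, "+")]
        )
        l1 = make_transcript("L", [(21_000, 22_000)], strand="-")
        l2 = make_transcript("L", [(21_000 + shift, 22_000 + shift)], strand="-")
        c1, c2 = assign_cis_target(l1, coding1), assign_cis_target(l2, coding2)
        assert (c1.relative_position, c1.relative_strand, c1.distance) == (
            c2.relative_position, c2.relative_strand, c2.distance,
        )

    def test_flipping_both_strands_preserves_relative_strand(self):
        coding_p = GenomeAnnotation([gene("G", 10_000, 20_000, "+")])
        coding_m = GenomeAnnotation([gene("G", 10_000, 20_000, "-")])
        lnc_m = make_transcript("L", [(21_000, 22_000)], strand="-")
        lnc_p = make_transcript("L", [(21_000, 22_000)], strand="+")
        assert (
            assign_cis_target(lnc_m, coding_p).relative_strand
            == assign_cis_target(lnc_p, coding_m).relative_strand
        )

    def test_distance_tie_breaks_lexicographically(self):
        coding = GenomeAnnotation(
            [gene("GB", 30_000, 31_000), gene("GA", 24_000, 25_000)]
        )
        lnc = make_transcript("L", [(27_000, 28_000)])
        # both genes are 2,000 bp away; g_GA_t < g_GB_t lexicographically
        assert assign_cis_target(lnc, coding).target_gene_id == "g_GA_t"

    def test_overlap_distance_invariant(self):
        with pytest.raises(ValueError):
            CisTargetCall("l", "g", "overlapping", "sense", 5)


def brute_force_hypergeom(k, N, K, n):
    total = math.comb(N, n)
    return sum(
        math.comb(K, kk) * math.comb(N - K, n - kk)
        for kk in range(k, min(K, n) + 1)
    ) / total


class TestEnrich:
    def test_worked_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        term_genes = {f"g{i}" for i in range(5)}
        query = {f"g{i}" for i in range(4)}
        res = enrich(query, {"T": term_genes}, universe)
        assert res.loc[0, "p"] == pytest.approx(5 / 210)

    def test_term_covering_universe_has_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        res = enrich({"g0", "g3"}, {"T": set(universe)}, universe)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_terms_without_hits_skipped(self):
        universe = {"a", "b", "c", "d"}
        res = enrich({"a"}, {"T1": {"a", "b"}, "T2": {"c", "d"}}, universe)
        assert list(res["term_id"]) == ["T1"]

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            enrich({"zzz"}, {"T": {"a"}}, {"a", "b"})

    def test_random_instances_match_combinatorial_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            N = int(rng.integers(2, 21))
            universe = {f"g{i}" for i in range(N)}
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(list(universe)[:K])
            query = set(rng.choice(sorted(universe), size=n, replace=False))
            k = len(term & query)
            if k == 0:
                continue
            res = enrich(query, {"T": term}, universe)
            assert res.loc[0, "p"] == pytest.approx(
                brute_force_hypergeom(k, N, K, n)
            )

    def test_p_monotone_nonincreasing_in_k(self):
        for N, K, n in [(20, 8, 10), (15, 5, 5)]:
            ps = [
                hypergeom_upper_tail(k, N, K, n)
                for k in range(0, min(K, n) + 1)
            ]
            assert all(a >= b for a, b in zip(ps, ps[1:]))
            assert all(0 < p <= 1 for p in ps)
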
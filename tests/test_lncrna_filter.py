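"""The novelty cascade: FPKM math, strict boundaries, overlap/distance
filters (with brute-force oracles), and planted-truth recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from adipolnc.expression import ExpressionError, ExpressionMatrix
from adipolnc.lncrna_filter import (
    REASON_EXON_OVERLAP,
    REASON_LOW_FPKM,
    REASON_NEAR_SINGLE_EXON,
    REASON_SHORT,
    FilterThresholds,
    compute_fpkm,
    filter_known_overlap,
    filter_length_fpkm,
    filter_single_exon_distance,
    identify_novel_lncrnas,
)
from adipolnc.models import GenomeAnnotation

from test_annotation_io import make_transcript


def matrix(data, samples=("s1", "s2")):
    frame = pd.DataFrame(data, columns=list(samples))
    return ExpressionMatrix(counts=frame, sample_groups={"g": list(samples)})


class TestComputeFpkm:
    def test_closed_form(self):
        em = matrix({"s1": [50, 999_950]}, samples=("s1",))
        em.counts.index = ["t", "filler"]
        fpkm = compute_fpkm(em, {"t": 2000, "filler": 1000})
        # 50 / (2 kb * 1M/1e6) = 25
        assert fpkm.loc["t", "s1"] == pytest.approx(25.0)

    def test_zero_count_gives_zero(self):
        em = matrix({"s1": [0, 10]}, samples=("s1",))
        em.counts.index = ["a", "b"]
        assert compute_fpkm(em, {"a": 500, "b": 500}).loc["a", "s1"] == 0.0

    def test_three_transcript_hand_check(self):
        counts = pd.DataFrame(
            {"s1": [10, 20, 70], "s2": [5, 5, 90]}, index=["a", "b", "c"]
        )
        em = ExpressionMatrix(counts=counts, sample_groups={"g": ["s1", "s2"]})
        lengths = {"a": 500, "b": 1000, "c": 2000}
        fpkm = compute_fpkm(em, lengths)
        for t, s in [("a", "s1"), ("b", "s1"), ("c", "s2")]:
            total = counts[s].sum()
            expect = counts.loc[t, s] / ((lengths[t] / 1000) * (total / 1e6))
            assert fpkm.loc[t, s] == pytest.approx(expect)

    def test_doubling_a_column_preserves_its_fpkm(self):
        counts = pd.DataFrame({"s1": [10, 30], "s2": [20, 20]}, index=["a", "b"])
        em1 = ExpressionMatrix(counts=counts, sample_groups={"g": ["s1", "s2"]})
        em2 = ExpressionMatrix(
            counts=counts.assign(s1=counts["s1"] * 2),
            sample_groups={"g": ["s1", "s2"]},
        )
        lengths = {"a": 500, "b": 800}
        assert np.allclose(
            compute_fpkm(em1, lengths)["s1"], compute_fpkm(em2, lengths)["s1"]
        )

    def test_zero_library_size_names_sample(self):
        em = matrix({"s1": [0, 0], "s2": [1, 1]})
        em.counts.index = ["a", "b"]
        with pytest.raises(ExpressionError, match="s1"):
            compute_fpkm(em, {"a": 100, "b": 100})


class TestLengthFpkmBoundaries:
    def run(self, length, fpkm_row):
        t = make_transcript("t", [(0, length)])
        fpkm = pd.DataFrame([fpkm_row], index=["t"])
        return filter_length_fpkm([t], fpkm)["t"]

    def test_length_exactly_200_fails(self):
        assert REASON_SHORT in self.run(200, [5.0, 5.0])

    def test_length_201_one_sample_above_passes(self):
        assert self.run(201, [0.4, 0.6]) == []

    def test_fpkm_exactly_half_fails(self):
        assert REASON_LOW_FPKM in self.run(201, [0.5, 0.5])

    def test_missing_candidate_rejected(self):
        t = make_transcript("absent", [(0, 300)])
        with pytest.raises(KeyError):
            filter_length_fpkm([t], pd.DataFrame({"s": [1.0]}, index=["other"]))


class TestOverlapFilter:
    def known(self, exons, strand="+", status="coding"):
        return GenomeAnnotation(
            [make_transcript("k", exons, strand=strand, status=status)]
        )

    def test_one_bp_overlap_fails(self):
        # 1-based 100-200 vs 200-300 share exactly base 200
        cand = make_transcript("c", [(99, 200)])
        res = filter_known_overlap([cand], self.known([(199, 300)]))
        assert res["c"] == [REASON_EXON_OVERLAP]

    def test_adjacency_is_not_overlap(self):
        cand = make_transcript("c", [(99, 200)])
        assert filter_known_overlap([cand], self.known([(200, 300)]))["c"] == []

    def test_known_exon_inside_candidate_intron_passes(self):
        cand = make_transcript("c", [(0, 100), (499, 600)])
        assert filter_known_overlap([cand], self.known([(199, 300)]))["c"] == []

    def test_antisense_overlap_fails_by_default_but_not_stranded(self):
        cand = make_transcript("c", [(100, 200)], strand="+")
        known = self.known([(150, 250)], strand="-")
        assert filter_known_overlap([cand], known)["c"] == [REASON_EXON_OVERLAP]
        thr = FilterThresholds(stranded_overlap=True)
        assert filter_known_overlap([cand], known, thr)["c"] == []


class TestDistanceFilter:
    def single_exon_at(self, start, end):
        return GenomeAnnotation(
            [make_transcript("se", [(start, end)], status="annotated_lncRNA")]
        )

    def test_gap_of_exactly_2000_fails(self):
        # candidate ends at base 1000 (1-based); single-exon starts at 3001
        cand = make_transcript("c", [(700, 1000)])
        res = filter_single_exon_distance([cand], self.single_exon_at(3000, 3500))
        assert res["c"] == [REASON_NEAR_SINGLE_EXON]

    def test_gap_of_2001_passes(self):
        cand = make_transcript("c", [(700, 1000)])
        res = filter_single_exon_distance([cand], self.single_exon_at(3001, 3500))
        assert res["c"] == []

    def test_no_single_exon_transcripts_passes_vacuously(self):
        cand = make_transcript("c", [(700, 1000)])
        known = GenomeAnnotation(
            [make_transcript("k", [(1100, 1200), (1400, 1500)], status="coding")]
        )
        assert filter_single_exon_distance([cand], known)["c"] == []

    def test_multi_exon_spans_measured_not_exons(self):
        # candidate span reaches to its last exon even across a long intron
        cand = make_transcript("c", [(0, 100), (8000, 8100)])
        res = filter_single_exon_distance([cand], self.single_exon_at(9000, 9100))
        assert res["c"] == [REASON_NEAR_SINGLE_EXON]


def brute_force_overlap(candidate, known_transcripts):
    for k in known_transcripts:
        if k.chrom != candidate.chrom:
            continue
        for ce in candidate.exons:
            for ke in k.exons:
                if ce.start < ke.end and ke.start < ce.end:
                    return True
    return False


def brute_force_near_single_exon(candidate, known_transcripts, max_gap=2000):
    cs, ce = candidate.span
    for k in known_transcripts:
        if k.n_exons != 1 or k.chrom != candidate.chrom:
            continue
        ks, ke = k.span
        gap = max(ks - ce, cs - ke, 0)
        if gap <= max_gap:
            return True
    return False


def random_annotation(rng, n_candidates, n_known):
    """Random multi-chromosome annotation with adversarial proximity."""
    def rand_transcript(i, status):
        chrom = f"chr{rng.integers(1, 4)}"
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(rng.integers(0, 60_000))
        exons = []
        for _ in range(int(rng.integers(1, 4))):
            length = int(rng.integers(50, 800))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 3000))
        return make_transcript(
            f"{status}_{i}", exons, strand=strand, chrom=chrom, status=status
        )

    candidates = [rand_transcript(i, "unannotated") for i in range(n_candidates)]
    known = GenomeAnnotation(
        [rand_transcript(i, "coding") for i in range(n_known)]
    )
    return candidates, known


class TestBruteForceOracle:
    def test_filters_match_naive_pairwise_scan(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            candidates, known = random_annotation(
                rng, int(rng.integers(5, 40)), int(rng.integers(5, 80))
            )
            known_list = list(known)
            ov = filter_known_overlap(candidates, known)
            dist = filter_single_exon_distance(candidates, known)
            for c in candidates:
                assert bool(ov[c.transcript_id]) == brute_force_overlap(
                    c, known_list
                )
                assert bool(dist[c.transcript_id]) == brute_force_near_single_exon(
                    c, known_list
                )


class TestIdentifyCascade:
    def _run(self, default_sim, sim_sequences, fitted_scorer, thr=None):
        scorer = lambda t: fitted_scorer.score(
            t.transcript_id, sim_sequences[t.transcript_id].sequence
        ).score
        kwargs = {"thr": thr} if thr else {}
        return identify_novel_lncrnas(
            default_sim["assembled"],
            default_sim["reference"],
            default_sim["counts"],
            scorer,
            **kwargs,
        )

    def test_recovers_exactly_the_planted_novel_set(
        self, default_sim, sim_sequences, fitted_scorer
    ):
        novel, decisions, funnel = self._run(
            default_sim, sim_sequences, fitted_scorer
        )
        got = {t.transcript_id for t in novel}
        want = set(default_sim["truth"].true_novel_ids())
        assert got == want

    def test_each_decoy_fails_at_its_designated_stage(
        self, default_sim, sim_sequences, fitted_scorer
    ):
        _, decisions, _ = self._run(default_sim, sim_sequences, fitted_scorer)
        stage_of = {d.transcript_id: d.stage_reached for d in decisions}
        expected_stage = {
            "decoy:short": "length_fpkm",
            "decoy:low_fpkm": "length_fpkm",
            "decoy:exon_overlap": "overlap",
            "decoy:near_single_exon": "distance",
            "decoy:coding_potential": "coding",
        }
        truth = default_sim["truth"]
        for label, stage in expected_stage.items():
            for tid in truth.ids_with_label(label):
                assert stage_of[tid] == stage, (tid, label)

    def test_funnel_counts_monotone_and_audit_complete(
        self, default_sim, sim_sequences, fitted_scorer
    ):
        novel, decisions, funnel = self._run(
            default_sim, sim_sequences, fitted_scorer
        )
        order = ["unannotated", "length_fpkm", "overlap", "distance", "coding"]
        values = [funnel[k] for k in order]
        assert values == sorted(values, reverse=True)
        n_unannotated = sum(
            1
            for t in default_sim["assembled"]
            if t.annotation_status == "unannotated"
        )
        assert len(decisions) == n_unannotated
        assert len({d.transcript_id for d in decisions}) == n_unannotated
        assert {d.transcript_id for d in decisions if d.passed} == {
            t.transcript_id for t in novel
        }

    def test_tightened_threshold_yields_subset(
        self, default_sim, sim_sequences, fitted_scorer
    ):
        novel_default, _, _ = self._run(default_sim, sim_sequences, fitted_scorer)
        novel_tight, _, _ = self._run(
            default_sim, sim_sequences, fitted_scorer,
            thr=FilterThresholds(min_length=500),
        )
        tight = {t.transcript_id for t in novel_tight}
        default = {t.transcript_id for t in novel_default}
        assert tight < default

    def test_empty_unannotated_set_gives_empty_output(self, default_sim):
        reference = default_sim["reference"]
        counts = ExpressionMatrix(
            counts=pd.DataFrame(
                1,
                index=[t.transcript_id for t in reference],
                columns=["s1"],
            ),
            sample_groups={"g": ["s1"]},
        )
        novel, decisions, funnel = identify_novel_lncrnas(
            reference, reference, counts, scorer=lambda t: -1.0
        )
        assert novel == [] and decisions == [] and funnel["unannotated"] == 0
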
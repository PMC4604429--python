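"""Sliding-window cluster calling against a brute-force enumerator."""

import numpy as np
import pytest

from pirnaflow.clusters import (
    PiRNACluster,
    assign_transcripts_to_clusters,
    call_clusters,
    classify_directionality,
    summarize_clusters,
)
from pirnaflow.simulate import simulate

from conftest import lib_of, pirna_only_config, rec, uniq_seq


def brute_force_clusters(lib, window_size=1000, step=968, min_reads=10,
                         lo=28, hi=32, trim=True):
    """Independent oracle: enumerate every window explicitly, merge by
    interval union over qualifying windows, trim to supporting reads."""
    out = []
    for ref_id in sorted(lib.ref_lengths):
        recs = [r for r in lib.records
                if r.ref_id == ref_id and r.n_hits == 1
                and lo <= len(r.read) <= hi]
        contig_len = lib.ref_lengths[ref_id]
        qualifying = []
        w = 0
        while w < contig_len:
            w_end = min(w + window_size, contig_len)
            n = sum(1 for r in recs if w <= r.five_prime < w_end)
            if n >= min_reads:
                qualifying.append((w, w_end))
            w += step
        # union of overlapping/abutting windows
        merged = []
        for s, e in qualifying:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        for s, e in merged:
            sup = [r for r in recs if s <= r.five_prime < e]
            if not sup:
                continue
            cs = min(r.start for r in sup) if trim else s
            ce = max(r.end for r in sup) if trim else e
            out.append((ref_id, cs, ce, len(sup)))
    return out


def random_library(rng, n_contigs=1, contig_len=10_000, n_reads=60):
    """Random 28-32-nt records scattered over toy contigs, some clumped."""
    recs = []
    refs = {f"t{i}": contig_len for i in range(n_contigs)}
    for _ in range(n_reads):
        ref = f"t{rng.integers(n_contigs)}"
        L = int(rng.integers(28, 33))
        if rng.random() < 0.6:  # clumped around a few foci
            center = int(rng.choice([1500, 4800, 9000]))
            fp = int(np.clip(center + rng.integers(-400, 400), L, contig_len - L - 1))
        else:
            fp = int(rng.integers(L, contig_len - L))
        recs.append(rec(ref, fp, L, "+-"[rng.integers(2)]))
    return lib_of(recs, ref_lengths=refs)


class TestCallClusters:
    def test_single_cluster_bounds_trimmed_to_reads(self):
        # 12 distinct unique 30-mers with 5' ends in [100, 900)
        fps = np.linspace(100, 880, 12).astype(int)
        lib = lib_of([rec("c", int(fp), 30, "+") for fp in fps],
                     ref_lengths={"c": 3000})
        (cl,) = call_clusters(lib)
        assert (cl.start, cl.end) == (100, 880 + 30)
        assert cl.n_unique_reads == 12

    def test_below_threshold_no_cluster(self):
        lib = lib_of([rec("c", 100 + 60 * i, 30, "+") for i in range(9)],
                     ref_lengths={"c": 3000})
        assert call_clusters(lib) == []

    def test_two_qualifying_windows_merge(self):
        # 10 reads in window [0,1000), 10 in [968,1968) -> one cluster
        fps = list(range(100, 900, 80)) + list(range(1000, 1800, 80))
        lib = lib_of([rec("c", fp, 30, "+") for fp in fps],
                     ref_lengths={"c": 3000})
        clusters = call_clusters(lib)
        assert len(clusters) == 1
        assert clusters[0].n_unique_reads == len(fps)

    def test_multimappers_excluded_from_counting(self):
        shared = uniq_seq(30)
        multi = [rec("c", 100 + 50 * i, 30, "+", seq=shared)
                 for i in range(12)]
        lib = lib_of(multi, ref_lengths={"c": 3000})
        assert call_clusters(lib) == []

    def test_contig_shorter_than_window(self):
        lib = lib_of([rec("c", 30 + 25 * i, 30, "+") for i in range(12)],
                     ref_lengths={"c": 500})
        (cl,) = call_clusters(lib)
        assert cl.end <= 500

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_brute_force_enumerator(self, seed):
        rng = np.random.default_rng(seed)
        lib = random_library(rng, n_contigs=2, n_reads=120)
        got = [(c.ref_id, c.start, c.end, c.n_unique_reads)
               for c in call_clusters(lib)]
        assert got == brute_force_clusters(lib)

    def test_min_reads_monotonicity(self):
        # raising min_reads shrinks the qualifying-window union: total
        # covered length never grows and every stricter cluster nests
        # inside a looser one (the count itself may rise through splits)
        rng = np.random.default_rng(99)
        lib = random_library(rng, n_reads=200)
        prev_cls, prev_len = None, None
        for mr in (5, 10, 20, 40):
            cls = call_clusters(lib, min_reads=mr, trim=False)
            tot = sum(c.length for c in cls)
            if prev_cls is not None:
                assert tot <= prev_len
                for c in cls:
                    assert any(p.ref_id == c.ref_id and p.start <= c.start
                               and c.end <= p.end for p in prev_cls)
            prev_cls, prev_len = cls, tot

    def test_output_disjoint_per_contig(self):
        rng = np.random.default_rng(7)
        lib = random_library(rng, n_reads=300)
        cls = sorted(call_clusters(lib, min_reads=5),
                     key=lambda c: (c.ref_id, c.start))
        for a, b in zip(cls, cls[1:]):
            if a.ref_id == b.ref_id:
                assert a.end <= b.start


class TestDirectionality:
    @pytest.mark.parametrize(
        "plus,minus,frac,expected",
        [
            (50, 50, 0.25, "bidirectional"),
            (100, 0, 0.25, "unidirectional"),
            (80, 20, 0.25, "unidirectional"),
            (80, 20, 0.20, "bidirectional"),
        ],
    )
    def test_minor_strand_fraction_rule(self, plus, minus, frac, expected):
        c = PiRNACluster("c", 0, 100, plus + minus, plus, minus)
        assert classify_directionality(c, bidir_min_frac=frac) == expected

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            classify_directionality(PiRNACluster("c", 0, 100, 0, 0, 0))


class TestSummary:
    def test_median_and_max(self):
        cls = [PiRNACluster("c", s, s + L, 10, 10, 0)
               for s, L in [(0, 2), (100, 4), (200, 6), (300, 100)]]
        lib = lib_of([], ref_lengths={"c": 10_000})
        summ = summarize_clusters(cls, lib)
        assert summ.median_length == 5.0
        assert summ.max_length == 100

    def test_toy_fractions(self):
        reads = [rec("c", 100 + 30 * i, 30, "+") for i in range(12)]
        lib = lib_of(reads, ref_lengths={"c": 100_000})
        (cl,) = call_clusters(lib)
        summ = summarize_clusters([PiRNACluster("c", 0, 1000, 12, 12, 0)],
                                  lib)
        assert summ.genome_fraction == pytest.approx(0.01)
        assert summ.unique_pirna_fraction == 1.0

    def test_empty_cluster_list_gives_zeros(self):
        lib = lib_of([], ref_lengths={"c": 1000})
        summ = summarize_clusters([], lib)
        assert summ.n_clusters == 0 and summ.genome_fraction == 0.0

    def test_planted_fraction_recovered(self):
        res = simulate(pirna_only_config(5, total_reads=20_000,
                                         n_species=2_000))
        lib = res.genome_library("ctrl", 1)
        summ = summarize_clusters(call_clusters(lib), lib)
        assert summ.unique_pirna_fraction == pytest.approx(
            res.truth.inside_fraction_realized, abs=0.02)


class TestTranscriptAssignment:
    CLUSTERS = [PiRNACluster("c", 1000, 2000, 10, 10, 0)]

    def test_inside_outside_unplaced(self):
        placements = {
            "in_t": ("c", 1200, 1600),
            "out_t": ("c", 5000, 5400),
            "lost_t": None,
        }
        flags = assign_transcripts_to_clusters(placements, self.CLUSTERS)
        assert flags == {"in_t": "in", "out_t": "out", "lost_t": "unplaced"}

    def test_overlap_fraction_threshold(self):
        # 60% of the transcript overlaps the cluster
        placements = {"t": ("c", 1700, 2200)}
        assert assign_transcripts_to_clusters(
            placements, self.CLUSTERS)["t"] == "in"
        assert assign_transcripts_to_clusters(
            placements, self.CLUSTERS, min_overlap_frac=0.7)["t"] == "out"
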
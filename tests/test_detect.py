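"""Containment filtering, core extraction (vs exhaustive window oracle),
group-common/unique set algebra, duplicate flagging."""

import numpy as np
import pytest

from cnsevo.align import AlignmentHit
from cnsevo.detect import (
    CNSRecord,
    extract_cores,
    filter_contained_hits,
    flag_duplicates,
    group_common,
    group_unique,
    map_to_subject,
)
from cnsevo.intervals import GenomicInterval, merge_intervals, total_length
from conftest import bitmap


def make_hit(columns, qstart=0, sstart=0, strand="+", score=None, chrom="chr1"):
    qlen = sum(c in "MXS" for c in columns)
    slen = sum(c in "MXQ" for c in columns)
    return AlignmentHit(
        GenomicInterval(chrom, qstart, qstart + qlen),
        GenomicInterval("s1", sstart, sstart + slen, strand),
        columns, score=score if score is not None else float(columns.count("M")),
        evalue=1e-10,
    )


def hit_on(qstart, qend, score=10.0, sstart=0):
    return make_hit("M" * (qend - qstart), qstart=qstart, sstart=sstart,
                    score=score)


class TestContainmentFilter:
    def test_contained_hit_discarded(self):
        a, b = hit_on(100, 400), hit_on(150, 300)
        assert filter_contained_hits([a, b]) == [a]
        assert filter_contained_hits([b, a]) == [a]

    def test_partial_overlap_kept(self):
        a, b = hit_on(100, 400), hit_on(300, 500)
        assert filter_contained_hits([a, b]) == [a, b]

    def test_equal_intervals_tiebreak(self):
        lo = hit_on(100, 300, score=5.0, sstart=50)
        hi = hit_on(100, 300, score=9.0, sstart=80)
        kept = filter_contained_hits([lo, hi])
        assert kept == [hi]
        # equal score: lower subject start wins
        other = hit_on(100, 300, score=5.0, sstart=10)
        kept = filter_contained_hits([lo, other])
        assert kept == [other]

    def test_deterministic_sorted_output(self):
        hits = [hit_on(500, 700), hit_on(0, 300), hit_on(200, 400)]
        kept = filter_contained_hits(list(reversed(hits)))
        starts = [h.query.start for h in kept]
        assert starts == sorted(starts)


# ---------------------------------------------------------------------------
# Core extraction vs exhaustive enumeration oracle


def oracle_cores(hit, threshold_divergence, min_length):
    """Brute-force reimplementation: enumerate every min_length-column
    window, union the passing ones, trim run ends to match columns, map
    through the column string."""
    cols = hit.columns
    n = len(cols)
    min_ident = 100.0 - threshold_divergence
    n_match = cols.count("M")
    qspan = sum(c in "MXS" for c in cols)
    if n and 100.0 * n_match / n >= min_ident and qspan >= min_length:
        return [(hit.query.start, hit.query.end)]
    if n < min_length:
        return []
    covered = set()
    for s in range(n - min_length + 1):
        w = cols[s:s + min_length]
        if 100.0 * w.count("M") / min_length >= min_ident:
            covered.update(range(s, s + min_length))
    # column -> reference position
    qpos = []
    p = hit.query.start
    for c in cols:
        qpos.append(p)
        if c in "MXS":
            p += 1
    out = []
    run = []
    for i in range(n + 1):
        if i < n and i in covered:
            run.append(i)
            continue
        if run:
            a, b = run[0], run[-1]
            while a <= b and cols[a] != "M":
                a += 1
            while b >= a and cols[b] != "M":
                b -= 1
            if a <= b and qpos[b] + 1 - qpos[a] >= min_length:
                out.append((qpos[a], qpos[b] + 1))
            run = []
    return out


def random_columns(rng, length, identity, planted_run=0):
    chars = []
    for _ in range(length):
        if rng.random() < identity:
            chars.append("M")
        else:
            chars.append(rng.choice(["X", "X", "Q", "S"]))
    if planted_run and planted_run < length:
        s = int(rng.integers(0, length - planted_run))
        chars[s:s + planted_run] = ["M"] * planted_run
    return "".join(chars)


class TestExtractCores:
    def test_all_match_returns_whole_span(self):
        h = make_hit("M" * 300, qstart=50)
        assert extract_cores(h, 5.0, 100) == [GenomicInterval("chr1", 50, 350)]

    def test_no_passing_window_returns_empty(self):
        h = make_hit("M" * 99 + "X" * 99)
        assert extract_cores(h, 5.0, 100) == []

    def test_window_longer_than_alignment_empty(self):
        h = make_hit("M" * 50)
        assert extract_cores(h, 50.0, 100) == [] or len(h.columns) >= 100

    def test_embedded_match_run_matches_oracle(self):
        rng = np.random.default_rng(0)
        cols = random_columns(rng, 600, 0.60, planted_run=150)
        h = make_hit(cols, qstart=1000)
        got = [(iv.start, iv.end) for iv in extract_cores(h, 5.0, 100)]
        assert got == oracle_cores(h, 5.0, 100)
        assert got  # the planted run must be found

    @pytest.mark.parametrize("seed", range(8))
    def test_random_column_strings_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            length = int(rng.integers(150, 2000))
            identity = float(rng.uniform(0.4, 0.99))
            planted = int(rng.integers(0, 200)) if rng.random() < 0.5 else 0
            thr = float(rng.uniform(2.0, 20.0))
            cols = random_columns(rng, length, identity, planted)
            h = make_hit(cols, qstart=int(rng.integers(0, 5000)))
            got = [(iv.start, iv.end) for iv in extract_cores(h, thr, 100)]
            assert got == oracle_cores(h, thr, 100)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        cols = random_columns(rng, 1500, 0.8)
        h = make_hit(cols)
        prev = -1
        for thr in (2.0, 5.0, 10.0, 20.0, 40.0):
            bases = sum(len(iv) for iv in extract_cores(h, thr, 100))
            assert bases >= prev
            prev = bases


class TestMapToSubject:
    def test_plus_strand_identity_mapping(self):
        h = make_hit("M" * 200, qstart=100, sstart=500)
        sub = map_to_subject(h, GenomicInterval("chr1", 150, 180))
        assert (sub.start, sub.end, sub.strand) == (550, 580, "+")

    def test_gap_aware_mapping(self):
        # 10 M, 5 Q (subject insertion), 10 M
        h = make_hit("M" * 10 + "Q" * 5 + "M" * 10, qstart=0, sstart=0)
        sub = map_to_subject(h, GenomicInterval("chr1", 10, 20))
        assert (sub.start, sub.end) == (15, 25)

    def test_minus_strand_mirrored(self):
        h = make_hit("M" * 100, qstart=0, sstart=1000, strand="-")
        sub = map_to_subject(h, GenomicInterval("chr1", 0, 10))
        assert (sub.start, sub.end, sub.strand) == (1090, 1100, "-")


class TestGroupCommon:
    def test_single_partner_identity(self):
        track = [GenomicInterval("chr1", 0, 500)]
        recs = group_common({"sp1": track}, [], 100)
        assert [r.interval for r in recs] == track

    def test_two_partner_intersection(self):
        recs = group_common(
            {"sp1": [GenomicInterval("chr1", 0, 500)],
             "sp2": [GenomicInterval("chr1", 200, 800)]}, [], 100)
        assert [r.interval for r in recs] == [GenomicInterval("chr1", 200, 500)]

    def test_missing_partner_is_error(self):
        with pytest.raises(ValueError, match="sp2"):
            group_common({"sp1": [GenomicInterval("chr1", 0, 500)],
                          "sp2": None}, [], 100)

    def test_random_tracks_match_bitmap_and_exclusions(self):
        rng = np.random.default_rng(3)
        L = 20_000
        from conftest import random_track
        for _ in range(10):
            tracks = {f"sp{i}": random_track(rng, 60, L) for i in range(3)}
            excl = random_track(rng, 20, L)
            recs = group_common(tracks, excl, min_length=20)
            got = bitmap([r.interval for r in recs], L)
            expect = np.ones(L, dtype=bool)
            for t in tracks.values():
                expect &= bitmap(t, L)
            expect &= ~bitmap(excl, L)
            # oracle minus fragments < min_length
            arr = expect.astype(np.int8)
            boundaries = np.nonzero(np.diff(np.concatenate([[0], arr, [0]])))[0]
            for s, e in zip(boundaries[::2], boundaries[1::2]):
                if e - s < 20:
                    expect[s:e] = False
            assert np.array_equal(got, expect)
            assert all(len(r) >= 20 for r in recs)
            assert not (got & bitmap(excl, L)).any()


class TestGroupUnique:
    def make_common(self, start, end):
        return CNSRecord("c1", GenomicInterval("chr1", start, end))

    def test_no_outgroup_coverage_retained_whole(self):
        recs = group_unique([self.make_common(0, 300)], {"og": []}, 100)
        assert [r.interval for r in recs] == [GenomicInterval("chr1", 0, 300)]
        assert "group-unique" in recs[0].labels

    def test_full_outgroup_coverage_removes(self):
        recs = group_unique([self.make_common(0, 300)],
                            {"og": [GenomicInterval("chr1", 0, 300)]}, 100)
        assert recs == []

    def test_partial_coverage_keeps_long_residual(self):
        recs = group_unique([self.make_common(0, 250)],
                            {"og": [GenomicInterval("chr1", 0, 120)]}, 100)
        assert [r.interval for r in recs] == [GenomicInterval("chr1", 120, 250)]

    def test_short_residual_dropped(self):
        recs = group_unique([self.make_common(0, 250)],
                            {"og": [GenomicInterval("chr1", 0, 180)]}, 100)
        assert recs == []


class TestFlagDuplicates:
    def test_planted_duplicate_flagged(self):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        elem = "".join(rng.choice(bases, size=300))
        filler = lambda n: "".join(rng.choice(bases, size=n))
        genome = {"chr1": filler(2000) + elem + filler(2000) + elem + filler(2000)}
        single = filler(300)
        genome["chr1"] += single + filler(1000)
        recs = [
            CNSRecord("dup", GenomicInterval("chr1", 2000, 2300)),
            CNSRecord("uniq", GenomicInterval("chr1", 6300, 6600)),
        ]
        flag_duplicates(recs, genome, threshold_divergence=6.0,
                        engine="internal")
        by_id = {r.cns_id: r for r in recs}
        assert by_id["dup"].single_copy is False
        assert by_id["uniq"].single_copy is True

    def test_near_identical_tandem_copies(self):
        rng = np.random.default_rng(9)
        bases = np.array(list("ACGT"))
        elem = "".join(rng.choice(bases, size=400))
        mutated = list(elem)
        for i in range(0, 400, 50):  # 2% divergence
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        genome = {"chr1": "".join(rng.choice(bases, size=1500)) + elem
                  + "".join(rng.choice(bases, size=1500)) + "".join(mutated)
                  + "".join(rng.choice(bases, size=1500))}
        recs = [CNSRecord("c", GenomicInterval("chr1", 1500, 1900))]
        flag_duplicates(recs, genome, threshold_divergence=6.0,
                        engine="internal")
        assert recs[0].single_copy is False
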
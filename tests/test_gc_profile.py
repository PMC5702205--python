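import math

import numpy as np
import pytest

from gcstratify.gc_profile import (
    CutoffError,
    GCHistogram,
    GCRecord,
    N_BINS,
    build_histogram,
    detect_peaks,
    determine_cutoffs,
    extract_cds_sequence,
    flanking_gc,
    gc_content,
    read_cutoff_file,
    read_gc_content,
    reverse_complement,
    smooth_histogram,
    write_profile_outputs,
)
from gcstratify.io_formats import GenomicInterval, ModelError, SequenceRecord

from conftest import make_model


def rec(gc_values):
    return [
        GCRecord(f"t{i}", 0, 0, 0, 0, 0, 0, v) for i, v in enumerate(gc_values)
    ]


def hist_from(values, start_bin=0):
    raw = np.zeros(N_BINS)
    raw[start_bin : start_bin + len(values)] = values
    return GCHistogram(raw=raw)


class TestExtractCDS:
    def test_plus_strand_splice(self):
        genome = [SequenceRecord(id="chr1", sequence="ATGCCCGGT")]
        m = make_model(cds=[(1, 3), (7, 9)], start=1, end=9)
        assert extract_cds_sequence(m, genome).sequence == "ATGGGT"

    def test_minus_strand_reverse_complement(self):
        genome = [SequenceRecord(id="chr1", sequence="ATGC")]
        m = make_model(cds=[(1, 4)], start=1, end=4, strand="-")
        assert extract_cds_sequence(m, genome).sequence == "GCAT"

    def test_interval_beyond_sequence_end(self):
        genome = [SequenceRecord(id="chr1", sequence="ACGT")]
        m = make_model(cds=[(5, 10)], start=5, end=10)
        with pytest.raises(ModelError, match="beyond end"):
            extract_cds_sequence(m, genome)

    def test_missing_seqid(self):
        genome = [SequenceRecord(id="chr2", sequence="ACGT")]
        m = make_model(cds=[(1, 4)], start=1, end=4)
        with pytest.raises(ModelError, match="not in genome"):
            extract_cds_sequence(m, genome)


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGCATGC", 50.0), ("GCGCGC", 100.0), ("ATGN", 100.0 / 3.0)],
    )
    def test_gc_percent(self, seq, expected):
        r = gc_content(SequenceRecord(id="x", sequence=seq))
        assert r.gc_percent == pytest.approx(expected)
        assert r.a + r.c + r.g + r.t + r.n == r.length

    def test_all_n_flagged_not_dropped(self):
        r = gc_content(SequenceRecord(id="x", sequence="NNNN"))
        assert r.undefined and r.n == 4

    def test_strand_flip_leaves_gc_unchanged(self, sim_small):
        _, genome, models, _ = sim_small
        flipped = [
            SequenceRecord(id=s.id, sequence=reverse_complement(s.sequence))
            for s in genome
        ]
        lengths = {s.id: len(s) for s in genome}
        for m in models[:25]:
            L = lengths[m.seqid]
            mirrored = make_model(
                tid=m.transcript_id,
                seqid=m.seqid,
                strand="-" if m.strand == "+" else "+",
                cds=[(L - iv.end + 1, L - iv.start + 1) for iv in reversed(m.cds)],
                start=L - m.location.end + 1,
                end=L - m.location.start + 1,
            )
            a = gc_content(extract_cds_sequence(m, genome)).gc_percent
            b = gc_content(extract_cds_sequence(mirrored, flipped)).gc_percent
            assert a == pytest.approx(b)


class TestHistogram:
    def test_floor_binning(self):
        h = build_histogram(rec([47.2, 47.9, 68.0]))
        assert h.raw[47] == 2 and h.raw[68] == 1

    def test_hundred_folds_into_last_bin(self):
        h = build_histogram(rec([100.0]))
        assert h.raw[100] == 1

    def test_empty_input_all_zero(self):
        assert build_histogram([]).raw.sum() == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        h = build_histogram(rec(rng.uniform(0, 100, 1000)))
        assert h.raw.sum() == 1000


class TestSmoothing:
    def test_windowed_mean_with_edge_truncation(self):
        h = smooth_histogram(hist_from([10, 0, 0, 30, 0, 0, 10]), 3)
        expect = [5.0, 10 / 3, 10.0, 10.0, 10.0, 10 / 3, 10 / 3]
        assert h.smoothed[:7] == pytest.approx(expect)
        # mirrored at the right edge: bin 100 only averages two bins
        h2 = smooth_histogram(hist_from([10, 0, 0, 30, 0, 0, 10], start_bin=94), 3)
        assert h2.smoothed[100] == pytest.approx(5.0)

    def test_window_one_is_identity(self):
        h = smooth_histogram(hist_from([1, 2, 3]), 1)
        assert np.array_equal(h.smoothed, h.raw)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth_histogram(hist_from([1]), 4)

    def test_mass_conserved_away_from_edges(self):
        # each interior count appears in w windows, each divided by w, so
        # smoothing conserves total mass exactly when no mass sits within a
        # half-window of the domain edges (the realistic GC-histogram case)
        rng = np.random.default_rng(1)
        for w in (3, 7, 11):
            raw = np.zeros(N_BINS)
            raw[w : N_BINS - w] = rng.integers(0, 50, N_BINS - 2 * w)
            s = smooth_histogram(GCHistogram(raw=raw), w)
            assert s.smoothed.sum() == pytest.approx(raw.sum())

    def test_edge_mass_perturbs_total_boundedly(self):
        rng = np.random.default_rng(2)
        for w in (3, 7):
            raw = rng.integers(0, 50, N_BINS).astype(float)
            s = smooth_histogram(GCHistogram(raw=raw), w)
            edge_mass = raw[:w].sum() + raw[-w:].sum()
            assert abs(s.smoothed.sum() - raw.sum()) <= edge_mass


def oracle_peaks(values, w_p):
    """Exhaustive per-bin check of the peak rule (independent of detect_peaks)."""
    half = (w_p - 1) // 2
    out = []
    for b in range(len(values)):
        if b - half < 0 or b + half >= len(values):
            continue
        ok = True
        for off in range(1, half + 1):
            if not (values[b - off] < values[b] and values[b + off] < values[b]):
                ok = False
                break
        if ok:
            out.append(b)
    return out


class TestPeakDetection:
    def test_two_peak_example(self):
        h = hist_from([1, 2, 5, 3, 2, 4, 8, 4, 1])
        assert detect_peaks(h, 5) == [2, 6]

    def test_monotonic_has_no_interior_maximum(self):
        # strictly increasing over the whole domain: the maximum sits on the
        # edge bin, which never has a full window, so no peak is reported
        h = GCHistogram(raw=np.arange(N_BINS, dtype=float))
        assert detect_peaks(h, 3) == []
        assert detect_peaks(GCHistogram(raw=np.arange(N_BINS, 0, -1.0)), 3) == []

    def test_plateau_tie_is_not_a_peak(self):
        raw = np.zeros(N_BINS)
        raw[10:14] = [1, 3, 3, 1]
        assert detect_peaks(GCHistogram(raw=raw), 3) == []

    def test_even_or_small_window_rejected(self):
        for w in (2, 1, 4):
            with pytest.raises(ValueError):
                detect_peaks(hist_from([1]), w)

    def test_matches_exhaustive_oracle_on_random_histograms(self):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            raw = rng.integers(0, 20, N_BINS).astype(float)
            h = GCHistogram(raw=raw)
            for w in (3, 5, 7):
                assert detect_peaks(h, w) == oracle_peaks(raw, w)


class TestCutoffs:
    def test_two_peaks_direct(self):
        raw = np.zeros(N_BINS)
        raw[45:50] = [10, 100, 900, 100, 10]
        raw[66:71] = [10, 50, 400, 50, 10]
        c = determine_cutoffs(GCHistogram(raw=raw), 5)
        assert (c.low_peak, c.high_peak) == (47, 68)

    def test_three_peaks_ranked_by_height(self):
        raw = np.zeros(N_BINS)
        raw[39:42] = [10, 100, 10]
        raw[47:50] = [100, 900, 100]
        raw[67:70] = [50, 400, 50]
        c = determine_cutoffs(GCHistogram(raw=raw), 3)
        assert (c.low_peak, c.high_peak) == (48, 68)

    def test_height_tie_broken_toward_extreme_bin(self):
        raw = np.zeros(N_BINS)
        raw[40] = raw[48] = raw[70] = 100  # 48 ties 70 impossible; equal heights
        raw[39] = raw[41] = raw[47] = raw[49] = raw[69] = raw[71] = 1
        c = determine_cutoffs(GCHistogram(raw=raw), 3)
        # all three peaks have height 100; the two farthest from 50 win
        assert (c.low_peak, c.high_peak) == (40, 70)

    def test_unimodal_raises_advice(self):
        raw = np.zeros(N_BINS)
        raw[48:53] = [1, 5, 9, 5, 1]
        with pytest.raises(CutoffError, match="manual"):
            determine_cutoffs(GCHistogram(raw=raw), 5)

    def test_recovers_modes_of_separated_mixture(self, sim_bimodal_2000):
        cfg, genome, models, truth = sim_bimodal_2000
        recs = [gc_content(extract_cds_sequence(m, genome)) for m in models]
        h = smooth_histogram(build_histogram(recs), 7)
        c = determine_cutoffs(h, 5)
        assert abs(c.low_peak - cfg.mu_low) <= 2
        assert abs(c.high_peak - cfg.mu_high) <= 2


class TestFlankingGC:
    def test_interior_gene_flanks(self):
        seq = "AT" * 2500 + "G" * 1000 + "GC" * 2500
        genome = [SequenceRecord(id="chr1", sequence=seq)]
        m = make_model(seqid="chr1", cds=[(5001, 6000)], start=5001, end=6000)
        up, down = flanking_gc(m, genome, 5000)
        assert up == pytest.approx(0.0)
        assert down == pytest.approx(100.0)

    def test_gene_at_sequence_start_has_no_upstream(self):
        genome = [SequenceRecord(id="chr1", sequence="A" * 200)]
        m = make_model(cds=[(1, 50)], start=1, end=50)
        up, down = flanking_gc(m, genome, 100)
        assert up is None and down is not None

    def test_zero_flank_undefined(self):
        genome = [SequenceRecord(id="chr1", sequence="A" * 200)]
        m = make_model(cds=[(50, 100)], start=50, end=100)
        assert flanking_gc(m, genome, 0) == (None, None)


class TestProfileOutputs:
    def test_files_and_cutoff_format(self, tmp_path, sim_small):
        _, genome, models, _ = sim_small
        cds = [extract_cds_sequence(m, genome) for m in models[:3]]
        recs = [gc_content(s) for s in cds]
        h = smooth_histogram(build_histogram(recs), 7)
        from gcstratify.gc_profile import GCCutoffs

        base = tmp_path / "TOY"
        files = write_profile_outputs(recs, h, GCCutoffs(47, 68), base, cds_sequences=cds)
        assert len(files) == 4
        assert (tmp_path / "TOY_cutoff.txt").read_text() == "low\t47\nhigh\t68\n"
        gc_lines = (tmp_path / "TOY_gc_content.txt").read_text().splitlines()
        assert all(len(l.split("\t")) == 8 for l in gc_lines)
        dist_lines = (tmp_path / "TOY_distribution.txt").read_text().splitlines()
        assert len(dist_lines) == 1 + N_BINS

    def test_gc_content_round_trip(self, tmp_path, sim_small):
        _, genome, models, _ = sim_small
        recs = [gc_content(extract_cds_sequence(m, genome)) for m in models[:5]]
        h = smooth_histogram(build_histogram(recs), 7)
        write_profile_outputs(recs, h, None, tmp_path / "RT")
        back = read_gc_content(tmp_path / "RT_gc_content.txt")
        assert [r.transcript_id for r in back] == [r.transcript_id for r in recs]
        for a, b in zip(recs, back):
            assert (a.a, a.c, a.g, a.t, a.n, a.length) == (b.a, b.c, b.g, b.t, b.n, b.length)
            assert b.gc_percent == pytest.approx(a.gc_percent, abs=0.005)

    def test_cutoff_file_round_trip(self, tmp_path):
        from gcstratify.gc_profile import GCCutoffs

        p = tmp_path / "c_cutoff.txt"
        p.write_text("low\t47\nhigh\t68\n")
        c = read_cutoff_file(p)
        assert (c.low_peak, c.high_peak) == (47, 68)
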
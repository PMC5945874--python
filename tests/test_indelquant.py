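"""Amplicon indel quantification: alignment, windowing, frame bookkeeping."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binom

from digenomekit import (
    AmpliconConfig,
    IndelSpectrum,
    IndelSpectrumEntry,
    align_read,
    batch_quantify,
    call_indels,
    simulate_amplicon,
    summarize,
)
from digenomekit.indelquant import IndelOp, quantify_fastq

from conftest import affine_dp_score

REF = (
    "ATGCTAGCTAGGACTGATCGATCCGATCGTTTAGCTGACGTAGAGTCCTAGCAATGCCATTGACCAGT"
    "CGATTGCAGTCCATGCAGGACTGACTGATTGCCGATCGATCAGGCTAGCATCGCATGCA"
)
# protospacer+PAM at [31, 58); the nuclease cuts around position 53
CONFIG = AmpliconConfig(
    amplicon_id="amp1", amplicon_reference=REF, guide_window=(31, 58), min_read_length=20
)


class TestAlignRead:
    def test_identity_read_no_ops(self):
        aln = align_read(REF, CONFIG)
        assert aln.ops == []
        assert aln.score == pytest.approx(2.0 * len(REF))

    def test_four_base_deletion_left_aligned(self):
        read = REF[:53] + REF[57:]
        aln = align_read(read, CONFIG)
        assert len(aln.ops) == 1
        op = aln.ops[0]
        assert op.kind == "del" and op.length == 4
        # left-normalised: no identical base immediately before the gap that
        # matches the gap's last base
        p = op.position
        assert p == 0 or REF[p - 1] != REF[p + op.length - 1]
        assert aln.score == pytest.approx(affine_dp_score(REF, read))

    def test_homopolymer_deletion_placed_leftmost(self):
        ref = "ACGTAAAAACGTACGTACGTACGTACG"
        cfg = AmpliconConfig("h", ref, (2, 20), min_read_length=10)
        read = ref[:6] + ref[8:]  # remove 2 A's from the run at [4,9)
        aln = align_read(read, cfg)
        assert aln.ops == [IndelOp("del", 4, 2)]

    def test_insertion_reported_with_sequence(self):
        read = REF[:53] + "GT" + REF[53:]
        aln = align_read(read, CONFIG)
        assert len(aln.ops) == 1
        op = aln.ops[0]
        assert op.kind == "ins" and op.length == 2 and len(op.inserted) == 2

    def test_short_read_rejected(self):
        with pytest.raises(ValueError, match="min_read_length"):
            align_read("ACGT", CONFIG)

    def test_truncated_read_free_end_gaps(self):
        read = REF[20:90]
        aln = align_read(read, CONFIG)
        assert aln.ops == []
        assert aln.ref_start == 20 and aln.ref_end == 90
        assert aln.score == pytest.approx(2.0 * 70)

    @given(st.data())
    def test_score_matches_independent_dp(self, data):
        """Alignment scores equal a hand-rolled quadratic Gotoh DP."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        m = int(rng.integers(25, 60))
        ref = "".join("ACGT"[i] for i in rng.integers(4, size=m).tolist())
        read = list(ref)
        for _ in range(int(rng.integers(0, 5))):
            k = int(rng.integers(len(read)))
            mode = int(rng.integers(3))
            if mode == 0:
                read[k] = "ACGT"[int(rng.integers(4))]
            elif mode == 1 and len(read) > 22:
                del read[k]
            else:
                read.insert(k, "ACGT"[int(rng.integers(4))])
        read = "".join(read)
        cfg = AmpliconConfig("t", ref, (1, m - 1), window_pad=0, min_read_length=5)
        assert align_read(read, cfg).score == pytest.approx(affine_dp_score(ref, read))


class TestCallIndels:
    def test_substitution_is_not_an_indel(self):
        read = REF[:40] + ("A" if REF[40] != "A" else "C") + REF[41:]
        ev = call_indels(align_read(read, CONFIG), CONFIG)
        assert ev.ops == [] and not ev.in_window and ev.net_length_change == 0

    def test_one_base_insertion_out_of_frame(self):
        read = REF[:50] + "T" + REF[50:]
        ev = call_indels(align_read(read, CONFIG), CONFIG)
        assert ev.in_window and ev.net_length_change == 1
        assert ev.net_length_change % 3 != 0

    def test_three_base_deletion_in_frame(self):
        read = REF[:50] + REF[53:]
        ev = call_indels(align_read(read, CONFIG), CONFIG)
        assert ev.in_window and ev.net_length_change == -3
        assert ev.net_length_change % 3 == 0

    def test_indel_outside_padded_window_not_counted(self):
        read = REF[:100] + REF[104:]  # deletion well downstream of the guide
        ev = call_indels(align_read(read, CONFIG), CONFIG)
        assert ev.ops and not ev.in_window

    def test_net_change_sums_all_ops(self):
        read = REF[:40] + "GG" + REF[40:50] + REF[53:]
        ev = call_indels(align_read(read, CONFIG), CONFIG)
        assert ev.net_length_change == 2 - 3


class TestSummarize:
    def _events(self, n_wt, specs):
        events = []
        for i in range(n_wt):
            events.append(call_indels(align_read(REF, CONFIG), CONFIG, f"wt{i}"))
        for j, (net, count) in enumerate(specs):
            if net < 0:
                read = REF[:50] + REF[50 - net:]
            else:
                read = REF[:50] + "ACGTG"[:net] + REF[50:]
            for i in range(count):
                events.append(call_indels(align_read(read, CONFIG), CONFIG, f"m{j}_{i}"))
        return events

    def test_frequency_and_frame_split(self):
        events = self._events(700, [(-4, 300)])
        s = summarize(events, total_reads=1000)
        assert s.indel_frequency == pytest.approx(30.0)
        assert s.out_of_frame_fraction == pytest.approx(100.0)
        assert s.indel_reads == 300

    def test_all_wild_type_missing_fractions(self):
        s = summarize(self._events(50, []), total_reads=50)
        assert s.indel_frequency == 0.0
        assert s.out_of_frame_fraction is None

    def test_no_reads_frequency_missing_not_zero(self):
        s = summarize([], total_reads=0)
        assert s.indel_frequency is None

    def test_half_in_frame_mixture(self):
        events = self._events(0, [(-3, 120), (1, 120)])
        s = summarize(events, total_reads=240)
        assert s.indel_frequency == pytest.approx(100.0)
        assert s.out_of_frame_fraction == pytest.approx(50.0)

    def test_frame_fractions_total_100(self):
        for specs in ([(-3, 10), (1, 5)], [(-4, 7)], [(-3, 3)]):
            s = summarize(self._events(5, specs), total_reads=100)
            in_frame = 100.0 - s.out_of_frame_fraction
            assert in_frame + s.out_of_frame_fraction == pytest.approx(100.0)

    def test_patterns_ranked_by_count_then_signature(self):
        events = self._events(0, [(-4, 5), (1, 9)])
        s = summarize(events, total_reads=14)
        assert [c for _, c, _ in s.patterns] == [9, 5]
        assert sum(c for _, c, _ in s.patterns) == s.indel_reads
        frames = {sig: fr for sig, _, fr in s.patterns}
        assert set(frames.values()) == {"out-of-frame"}  # -4 and +1 both shift


class TestEndToEndQuantification:
    def test_recovers_planted_fraction_with_sequencing_error(self, tmp_path):
        spectrum = IndelSpectrum(
            entries=[IndelSpectrumEntry(-4, 0, 0.3)], wild_type_fraction=0.7
        )
        res = simulate_amplicon(REF, spectrum, 1000, 0.003, 53, seed=9, outdir=tmp_path)
        s = quantify_fastq(res.fastq, CONFIG)
        import pandas as pd

        truth = pd.read_csv(res.truth, sep="\t")
        true_frac = float((truth.net_length_change != 0).mean())
        assert s.indel_frequency == pytest.approx(100 * true_frac, abs=1e-9)
        lo, hi = binom.interval(0.99, 1000, 0.3)
        assert lo / 10 <= s.indel_frequency <= hi / 10

    def test_error_rate_robustness(self, tmp_path):
        spectrum = IndelSpectrum(
            entries=[IndelSpectrumEntry(-4, 0, 0.3)], wild_type_fraction=0.7
        )
        clean = simulate_amplicon(REF, spectrum, 800, 0.0, 53, seed=21, outdir=tmp_path / "c")
        noisy = simulate_amplicon(REF, spectrum, 800, 0.005, 53, seed=21, outdir=tmp_path / "n")
        s_clean = quantify_fastq(clean.fastq, CONFIG)
        s_noisy = quantify_fastq(noisy.fastq, CONFIG)
        # identical class draws by seed; substitution errors must not move
        # the indel frequency by more than half a percentage point
        assert abs(s_clean.indel_frequency - s_noisy.indel_frequency) <= 0.5


class TestBatchQuantify:
    def _fastq(self, tmp_path, name, frac, seed):
        spectrum = IndelSpectrum(
            entries=[IndelSpectrumEntry(-4, 0, frac)] if frac else [],
            wild_type_fraction=1 - frac,
        )
        return simulate_amplicon(REF, spectrum, 300, 0.0, 53, seed=seed,
                                 outdir=tmp_path, prefix=name).fastq

    def test_two_amplicons_ordered_frequencies(self, tmp_path):
        fq_hi = self._fastq(tmp_path, "hi", 0.5, 1)
        fq_lo = self._fastq(tmp_path, "lo", 0.0, 2)
        cfgs = {
            "hi": AmpliconConfig("hi", REF, (31, 58), min_read_length=20),
            "lo": AmpliconConfig("lo", REF, (31, 58), min_read_length=20),
        }
        df = batch_quantify({"hi": fq_hi, "lo": fq_lo}, cfgs, out_tsv=tmp_path / "s.tsv")
        out = df.set_index("amplicon_id")
        assert out.loc["hi", "indel_frequency"] > out.loc["lo", "indel_frequency"]
        assert (tmp_path / "s.tsv").exists()

    def test_empty_fastq_missing_frequency(self, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        df = batch_quantify(
            {"e": fq}, {"e": AmpliconConfig("e", REF, (31, 58))}, out_tsv=tmp_path / "s.tsv"
        )
        assert df.loc[0, "analyzed_reads"] == 0
        assert df.loc[0, "indel_frequency"] is None or np.isnan(df.loc[0, "indel_frequency"])
        assert "NA" in (tmp_path / "s.tsv").read_text()

    def test_missing_config_error_names_amplicon(self, tmp_path):
        fq = self._fastq(tmp_path, "x", 0.0, 3)
        with pytest.raises(KeyError, match="x"):
            batch_quantify({"x": fq}, {})

    def test_duplicate_amplicon_ids_rejected(self):
        cfg = AmpliconConfig("dup", REF, (31, 58))
        with pytest.raises(ValueError, match="duplicate"):
            batch_quantify({}, [cfg, cfg])
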
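"""Leader annotation: uAUG scan, uORF classes, Kozak, cap proximity.

The scanner is cross-checked against an independent brute-force
implementation that walks every TL offset and translates codon by codon,
and against planted-truth transcripts from the simulator.
"""

import numpy as np
import pytest

from translatome.io import TranscriptRecord
from translatome.simulate import SimSpec, plant_transcript, simulate_transcripts
from translatome.tl_features import (
    annotate_transcript,
    classify_kozak,
    enumerate_uorfs,
    extract_tl,
    scan_uaugs,
)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_uorfs(sequence: str, cds_start: int):
    """Independent oracle: scan every TL offset, translate codon-by-codon.

    Returns tuples (start, frame, orf_class, n_codons, stop_end, gap).
    """
    out = []
    for i in range(cds_start):
        if sequence[i : i + 3] != "ATG":
            continue
        frame = (i - cds_start) % 3
        stop_pos = None
        j = i
        while j + 3 <= len(sequence):
            if sequence[j : j + 3] in STOPS:
                stop_pos = j
                break
            j += 3
        if frame == 0 and (stop_pos is None or stop_pos + 3 > cds_start):
            out.append((i, frame, "in_frame_extension", None, None, None))
        elif stop_pos is not None and stop_pos + 3 <= cds_start:
            out.append(
                (i, frame, "upstream", (stop_pos - i) // 3, stop_pos + 3, cds_start - stop_pos - 3)
            )
        else:
            n = None if stop_pos is None else (stop_pos - i) // 3
            out.append((i, frame, "overlapping", n, None if stop_pos is None else stop_pos + 3, None))
    return out


def _as_tuples(uorfs):
    return [
        (u.start, u.frame, u.orf_class, u.n_codons, u.stop_end, u.gap_to_main) for u in uorfs
    ]


def _record(seq, cds_start, tid="t"):
    return TranscriptRecord(tid, "g", "tss", seq, cds_start)


class TestScan:
    def test_overlapping_and_adjacent_hits(self):
        assert scan_uaugs("ATGATG") == [0, 3]
        assert scan_uaugs("ATATGG") == [2]
        assert scan_uaugs("CCCCCC") == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tl = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 60)))
            expected = [i for i in range(len(tl)) if tl[i : i + 3] == "ATG"]
            assert scan_uaugs(tl) == expected


class TestExtract:
    def test_boundaries(self):
        assert extract_tl(_record("ATGAAATAA", 0)) == ""
        assert extract_tl(_record("GGGATGAAATAA", 3)) == "GGG"

    def test_length_equals_cds_start(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(0, 30))
            seq = "".join(rng.choice(list("ACGT"), size=n)) + "ATGTAA"
            rec = _record(seq, n)
            assert len(extract_tl(rec)) == n


class TestUorfClasses:
    def test_short_upstream_uorf(self):
        # TL: uORF ATG AAA TAG then main ORF immediately after
        rec = _record("ATGAAATAG" + "ATGCCCTAA", 9)
        (u,) = enumerate_uorfs(rec)
        assert u.orf_class == "upstream"
        assert u.n_codons == 2
        assert u.gap_to_main == 0
        assert u.stop_end == 9

    def test_in_frame_extension(self):
        rec = _record("ATGGGG" + "ATGCCCTAA", 6)
        (u,) = enumerate_uorfs(rec)
        assert u.orf_class == "in_frame_extension"
        assert u.frame == 0
        assert u.n_codons is None and u.stop_end is None

    def test_overlapping_out_of_frame(self):
        # uAUG at 2, frame 1 relative to cds_start 7; no in-frame stop at all
        rec = _record("CCATGGG" + "ATGCCCTAAGG", 7)
        (u,) = enumerate_uorfs(rec)
        assert u.orf_class == "overlapping"
        assert u.frame != 0
        assert u.stop_end is None or u.stop_end > 7

    def test_minimal_one_codon_uorf(self):
        """An AUG immediately followed by a stop counts as 1 codon."""
        rec = _record("ATGTAA" + "ATGCCCTAA", 6)
        (u,) = enumerate_uorfs(rec)
        assert u.orf_class == "upstream"
        assert u.n_codons == 1


class TestKozak:
    @pytest.mark.parametrize(
        "context, expected",
        [
            ("GCCATGG", "strong"),
            ("ACCATGC", "moderate"),  # purine at -3 but no G at +4
            ("TCCATGG", "moderate"),
            ("TTTATGT", "weak"),
        ],
    )
    def test_classes(self, context, expected):
        cls, ctx = classify_kozak("NN" + context + "NN", 5)
        assert cls == expected
        assert ctx == context

    def test_edge_padding_with_n(self):
        cls, ctx = classify_kozak("ATGG", 0)
        assert ctx == "NNNATGG"
        assert cls == "moderate"  # N at -3 fails, G at +4 holds
        cls2, ctx2 = classify_kozak("AATG", 1)
        assert ctx2 == "NNAATGN"
        assert cls2 == "weak"

    def test_non_atg_position_rejected(self):
        with pytest.raises(ValueError):
            classify_kozak("GCCATGG", 0)


class TestAnnotate:
    def test_empty_tl(self):
        ann = annotate_transcript(_record("ATGCCCTAA", 0))
        assert ann.tl_length == 0
        assert ann.uaug_positions == []
        assert ann.main_kozak_class in {"strong", "moderate", "weak"}

    def test_cap_proximal_flagging(self):
        # uAUG 12 nt from the cap is below the 15-nt default threshold
        rng = np.random.default_rng(9)
        rec, _ = plant_transcript(rng, tl_length=60, uorf_specs=[(12, 6)])
        ann = annotate_transcript(rec, cap_threshold=15)
        assert ann.cap_proximal_flags == [12]
        ann2 = annotate_transcript(rec, cap_threshold=10)
        assert ann2.cap_proximal_flags == []


class TestOracleEquivalence:
    def test_random_transcripts_match_brute_force(self):
        """1000 random transcripts (len <= 500, GC 0.25-0.75) agree field-for-field."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            gc = rng.uniform(0.25, 0.75)
            total_len = int(rng.integers(9, 501))
            cds_start = int(rng.integers(0, total_len - 8))
            probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            seq = "".join(rng.choice(list("ACGT"), size=total_len, p=probs))
            seq = seq[:cds_start] + "ATG" + seq[cds_start + 3 :]
            rec = _record(seq, cds_start)
            assert _as_tuples(enumerate_uorfs(rec)) == brute_force_uorfs(seq, cds_start)

    def test_monotone_under_downstream_extension(self):
        """Appending sequence after the CDS never changes TL-level fields."""
        rng = np.random.default_rng(77)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            cds_start = 40
            seq = seq[:cds_start] + "ATG" + seq[cds_start + 3 :]
            rec1 = _record(seq, cds_start)
            rec2 = _record(seq + "GGGCCC", cds_start)
            a1, a2 = annotate_transcript(rec1), annotate_transcript(rec2)
            assert a1.uaug_positions == a2.uaug_positions
            assert a1.tl_length == a2.tl_length


class TestPlantedTruth:
    def test_planted_uorf_recovered_exactly(self):
        rng = np.random.default_rng(6)
        rec, truth = plant_transcript(rng, tl_length=120, uorf_specs=[(10, 5)], gc=0.5)
        (u,) = enumerate_uorfs(rec)
        assert (u.start, u.n_codons, u.stop_end) == (10, 5, 10 + 15 + 3)
        assert u.orf_class == "upstream"
        assert u.gap_to_main == 120 - 28

    def test_batch_recovery_against_simulator_truth(self):
        """500 simulated transcripts: scanner output equals planted truth."""
        spec = SimSpec(seed=99)
        records, truth = simulate_transcripts(spec, n_transcripts=500)
        planted = truth.uorfs.groupby("transcript_id")
        for rec in records:
            found = enumerate_uorfs(rec)
            if rec.transcript_id not in planted.groups:
                assert found == []
                continue
            expected = planted.get_group(rec.transcript_id).sort_values("start")
            assert [u.start for u in found] == expected["start"].tolist()
            assert [u.n_codons for u in found] == expected["n_codons"].tolist()
            assert [u.stop_end for u in found] == expected["stop_end"].tolist()
            assert [u.orf_class for u in found] == expected["orf_class"].tolist()
            assert [u.gap_to_main for u in found] == expected["gap_to_main"].tolist()
            assert [u.frame for u in found] == expected["frame"].tolist()

    def test_infeasible_packing_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="fit"):
            plant_transcript(rng, tl_length=10, uorf_specs=[(0, 5)])
        with pytest.raises(ValueError, match="overlap"):
            plant_transcript(rng, tl_length=60, uorf_specs=[(0, 5), (10, 2)])
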
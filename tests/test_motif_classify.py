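import itertools

import numpy as np
import pandas as pd
import pytest

from glycomine.io_formats import BlastHit
from glycomine.motif_classify import (
    AA20,
    SubfamilyCall,
    classify_motif,
    classify_proteome,
    default_patterns,
    filter_hits,
    locate_catalytic_window,
    motif_frequency_matrix,
    scan_motif,
)
from glycomine.synthetic_data import generate_motif_protein


def _hit(evalue, identity, coverage):
    return BlastHit("q", "s", identity, evalue, coverage, 100.0)


class TestFilterHits:
    @pytest.mark.parametrize(
        "evalue,identity,coverage,kept",
        [
            (1e-3, 40.0, 0.9, False),  # fails the 1e-4 e-value cutoff
            (1e-5, 30.0, 0.9, True),
            (1e-5, 20.0, 0.9, False),  # fails the 25% identity cutoff
            (1e-4, 25.0, 0.76, True),  # inclusive e-value/identity bounds
            (1e-5, 30.0, 0.75, False),  # coverage must be strictly > 0.75
        ],
    )
    def test_cutoffs(self, evalue, identity, coverage, kept):
        out = filter_hits([_hit(evalue, identity, coverage)])
        assert bool(out) is kept

    def test_empty_and_order(self):
        assert filter_hits([]) == []
        hits = [_hit(1e-5, 30, 0.9), _hit(1e-6, 40, 0.9)]
        assert filter_hits(hits) == hits


class TestClassifyMotif:
    @pytest.mark.parametrize(
        "window,subfamily,variant",
        [
            ("QID", "YQL", None),
            ("QVQ", "AZL", "QΦQ"),
            ("HVQ", "AZL", "HΦQ"),
            ("HLTD", "AZL2", None),
            ("HMSE", "AZL2", None),
            ("KGE", "UNCLASSIFIED", None),
            ("QIDX"[:3], "YQL", None),
        ],
    )
    def test_examples(self, window, subfamily, variant):
        assert classify_motif(window) == (subfamily, variant)

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            classify_motif("Q-D")

    def test_pure_function(self):
        assert classify_motif("QVD") == classify_motif("QVD")

    def test_exhaustive_trigram_exclusivity(self):
        """No 3-residue window satisfies two patterns (all 8000 trigrams)."""
        patterns = default_patterns()
        tri_patterns = [patterns["YQL"], patterns["AZL"]]
        for tri in map("".join, itertools.product(AA20, repeat=3)):
            assert sum(p.matches(tri) for p in tri_patterns) <= 1

    def test_quadgram_sample_exclusivity(self):
        patterns = default_patterns()
        rng = np.random.default_rng(0)
        aa = np.array(list(AA20))
        for _ in range(5000):
            quad = "".join(rng.choice(aa, 4))
            matches = [p.name for p in patterns.values() if p.matches(quad)]
            assert len(matches) <= 1
            if matches:
                assert matches == ["AZL2"]


class TestLocateWindow:
    def test_identity_query(self, anchors):
        ref = anchors["AZL"]
        start, window = locate_catalytic_window(ref.sequence, ref.sequence, 40, 3)
        assert start == 40 and window == ref.sequence[40:43]

    def test_prefix_padding_shifts_start(self, anchors):
        ref = anchors["YQL"]
        pad = "GPNSTWKRCE"
        start, window = locate_catalytic_window(pad + ref.sequence, ref.sequence, 60, 3)
        assert start == 60 + len(pad)
        assert window == ref.sequence[60:63]

    def test_planted_offset_recovered(self, anchors):
        seq = generate_motif_protein("AZL", 370, 55, seed=9, anchor=anchors["AZL"])
        start, window = locate_catalytic_window(seq, anchors["AZL"].sequence, 40, 3)
        assert start == 55
        assert classify_motif(window)[0] == "AZL"

    def test_empty_sequence_rejected(self, anchors):
        with pytest.raises(ValueError):
            locate_catalytic_window("", anchors["AZL"].sequence, 40, 3)


class TestClassifyProteome:
    def test_single_yql_is_100_percent(self, anchors):
        seq = generate_motif_protein("YQL", 350, 60, seed=1, anchor=anchors["YQL"])
        calls, summary = classify_proteome({"p": seq}, [anchors["AZL"], anchors["YQL"]])
        assert calls[0].subfamily == "YQL"
        row = summary.set_index("subfamily").loc["YQL"]
        assert row["percent"] == 100.0

    def test_planted_mix_recovered_exactly(self, anchors):
        # 49 / 43 / 8 mix scaled down to 25 proteins
        plan = [("YQL", 12), ("AZL", 11), ("AZL2", 2)]
        proteins = {}
        expected = {}
        i = 0
        for subfamily, n in plan:
            anchor = anchors["YQL" if subfamily == "YQL" else "AZL"]
            for _ in range(n):
                pid = f"p{i:03d}"
                proteins[pid] = generate_motif_protein(
                    subfamily, 360, anchor.window_start + (i % 15), seed=[3, i],
                    anchor=anchor,
                )
                expected[pid] = subfamily
                i += 1
        calls, summary = classify_proteome(proteins, [anchors["AZL"], anchors["YQL"]])
        assert {c.protein_id: c.subfamily for c in calls} == expected
        pct = summary.set_index("subfamily")["percent"]
        assert pct["YQL"] == pytest.approx(100 * 12 / 25)
        assert pct.sum() == pytest.approx(100.0, abs=0.1)

    def test_counts_sum_to_inputs(self, anchors, small_truth):
        calls, summary = classify_proteome(
            small_truth.proteins, [anchors["AZL"], anchors["YQL"]]
        )
        assert summary["count"].sum() == len(small_truth.proteins)

    def test_motifless_protein_unclassified(self, anchors):
        seq = generate_motif_protein("UNCLASSIFIED", 300, 0, seed=4)
        calls, _ = classify_proteome({"p": seq}, [anchors["AZL"], anchors["YQL"]])
        assert calls[0].subfamily == "UNCLASSIFIED"

    def test_duplicate_ids_rejected(self, anchors):
        with pytest.raises(ValueError, match="duplicate"):
            classify_proteome([("p", "MKL" * 50), ("p", "MKV" * 50)],
                              [anchors["AZL"]])

    def test_regex_fallback_finds_first_motif(self):
        seq = "MKTA" + "QVD" + "GSRNE" * 10
        assert scan_motif(seq)[:2] == ("YQL", None)
        assert scan_motif("GSRNE" * 10)[0] == "UNCLASSIFIED"


class TestFrequencyMatrix:
    def _calls(self, windows):
        return [SubfamilyCall(f"p{i}", "AZL", w, 0) for i, w in enumerate(windows)]

    def test_identical_windows(self):
        pfm = motif_frequency_matrix(self._calls(["QVQ"] * 7))
        assert pfm.loc["Q", 0] == 1.0 and pfm.loc["V", 1] == 1.0

    def test_half_and_half_first_column(self):
        pfm = motif_frequency_matrix(self._calls(["QVQ", "HVQ"]))
        assert pfm.loc["Q", 0] == 0.5 and pfm.loc["H", 0] == 0.5

    def test_columns_sum_to_one_vs_brute_count(self):
        rng = np.random.default_rng(7)
        aa = np.array(list(AA20))
        windows = ["".join(rng.choice(aa, 3)) for _ in range(60)]
        pfm = motif_frequency_matrix(self._calls(windows))
        assert np.allclose(pfm.sum(axis=0), 1.0)
        # independent counting oracle
        for j in range(3):
            counts = pd.Series([w[j] for w in windows]).value_counts()
            for res, n in counts.items():
                assert pfm.loc[res, j] == pytest.approx(n / 60)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            motif_frequency_matrix(self._calls(["QVQ", "HLTD"]))
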
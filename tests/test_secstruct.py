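"""Secondary-structure reduction, segment extraction, content and the
Welch test."""

import numpy as np
import pytest
from scipy import stats as sps

from nullprot.scoring import DISORDERED, ORDERED, RegionLabeling
from nullprot.secstruct import (
    SSString,
    content,
    content_table,
    extract_segments,
    merge_8_to_3,
    read_ss_fasta,
    segment_length_distribution,
    unpaired_t_test,
    write_ss_fasta,
)


def mask(labels, seq_id="x"):
    return RegionLabeling(seq_id=seq_id, labels=labels, threshold=0.5)


def brute_segments(ss3, labels, region_class):
    """Oracle: enumerate maximal homogeneous H/E runs inside each maximal
    block of positions belonging to the region class."""
    segs = []
    i = 0
    n = len(ss3)
    while i < n:
        if labels[i] != region_class:
            i += 1
            continue
        j = i
        while j < n and labels[j] == region_class:
            j += 1
        k = i
        while k < j:
            st = ss3[k]
            m = k
            while m < j and ss3[m] == st:
                m += 1
            if st in "HE":
                segs.append((st, k + 1, m - k))
            k = m
        i = j
    return segs


class TestMerge:
    def test_published_mapping(self):
        assert merge_8_to_3(SSString("x", "GHIBETSD")).states == "HHHEECCC"

    def test_empty(self):
        assert merge_8_to_3(SSString("x", "")).states == ""

    def test_fixed_points(self):
        assert merge_8_to_3(SSString("x", "HHHH")).states == "HHHH"

    def test_dash_coil_dialect(self):
        assert merge_8_to_3(SSString("x", "-T-")).states == "CCC"

    def test_surjective_onto_three_states(self):
        assert set(merge_8_to_3(SSString("x", "HGIBETSD-")).states) == set("HEC")

    def test_unknown_symbol_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            merge_8_to_3(SSString("x", "HQH"))


class TestSegments:
    def test_direct_runs(self):
        segs = extract_segments(SSString("x", "HHHCEE"), mask("OOOOOO"), ORDERED)
        assert [(s.state, s.start, s.length) for s in segs] == [
            ("H", 1, 3),
            ("E", 5, 2),
        ]

    def test_boundary_split(self):
        segs = extract_segments(SSString("x", "HHHH"), mask("OODD"), ORDERED)
        assert [(s.state, s.start, s.length) for s in segs] == [("H", 1, 2)]
        segs_d = extract_segments(SSString("x", "HHHH"), mask("OODD"), DISORDERED)
        assert [(s.state, s.start, s.length) for s in segs_d] == [("H", 3, 2)]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            extract_segments(SSString("x", "HH"), mask("OOO"), ORDERED)

    def test_matches_bruteforce_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(1, 11)
            ss3 = "".join(rng.choice(list("HEC"), n))
            labels = "".join(rng.choice(["O", "D"], n))
            for cls in (ORDERED, DISORDERED):
                got = [
                    (s.state, s.start, s.length)
                    for s in extract_segments(SSString("x", ss3), mask(labels), cls)
                ]
                assert got == brute_segments(ss3, labels, cls)

    def test_conservation_ties_segments_to_content(self):
        """Summed segment lengths per state equal the state's residue count
        within the region class."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            ss3 = "".join(rng.choice(list("HEC"), 60))
            labels = "".join(rng.choice(["O", "D"], 60))
            for cls in (ORDERED, DISORDERED):
                segs = extract_segments(SSString("x", ss3), mask(labels), cls)
                for st in "HE":
                    total = sum(s.length for s in segs if s.state == st)
                    direct = sum(
                        1 for a, l in zip(ss3, labels) if a == st and l == cls
                    )
                    assert total == direct


class TestContent:
    def test_direct_fractions(self):
        c = content(SSString("x", "HHHHCC"), mask("OOOOOO"), ORDERED)
        assert c.helix_fraction == pytest.approx(4 / 6)
        assert c.sheet_fraction == 0.0

    def test_all_coil(self):
        c = content(SSString("x", "CCCC"), mask("OOOO"), ORDERED)
        assert c.helix_fraction == 0.0 and c.sheet_fraction == 0.0

    def test_no_residues_in_class_excluded(self):
        assert content(SSString("x", "HHH"), mask("OOO"), DISORDERED) is None

    def test_dataset_mean_sd_matches_hand_computation(self):
        fixtures = [
            ("HHCC", "OOOO"),  # helix 0.5
            ("HHHH", "OOOO"),  # 1.0
            ("CCCC", "OOOO"),  # 0.0
            ("HECE", "OOOO"),  # 0.25
            ("HHHC", "OOOO"),  # 0.75
        ]
        rows = [
            content(SSString(f"s{i}", ss), mask(m, f"s{i}"), ORDERED)
            for i, (ss, m) in enumerate(fixtures)
        ]
        table = content_table(rows)
        hf = np.array([0.5, 1.0, 0.0, 0.25, 0.75])
        m, sd, n = table[(ORDERED, "helix")]
        assert n == 5
        assert m == pytest.approx(hf.mean())
        assert sd == pytest.approx(hf.std(ddof=0))


class TestWelch:
    def test_identical_samples(self):
        t, p = unpaired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_textbook_pair_hand_formulas(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        # by hand: means 2 and 5, s^2 = 1 each, n = 3
        # t = (2-5)/sqrt(1/3+1/3) = -3/sqrt(2/3); df = (2/3)^2/(2*(1/3)^2/2) = 4
        t, p = unpaired_t_test(x, y)
        assert t == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-12)
        expected_p = 2 * sps.t.sf(abs(t), 4)
        assert p == pytest.approx(expected_p, abs=1e-12)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            x = rng.normal(size=rng.integers(2, 40))
            y = rng.normal(loc=rng.normal(), size=rng.integers(2, 40))
            t, p = unpaired_t_test(x, y)
            ref = sps.ttest_ind(x, y, equal_var=False)
            assert abs(t - ref.statistic) < 1e-10
            assert abs(p - ref.pvalue) < 1e-10

    def test_large_shift_is_significant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 0.1, 100)
        y = rng.normal(1.0, 0.1, 100)
        _, p = unpaired_t_test(x, y)
        assert p < 1e-6

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            unpaired_t_test([1.0, 1.0], [2.0, 2.0])


class TestSegmentLengthDistribution:
    def _segs(self, n, state="H", length=3):
        from nullprot.secstruct import Segment

        return [Segment(f"p{i}", state, 1, length, ORDERED) for i in range(n)]

    def test_low_support_suppressed(self):
        rows = segment_length_distribution(self._segs(4), 100, 5)
        assert len(rows) == 1 and rows[0]["suppressed"]

    def test_filter_zero_reports_all(self):
        rows = segment_length_distribution(self._segs(4), 100, 0)
        assert not rows[0]["suppressed"]

    def test_fractions_sum_to_one_per_state(self):
        segs = self._segs(4, "H", 3) + self._segs(2, "H", 5) + self._segs(3, "E", 2)
        rows = segment_length_distribution(segs, 100, 5)
        for state in "HE":
            assert sum(r["fraction"] for r in rows if r["state"] == state) == (
                pytest.approx(1.0)
            )

    def test_log2_scaling(self):
        rows = segment_length_distribution(self._segs(4), 100, 0)
        assert rows[0]["log2_fraction_x10000"] == pytest.approx(np.log2(10000))


class TestSSIO:
    def test_fasta_like_round_trip(self, tmp_path):
        recs = [SSString("a", "HHEECC" * 15), SSString("b", "CCC")]
        p = tmp_path / "ss.fasta"
        write_ss_fasta(recs, p)
        assert read_ss_fasta(p) == recs
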
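"""Peak decoding, genotype calling and configuration flags."""

import random

import pytest

from ssu1_checkup.panel import (
    AmbiguousPeakError,
    DyeChannel,
    PanelError,
    Peak,
    call_chr16_genotype,
    classify_configuration,
    decode_peaks,
    load_panel,
)


def mkpeaks(*specs, sample="s1"):
    return [Peak(sample, DyeChannel(d), s) for d, s in specs]


class TestLoadPanel:
    def test_default_panel_contains_published_alleles(self, panel):
        xvi = panel.by_id("XVI-wt^991")
        assert xvi.expected_size_bp == 991
        assert xvi.dye_set == frozenset({DyeChannel.HEX})
        sizes = {
            a.allele_id: a.expected_size_bp
            for a in panel.alleles
            if a.expected_size_bp is not None
        }
        assert sizes["VIII-t-XVI^388"] == 388
        assert sizes["VIII-t-XVI^478"] == 478
        assert sizes["VIII-t-XVI^555"] == 555
        assert sizes["VIII-t-XVI^631"] == 631
        assert sizes["XV-t-XVI^496"] == 496
        assert sizes["inv-XVI^781"] == 781
        assert sizes["XV-wt^702"] == 702

    def test_cen16_linkage_follows_hex_dye(self, panel):
        for a in panel.alleles:
            assert a.cen16_linked == (DyeChannel.HEX in a.dye_set)

    def test_colliding_alleles_rejected(self):
        config = {
            "size_tolerance_bp": 3,
            "alleles": [
                {"allele_id": "a", "chrom_class": "XVI-wt", "size": 991, "dyes": ["HEX"]},
                {"allele_id": "b", "chrom_class": "XVI-wt", "size": 992, "dyes": ["HEX"]},
            ],
        }
        with pytest.raises(PanelError, match="collide"):
            load_panel(config)

    def test_empty_panel_rejected(self):
        with pytest.raises(PanelError):
            load_panel({"alleles": []})

    def test_unknown_dye_rejected(self):
        config = {
            "alleles": [
                {"allele_id": "a", "chrom_class": "XVI-wt", "size": 991, "dyes": ["CY5"]}
            ]
        }
        with pytest.raises(PanelError, match="dye"):
            load_panel(config)


class TestDecodePeaks:
    @pytest.mark.parametrize(
        "peaks, expected",
        [
            ([("HEX", 991.3)], ["XVI-wt^991"]),
            ([("FAM", 555.0), ("HEX", 554.6)], ["VIII-t-XVI^555"]),
            (
                [("ATTO550", 702), ("ATTO565", 781), ("HEX", 781)],
                ["XV-wt^702", "inv-XVI^781"],
            ),
            ([], []),
            ([("FAM", 604)], ["VIII-wt"]),  # wt-VIII matches by size range
        ],
    )
    def test_worked_examples(self, panel, peaks, expected):
        result = decode_peaks(mkpeaks(*peaks), panel)
        assert result.allele_ids == sorted(expected)
        assert result.unassigned == []

    def test_dual_dye_requires_comigration(self, panel):
        # HEX at 496 without an ATTO550 partner is not the XV-t-XVI junction
        result = decode_peaks(mkpeaks(("HEX", 496.0)), panel)
        assert result.calls == []
        assert len(result.unassigned) == 1

    def test_fam_peak_with_hex_partner_is_junction_not_wt(self, panel):
        # 555 lies inside the wt-VIII size range but the HEX partner proves
        # the fragment is the VIII-t-XVI junction
        result = decode_peaks(mkpeaks(("FAM", 555.0), ("HEX", 555.2)), panel)
        assert result.allele_ids == ["VIII-t-XVI^555"]

    def test_each_peak_supports_at_most_one_call(self, panel):
        peaks = mkpeaks(
            ("FAM", 555.0), ("HEX", 555.0), ("ATTO550", 496.0), ("HEX", 496.0)
        )
        result = decode_peaks(peaks, panel)
        used = [id(p) for c in result.calls for p in c.supporting_peaks]
        assert len(used) == len(set(used)) == 4

    def test_order_invariance(self, panel):
        peaks = mkpeaks(
            ("HEX", 991.0), ("FAM", 555.0), ("HEX", 555.0), ("ATTO550", 702.0)
        )
        base = decode_peaks(peaks, panel).allele_ids
        rng = random.Random(0)
        for _ in range(10):
            shuffled = peaks[:]
            rng.shuffle(shuffled)
            assert decode_peaks(shuffled, panel).allele_ids == base

    def test_ambiguous_peak_raises(self):
        # A collision-free panel cannot produce ties, but a tolerance widened
        # after validation can; the decoder must refuse to tie-break silently.
        config = {
            "size_tolerance_bp": 3,
            "alleles": [
                {"allele_id": "lo", "chrom_class": "XVI-wt", "size": 100, "dyes": ["HEX"]},
                {"allele_id": "hi", "chrom_class": "XVI-wt", "size": 110, "dyes": ["HEX"]},
            ],
        }
        p = load_panel(config)
        p.size_tolerance_bp = 6.0
        with pytest.raises(AmbiguousPeakError):
            decode_peaks(mkpeaks(("HEX", 105.0)), p)  # equidistant from lo/hi

    def test_liz_rows_ignored(self, panel):
        peaks = mkpeaks(("HEX", 991.0), ("LIZ", 600.0))
        assert decode_peaks(peaks, panel).allele_ids == ["XVI-wt^991"]


class TestCallGenotype:
    def test_single_allele_duplicated_homozygous(self, panel):
        decoded = decode_peaks(mkpeaks(("HEX", 991.0)), panel)
        g = call_chr16_genotype(decoded, panel)
        assert g.cen16_alleles == ("XVI-wt^991", "XVI-wt^991")
        assert g.zygosity == "homozygous"
        assert g.copy_number == 2

    def test_three_distinct_alleles_is_aneuploid(self, panel):
        """The reference aneuploid strain carries wt-991, 555 and 496 at once."""
        peaks = mkpeaks(
            ("HEX", 991.0),
            ("FAM", 555.0), ("HEX", 555.0),
            ("ATTO550", 496.0), ("HEX", 496.0),
        )
        g = call_chr16_genotype(decode_peaks(peaks, panel), panel)
        assert g.zygosity == "aneuploid"
        assert g.copy_number == 3
        assert set(g.cen16_alleles) == {
            "XVI-wt^991", "VIII-t-XVI^555", "XV-t-XVI^496"
        }

    def test_no_peaks_flags_no_amplification(self, panel):
        g = call_chr16_genotype(decode_peaks([], panel), panel)
        assert g.zygosity == "no_amplification"
        assert g.copy_number == 0
        assert g.cen16_alleles == ()

    def test_copy_number_at_least_two_when_observed(self, panel, cen16_allele_ids):
        for a in cen16_allele_ids:
            allele = panel.by_id(a)
            peaks = [
                Peak("s", d, float(allele.expected_size_bp))
                for d in allele.dye_set
            ]
            g = call_chr16_genotype(decode_peaks(peaks, panel), panel)
            assert g.copy_number >= 2

    def test_wt_viii_records_as_other_allele(self, panel):
        decoded = decode_peaks(mkpeaks(("HEX", 991.0), ("FAM", 604.0)), panel)
        g = call_chr16_genotype(decoded, panel)
        assert g.other_alleles == frozenset({"VIII-wt"})
        assert g.copy_number == 2


class TestClassifyConfiguration:
    @pytest.mark.parametrize(
        "peaks, has_cr, label",
        [
            ([("HEX", 991.0)], False, "991:991"),
            ([("FAM", 555.0), ("HEX", 555.0)], True, "555:555"),
            (
                [("HEX", 991.0), ("ATTO550", 496.0), ("HEX", 496.0)],
                True,
                "991:496",
            ),
        ],
    )
    def test_flags_and_labels(self, panel, peaks, has_cr, label):
        g = call_chr16_genotype(decode_peaks(mkpeaks(*peaks), panel), panel)
        flags = classify_configuration(g, panel)
        assert flags.has_CR is has_cr
        assert flags.label == label

    def test_no_amplification_label(self, panel):
        g = call_chr16_genotype([], panel)
        flags = classify_configuration(g, panel)
        assert flags.label == "NA:NA"
        assert not flags.has_CR
        assert not any(flags.class_presence.values())
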
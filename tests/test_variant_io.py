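"""Panel container, VCF round trips, polarization rule and window iteration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from balscan.panel import GenomicWindow, HaplotypePanel
from balscan.synthetic_data import ScenarioSpec, generate_panel
from balscan.variant_io import (
    ReadReport,
    iter_windows,
    polarize_reference,
    read_haplotype_panel,
    read_popmap,
    write_popmap,
    write_vcf,
)
from tests.conftest import make_panel


class TestGenomicWindow:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            GenomicWindow("1", 10, 10)
        with pytest.raises(ValueError):
            GenomicWindow("1", -1, 5)

    def test_position_membership_is_half_open(self):
        win = GenomicWindow("1", 100, 200)
        assert win.contains_position(101)
        assert win.contains_position(200)
        assert not win.contains_position(100)
        assert not win.contains_position(201)


class TestHaplotypePanel:
    def test_shape_and_invariant_checks(self):
        with pytest.raises(ValueError):
            make_panel([[0, 1], [1, 0]], positions=[5, 5])
        with pytest.raises(ValueError):
            make_panel([[0, 2], [1, 0]])
        with pytest.raises(ValueError):
            HaplotypePanel(
                matrix=np.zeros((2, 3), dtype=np.int8),
                positions=np.array([1, 2, 3]),
                populations=np.array(["A"], dtype=object),
            )

    def test_population_helpers(self):
        panel = make_panel(
            [[0, 1], [1, 0], [0, 0], [1, 1]],
            populations=["A", "A", "B", "B"],
        )
        assert panel.population_names() == ["A", "B"]
        assert panel.derived_frequency(0, "B") == 0.5
        sub = panel.subset("A")
        assert sub.n_haplotypes == 2
        assert list(sub.populations) == ["A", "A"]


class TestPolarizeReference:
    @pytest.mark.parametrize(
        "ref_freq, anc_as_derived, anc_freq, expected",
        [
            (0.005, False, None, "replace"),  # essentially absent reference
            (0.30, True, 0.30, "replace"),  # ancestral still segregates >1%
            (0.995, False, None, "keep"),  # common reference retained
            (0.30, True, 0.005, "keep"),  # ancestral present but rare
        ],
    )
    def test_replacement_rule(self, ref_freq, anc_as_derived, anc_freq, expected):
        assert polarize_reference(ref_freq, anc_as_derived, anc_freq) == expected

    def test_rejects_invalid_frequency(self):
        with pytest.raises(ValueError):
            polarize_reference(1.5, False)


class TestIterWindows:
    def test_exact_tiling(self):
        wins = list(iter_windows(20_000, 10_000, 2_000))
        assert len(wins) == 6
        assert [w.start for w in wins] == [0, 2000, 4000, 6000, 8000, 10000]

    def test_window_equal_to_region(self):
        wins = list(iter_windows(10_000, 10_000, 2_000))
        assert len(wins) == 1
        assert (wins[0].start, wins[0].end) == (0, 10_000)

    def test_enumerated_partial_region(self):
        wins = list(iter_windows(25_000, 10_000, 2_000))
        assert len(wins) == 8
        assert (wins[-1].start, wins[-1].end) == (14_000, 24_000)

    def test_oversized_window_warns_and_yields_nothing(self):
        with pytest.warns(UserWarning):
            assert list(iter_windows(5_000, 10_000, 1_000)) == []

    @given(
        region=st.integers(1, 5000),
        window=st.integers(1, 5000),
        step=st.integers(1, 1000),
    )
    def test_overlap_is_window_minus_step(self, region, window, step):
        wins = list(iter_windows(region, window, step)) if window <= region else []
        for a, b in zip(wins, wins[1:]):
            overlap = max(0, a.end - b.start)
            assert overlap == max(0, window - step)
            assert b.start - a.start == step


class TestVcfRoundTrip:
    def test_write_read_identity(self, tmp_path):
        spec = ScenarioSpec(
            scenario_name="neutral",
            sample_sizes={"AFR": 8, "EUR": 6},
            target_freqs={"AFR": 0.25, "EUR": 0.5},
            region_length=5_000,
            seed=11,
            pool_window=0.5,
        )
        panel = generate_panel(spec)
        vcf = tmp_path / "panel.vcf"
        popmap = tmp_path / "panel.popmap.tsv"
        write_vcf(panel, vcf)
        write_popmap(panel, popmap)
        back = read_haplotype_panel(vcf, popmap)
        assert np.array_equal(back.matrix, panel.matrix)
        assert np.array_equal(back.positions, panel.positions)
        assert list(back.populations) == list(panel.populations)
        assert back.focal_index == panel.focal_index
        assert read_popmap(popmap)  # parses

    def test_alt_ancestral_record_is_flipped(self, tmp_path):
        vcf = tmp_path / "flip.vcf"
        popmap = tmp_path / "flip.popmap.tsv"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t10\t.\tA\tT\t.\tPASS\tAA=T\tGT\t0|1\t0|0\n"  # ancestral = ALT
            "1\t20\t.\tG\tC\t.\tPASS\tAA=G\tGT\t1|0\t0|1\n"
        )
        popmap.write_text("s1\tX\ns2\tX\n")
        panel = read_haplotype_panel(vcf, popmap)
        # first record: REF carriers are the derived ones after flipping
        assert list(panel.matrix[:, 0]) == [1, 0, 1, 1]
        assert list(panel.matrix[:, 1]) == [1, 0, 0, 1]

    def test_records_without_ancestral_are_dropped_and_counted(self, tmp_path):
        vcf = tmp_path / "na.vcf"
        popmap = tmp_path / "na.popmap.tsv"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0|1\n"
            "1\t20\t.\tA\tT\t.\tPASS\tAA=G\tGT\t0|1\n"
            "1\t30\t.\tA\tT\t.\tPASS\tAA=A\tGT\t1|1\n"
        )
        popmap.write_text("s1\tX\n")
        report = ReadReport()
        panel = read_haplotype_panel(vcf, popmap, report=report)
        assert panel.n_sites == 1
        assert report.n_no_ancestral == 2

    def test_unphased_genotype_raises_with_coordinate(self, tmp_path):
        vcf = tmp_path / "unphased.vcf"
        popmap = tmp_path / "unphased.popmap.tsv"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t42\t.\tA\tT\t.\tPASS\tAA=A\tGT\t0/1\n"
        )
        popmap.write_text("s1\tX\n")
        with pytest.raises(ValueError, match="42"):
            read_haplotype_panel(vcf, popmap)

    def test_sample_missing_from_popmap_is_named(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        popmap = tmp_path / "m.popmap.tsv"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=1,length=1000>\n"
            '##INFO=<ID=AA,Number=1,Type=String,Description="AA">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tlost_sample\n"
            "1\t10\t.\tA\tT\t.\tPASS\tAA=A\tGT\t0|1\n"
        )
        popmap.write_text("other\tX\n")
        with pytest.raises(KeyError, match="lost_sample"):
            read_haplotype_panel(vcf, popmap)
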
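"""Spectrum container, I/O, referencing, peak picking, integration,
sideband flagging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resinate import config
from resinate.errors import (
    ContractError,
    InvalidSpectrumError,
    OutOfRangeError,
    ParseError,
)
from resinate.specmodel import (
    Peak,
    PeakTable,
    Spectrum,
    assign_peaks,
    flag_sidebands,
    integrate_peak,
    load_peak_table,
    load_spectrum,
    pick_peaks,
    reference_shift,
    save_peak_table,
    save_spectrum,
)

from conftest import make_spectrum


class TestSpectrumIO:
    def test_csv_round_trip_descending(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("180,0.1\n170,0.9\n160,0.2\n")
        s = load_spectrum(p)
        assert len(s) == 3
        np.testing.assert_allclose(s.ppm_axis, [180, 170, 160])
        np.testing.assert_allclose(s.intensity, [0.1, 0.9, 0.2])

    def test_ascending_input_sorted_consistently(self, tmp_path):
        pa = tmp_path / "asc.csv"
        pa.write_text("160,0.2\n170,0.9\n180,0.1\n")
        pd = tmp_path / "desc.csv"
        pd.write_text("180,0.1\n170,0.9\n160,0.2\n")
        a, d = load_spectrum(pa), load_spectrum(pd)
        np.testing.assert_array_equal(a.ppm_axis, d.ppm_axis)
        np.testing.assert_array_equal(a.intensity, d.intensity)

    def test_parse_error_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("180,0.1\n170,oops\n160,0.2\n")
        with pytest.raises(ParseError) as err:
            load_spectrum(p)
        assert err.value.line == 2

    def test_too_few_points_rejected(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("180,0.1\n")
        with pytest.raises(InvalidSpectrumError):
            load_spectrum(p)

    def test_metadata_header_parsed_and_round_tripped(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("# contact_time: 1000\n# sample_id: MQ\n180,1\n160,2\n")
        s = load_spectrum(p)
        assert s.meta["contact_time"] == 1000.0
        assert s.meta["sample_id"] == "MQ"
        out = tmp_path / "o.csv"
        save_spectrum(s, out)
        s2 = load_spectrum(out)
        assert s2.meta["contact_time"] == 1000.0
        np.testing.assert_allclose(s2.ppm_axis, s.ppm_axis)

    def test_jcamp_single_block(self, tmp_path):
        p = tmp_path / "s.jdx"
        p.write_text(
            "##TITLE=demo\n##JCAMP-DX=4.24\n##NPOINTS=5\n"
            "##FIRSTX=200\n##LASTX=100\n##YFACTOR=0.5\n"
            "##XYDATA=(X++(Y..Y))\n200 2 4 6\n150 8 10\n##END=\n"
        )
        s = load_spectrum(p, dialect="jcamp")
        assert len(s) == 5
        assert s.meta["sample_id"] == "demo"
        # YFACTOR applied, axis flipped to descending
        np.testing.assert_allclose(sorted(s.intensity), [1, 2, 3, 4, 5])

    def test_peak_table_round_trip(self, tmp_path):
        t = PeakTable([Peak(145.2, "C2", (143.0, 147.0)),
                       Peak(67.8, "C11", (65.0, 70.0), overlap_group="R")])
        p = tmp_path / "t.csv"
        save_peak_table(t, p)
        t2 = load_peak_table(p)
        assert t2.assignments == ["C2", "C11"]
        assert t2.peaks[1].overlap_group == "R"

    def test_nonmonotone_axis_rejected(self):
        with pytest.raises(InvalidSpectrumError):
            Spectrum(np.array([180.0, 160.0, 170.0]), np.zeros(3))


class TestReferencing:
    def test_glycine_carbonyl_alignment(self):
        # axis chosen so the observed carbonyl sits exactly on a grid point
        s = make_spectrum([175.0], [1.0], axis=(0.0, 200.0, 4001))
        ref = reference_shift(s, observed_ref=175.0)
        i = np.argmax(ref.intensity)
        assert ref.ppm_axis[i] == pytest.approx(176.03, abs=1e-9)
        assert ref.meta["reference_offset_ppm"] == pytest.approx(1.03)

    def test_identity_when_already_referenced(self):
        s = make_spectrum([176.03], [1.0])
        ref = reference_shift(s, observed_ref=176.03)
        np.testing.assert_array_equal(ref.ppm_axis, s.ppm_axis)
        np.testing.assert_array_equal(ref.intensity, s.intensity)

    def test_out_of_range_reference_rejected(self):
        s = make_spectrum([100.0], [1.0], axis=(50.0, 150.0, 1024))
        with pytest.raises(OutOfRangeError):
            reference_shift(s, observed_ref=300.0)

    @given(offset=st.floats(-50, 50),
           observed=st.floats(10.0, 190.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_translation_preserves_pairwise_differences(self, offset,
                                                        observed):
        s = make_spectrum([100.0, 110.0], [1.0, 0.5])
        ref = reference_shift(s, observed, true_ref=observed + offset)
        np.testing.assert_allclose(np.diff(ref.ppm_axis),
                                   np.diff(s.ppm_axis), rtol=0, atol=1e-12)


class TestPeakPicking:
    def test_single_noiseless_lorentzian(self):
        s = make_spectrum([114.4], [1.0])
        t = pick_peaks(s, min_prominence=0.1, min_separation=0.5)
        assert len(t) == 1
        assert abs(t.peaks[0].center - 114.4) <= s.axis_step()

    def test_resolved_triplet_counted(self):
        # the C11 splitting pattern: 1.6-1.7 ppm spacings at 60 Hz linewidth
        s = make_spectrum([70.2, 68.6, 66.9], [1.0, 0.8, 0.9])
        t = pick_peaks(s, min_prominence=0.1, min_separation=0.8)
        assert len(t) == 3
        for truth, got in zip([70.2, 68.6, 66.9],
                              [p.center for p in t.peaks]):
            assert abs(got - truth) <= s.axis_step()

    def test_merge_rule_keeps_taller(self):
        s = make_spectrum([100.0, 100.3], [1.0, 0.6])
        t = pick_peaks(s, min_prominence=0.05, min_separation=1.0)
        assert len(t) == 1
        assert abs(t.peaks[0].center - 100.0) <= 2 * s.axis_step()

    def test_flat_spectrum_gives_empty_table(self):
        s = Spectrum(np.linspace(0, 200, 1024), np.ones(1024))
        assert len(pick_peaks(s)) == 0

    def test_well_separated_lines_all_found(self):
        centers = [180.0, 145.2, 114.4, 67.8, 21.0]
        s = make_spectrum(centers, [0.5, 1.0, 0.7, 0.9, 0.6])
        t = pick_peaks(s, min_prominence=0.1, min_separation=1.0)
        assert len(t) == len(centers)


class TestIntegration:
    def test_unit_area_lorentzian(self):
        # unit-area line: amplitude pi*hw gives peak-normalized height such
        # that the analytic integral is 1; window +/-40 FWHM keeps the
        # truncated tail below 2%
        fwhm = 0.6
        hw = fwhm / 2
        x = np.linspace(0, 200, 40000)
        y = (1 / np.pi) * hw / ((x - 100.0) ** 2 + hw**2)
        s = Spectrum(x, y)
        peak = Peak(100.0, "X", (100 - 40 * fwhm, 100 + 40 * fwhm))
        assert integrate_peak(s, peak, "area") == pytest.approx(1.0, rel=0.02)

    def test_zero_intensity_integrates_to_zero(self):
        s = Spectrum(np.linspace(0, 10, 512), np.zeros(512))
        assert integrate_peak(s, Peak(5.0, "", (2.0, 8.0)), "area") == 0.0

    def test_linearity_and_additivity(self):
        # window edges on grid points so subinterval trapezoids tile exactly
        s = make_spectrum([50.0, 150.0], [1.0, 2.0],
                          axis=(0.0, 200.0, 4001))
        p1 = Peak(50.0, "", (40.0, 60.0))
        p2 = Peak(150.0, "", (140.0, 160.0))
        both = Peak(100.0, "", (40.0, 160.0))
        a1 = integrate_peak(s, p1)
        a2 = integrate_peak(s, p2)
        s2 = Spectrum(s.ppm_axis, 2 * s.intensity)
        assert integrate_peak(s2, p1) == pytest.approx(2 * a1, rel=1e-12)
        assert integrate_peak(s2, p1, "height") == pytest.approx(
            2 * integrate_peak(s, p1, "height"), rel=1e-12)
        # disjoint-window additivity (cross-tails are part of each window)
        assert integrate_peak(s, both) == pytest.approx(
            a1 + a2 + integrate_peak(s, Peak(100.0, "", (60.0, 140.0))),
            rel=1e-9)

    def test_window_outside_axis_rejected(self):
        s = make_spectrum([50.0], [1.0], axis=(0.0, 100.0, 512))
        with pytest.raises(OutOfRangeError):
            integrate_peak(s, Peak(150.0, "", (140.0, 160.0)))


class TestSidebands:
    spacing = config.DEFAULT_SPIN_RATE_HZ / config.DEFAULT_LARMOR_MHZ

    def test_spacing_value(self):
        # 9800 Hz at the 9.4 T carbon frequency
        assert self.spacing == pytest.approx(97.406, abs=0.001)
        # cross-check the field-derived Larmor frequency against the
        # instrument-reported one
        assert config.DEFAULT_FIELD_T * config.GAMMA_13C_MHZ_PER_T == \
            pytest.approx(config.DEFAULT_LARMOR_MHZ, rel=0.01)

    def _family(self):
        iso = Peak(148.5, "", (147.5, 149.5), height=1.0)
        sat = Peak(148.5 - self.spacing, "", (50.0, 52.2), height=0.1)
        return PeakTable([iso, sat])

    def test_satellite_flagged_minus_one(self):
        out = flag_sidebands(self._family(), config.DEFAULT_SPIN_RATE_HZ,
                             config.DEFAULT_LARMOR_MHZ, max_order=2)
        assert not out.peaks[0].is_sideband
        assert out.peaks[1].is_sideband
        assert out.peaks[1].sideband_order == -1

    def test_idempotent_and_strongest_never_flagged(self):
        once = flag_sidebands(self._family(), config.DEFAULT_SPIN_RATE_HZ,
                              config.DEFAULT_LARMOR_MHZ)
        twice = flag_sidebands(once, config.DEFAULT_SPIN_RATE_HZ,
                               config.DEFAULT_LARMOR_MHZ)
        assert [(p.is_sideband, p.sideband_order) for p in once] == \
            [(p.is_sideband, p.sideband_order) for p in twice]
        assert not twice.peaks[0].is_sideband

    def test_no_candidates_table_unchanged(self):
        t = PeakTable([Peak(148.5, "", (147.5, 149.5), height=1.0),
                       Peak(100.0, "", (99.0, 101.0), height=0.5)])
        out = flag_sidebands(t, 2_000_000.0, config.DEFAULT_LARMOR_MHZ)
        assert all(not p.is_sideband for p in out)


class TestAssignment:
    def test_nearest_center_join_with_gate(self):
        picked = PeakTable([Peak(145.3, "", (144.0, 146.0)),
                            Peak(90.0, "", (89.0, 91.0))])
        ref = PeakTable([Peak(145.2, "C2", (143.0, 147.0))])
        out = assign_peaks(picked, ref, gate_ppm=0.5)
        assert out.peaks[0].assignment == "C2"
        assert out.peaks[1].assignment == ""

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ContractError):
            PeakTable([Peak(100.0, "A", (99.0, 101.0)),
                       Peak(100.5, "B", (100.0, 102.0))])
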
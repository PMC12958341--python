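"""FID processing, line shape, calibration, integration and file formats."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import rcfqnmr as rq
from rcfqnmr.processing import (
    CalibrationError,
    Fid,
    FormatError,
    InputError,
    RangeError,
    Spectrum,
    estimate_noise,
)


def single_line_fid(offset_hz=200.0, r2=3.0, sf=400.0, sw_hz=5000.0, aq=2.0, amp=1.0):
    dt = 1.0 / sw_hz
    t = np.arange(int(aq * sw_hz)) * dt
    pts = amp * np.exp((2j * np.pi * offset_hz - r2) * t)
    return Fid(points=pts, dwell_s=dt, sf_mhz=sf, carrier_ppm=5.0)


def measured_fwhm_hz(spec, sf):
    y = spec.intensity
    k = int(np.argmax(y))
    half = y[k] / 2
    x = spec.ppm
    left = right = None
    for i in range(k, 0, -1):
        if y[i - 1] < half <= y[i]:
            f = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + f * (x[i] - x[i - 1])
            break
    for i in range(k, y.size - 1):
        if y[i + 1] < half <= y[i]:
            f = (half - y[i + 1]) / (y[i] - y[i + 1])
            right = x[i + 1] + f * (x[i] - x[i + 1])
            break
    return abs(left - right) * sf


def test_zero_fid_gives_zero_spectrum():
    fid = Fid(points=np.zeros(256, complex), dwell_s=1e-4, sf_mhz=400.0, carrier_ppm=5.0)
    spec = rq.process_fid(fid, 0.3, 1)
    assert np.allclose(spec.intensity, 0.0)
    assert spec.ppm.size == 512


def test_empty_fid_rejected():
    with pytest.raises(InputError):
        Fid(points=np.array([]), dwell_s=1e-4, sf_mhz=400.0, carrier_ppm=5.0)


def test_lorentzian_fwhm_matches_closed_form():
    """exp(-R2 t) plus LB Hz broadening gives FWHM = R2/pi + LB."""
    r2, lb = 3.0, 0.3
    fid = single_line_fid(r2=r2)
    spec = rq.process_fid(fid, line_broadening_hz=lb, zero_fill_levels=2)
    expected = r2 / math.pi + lb
    assert measured_fwhm_hz(spec, fid.sf_mhz) == pytest.approx(expected, rel=0.05)
    # the peak sits at carrier + offset/sf
    peak_ppm = spec.ppm[int(np.argmax(spec.intensity))]
    assert peak_ppm == pytest.approx(5.0 + 200.0 / 400.0, abs=2 * spec.dx)


def test_zero_fill_preserves_window_integrals():
    fid = single_line_fid()
    s0 = rq.process_fid(fid, 0.3, 0)
    s1 = rq.process_fid(fid, 0.3, 1)
    window = (5.3, 5.7)
    i0 = rq.integrate_region(s0, window)
    i1 = rq.integrate_region(s1, window)
    assert i1 == pytest.approx(i0, rel=0.01)


def test_total_integral_tracks_first_apodized_point():
    """Sum over the whole spectrum equals (first apodized point)/2 * sw_ppm."""
    for lb in (0.0, 1.0):
        fid = single_line_fid(amp=2.5)
        spec = rq.process_fid(fid, line_broadening_hz=lb, zero_fill_levels=1)
        sw_ppm = fid.sweep_width_hz / fid.sf_mhz
        total = -np.trapezoid(spec.intensity, spec.ppm)  # descending axis
        assert total == pytest.approx(2.5 * sw_ppm / 2.0, rel=1e-3)


def test_lorentzian_window_fraction_analytic():
    """Area within +/-20 FWHM of a Lorentzian is (2/pi) atan(40) of total."""
    r2 = math.pi  # FWHM = 1 Hz with no extra broadening
    fid = single_line_fid(offset_hz=0.0, r2=r2)
    spec = rq.process_fid(fid, line_broadening_hz=0.0, zero_fill_levels=1)
    f_ppm = 1.0 / fid.sf_mhz
    c = 5.0
    frac_window = rq.integrate_region(spec, (c - 20 * f_ppm, c + 20 * f_ppm))
    total = -np.trapezoid(spec.intensity, spec.ppm)
    expected = (2 / math.pi) * math.atan(40.0)
    assert frac_window / total == pytest.approx(expected, rel=0.01)


def test_integrate_zero_and_constant_baseline():
    ppm = np.linspace(10, 0, 1001)
    zero = Spectrum(ppm, np.zeros_like(ppm), 400.0)
    assert rq.integrate_region(zero, (2, 4)) == 0.0
    const = Spectrum(ppm, np.full_like(ppm, 3.3), 400.0)
    assert rq.integrate_region(const, (2, 4), baseline="endpoints_linear") == pytest.approx(0.0, abs=1e-12)
    # closed interval recovers the full constant area; the default interval
    # is half-open so adjacent windows never double-count their shared point
    assert rq.integrate_region(const, (2, 4), closed_upper=True) == pytest.approx(6.6, rel=1e-6)


def test_integrate_range_errors():
    ppm = np.linspace(10, 0, 101)
    spec = Spectrum(ppm, np.zeros_like(ppm), 400.0)
    with pytest.raises(RangeError):
        rq.integrate_region(spec, (9, 11))


@given(a=st.floats(min_value=-5, max_value=5, allow_nan=False))
def test_integration_linearity(a):
    ppm = np.linspace(8, 2, 601)
    rng = np.random.default_rng(0)
    y = rng.normal(size=ppm.size)
    spec = Spectrum(ppm, y, 400.0)
    base = rq.integrate_region(spec, (3, 7))
    scaled = rq.integrate_region(spec.scaled(a), (3, 7))
    assert scaled == pytest.approx(a * base, rel=1e-9, abs=1e-9)


# -- calibration -------------------------------------------------------------

def test_calibrate_already_aligned():
    fid = single_line_fid(offset_hz=0.0)
    spec = rq.process_fid(fid, 0.3, 1)
    out = rq.calibrate_ppm(spec, 5.0, (4.9, 5.1))
    assert out.provenance["calibration_shift_ppm"] == pytest.approx(0.0, abs=spec.dx)


def test_calibrate_recovers_known_offset():
    fid = single_line_fid(offset_hz=0.0)
    spec = rq.process_fid(fid, 0.3, 1)
    shifted = Spectrum(spec.ppm + 0.02, spec.intensity, spec.sf_mhz)
    out = rq.calibrate_ppm(shifted, 5.0, (4.9, 5.1))
    assert out.provenance["calibration_shift_ppm"] == pytest.approx(-0.02, abs=spec.dx)


def test_calibrate_flat_spectrum_fails():
    ppm = np.linspace(10, 0, 1001)
    flat = Spectrum(ppm, np.zeros_like(ppm), 400.0)
    with pytest.raises(CalibrationError):
        rq.calibrate_ppm(flat, 5.0, (4.9, 5.1))


def test_noise_estimate_on_known_noise():
    rng = np.random.default_rng(3)
    ppm = np.linspace(11, 0, 4001)
    spec = Spectrum(ppm, rng.normal(0, 2.0, ppm.size), 400.0)
    assert estimate_noise(spec, (9.5, 10.0)) == pytest.approx(2.0, rel=0.2)


# -- file formats ------------------------------------------------------------

def _example_spectrum():
    fid = single_line_fid()
    return rq.process_fid(fid, 0.3, 0)


def test_xy_text_round_trip(tmp_path):
    spec = _example_spectrum()
    p = tmp_path / "spec.xy"
    rq.write_spectrum(spec, p, fmt="xy_text")
    back = rq.read_spectrum(p, fmt="xy_text")
    assert back.sf_mhz == pytest.approx(spec.sf_mhz)
    assert np.allclose(back.ppm, spec.ppm, atol=1e-7)
    assert np.allclose(back.intensity, spec.intensity, rtol=1e-6, atol=1e-8)


def test_xy_text_ascending_axis_normalized(tmp_path):
    p = tmp_path / "asc.xy"
    with open(p, "w") as fh:
        fh.write("# sf_mhz 400\n")
        for x, y in zip(np.linspace(0, 10, 11), range(11)):
            fh.write(f"{x} {y}\n")
    spec = rq.read_spectrum(p, fmt="xy_text")
    assert spec.ppm[0] > spec.ppm[-1]
    assert spec.intensity[0] == 10 and spec.intensity[-1] == 0


def test_jcamp_round_trip(tmp_path):
    spec = _example_spectrum()
    p = tmp_path / "spec.jdx"
    rq.write_spectrum(spec, p, fmt="jcamp")
    back = rq.read_spectrum(p, fmt="jcamp")
    assert back.sf_mhz == pytest.approx(spec.sf_mhz)
    assert np.allclose(back.ppm, spec.ppm, atol=1e-6)
    scale = np.max(np.abs(spec.intensity))
    assert np.allclose(back.intensity, spec.intensity, atol=1e-8 * scale)


def test_malformed_files_report_line_numbers(tmp_path):
    p = tmp_path / "bad.xy"
    p.write_text("1.0 2.0\nthree columns not ok here\n")
    with pytest.raises(FormatError, match="line 2"):
        rq.read_spectrum(p, fmt="xy_text")
    j = tmp_path / "bad.jdx"
    j.write_text("##TITLE=x\n##XYDATA=(X++(Y..Y))\n1.0\n")
    with pytest.raises(FormatError):
        rq.read_spectrum(j, fmt="jcamp")


def test_missing_frequency_metadata_warns(tmp_path):
    p = tmp_path / "nosf.xy"
    p.write_text("1.0 2.0\n0.5 3.0\n")
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        spec = rq.read_spectrum(p, fmt="xy_text")
    assert spec.sf_mhz is None
    assert any("frequency" in str(x.message) for x in w)
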
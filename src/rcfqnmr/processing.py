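"""FID processing, spectrum containers, calibration and region integration.

The processing chain mirrors routine 1D proton work: exponential apodization
(line broadening), zero-filling, Fourier transform, zero-order phasing and
internal-standard referencing.  Spectra are stored with a strictly
descending ppm axis, the field's plotting convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Fid",
    "Spectrum",
    "process_fid",
    "calibrate_ppm",
    "integrate_region",
    "read_spectrum",
    "write_spectrum",
    "estimate_noise",
    "InputError",
    "FormatError",
    "CalibrationError",
    "RangeError",
]

DEFAULT_SF_MHZ = 400.0  # assumed 1H frequency when metadata is absent


class InputError(ValueError):
    pass


class FormatError(ValueError):
    pass


class CalibrationError(ValueError):
    pass


class RangeError(ValueError):
    pass


@dataclass
class Fid:
    """Complex free induction decay plus acquisition metadata."""

    points: np.ndarray
    dwell_s: float
    sf_mhz: float
    carrier_ppm: float
    n_scans: int = 1

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=complex)
        if self.points.size == 0:
            raise InputError("FID has no points")
        if self.dwell_s <= 0:
            raise InputError("dwell time must be positive")
        if self.sf_mhz <= 0:
            raise InputError("spectrometer frequency must be positive")

    @property
    def sweep_width_hz(self) -> float:
        return 1.0 / self.dwell_s

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.points.size) * self.dwell_s


@dataclass
class Spectrum:
    """Frequency-domain trace: descending ppm axis + real intensity."""

    ppm: np.ndarray
    intensity: np.ndarray
    sf_mhz: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape:
            raise InputError("ppm and intensity must have the same length")
        d = np.diff(self.ppm)
        if d.size and not (np.all(d < 0) or np.all(d > 0)):
            raise InputError("ppm axis must be strictly monotone")
        if d.size and d[0] > 0:  # normalize to descending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()

    @property
    def dx(self) -> float:
        """Digital resolution in ppm (positive)."""
        return float(abs(self.ppm[0] - self.ppm[-1]) / (self.ppm.size - 1))

    def window_slice(self, window: tuple[float, float], closed_upper: bool = False):
        """Indices of points inside ``window``.

        By default the interval is half-open ``[low, high)`` on the ppm axis
        so that adjacent windows sharing a boundary never double-count: the
        shared point belongs to the lower-ppm window.
        """
        lo, hi = min(window), max(window)
        if closed_upper:
            mask = (self.ppm >= lo) & (self.ppm <= hi)
        else:
            mask = (self.ppm >= lo) & (self.ppm < hi)
        return np.nonzero(mask)[0]

    def scaled(self, a: float) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity * a, self.sf_mhz, dict(self.provenance))


def process_fid(fid: Fid, line_broadening_hz: float = 0.3, zero_fill_levels: int = 1) -> Spectrum:
    """Apodize, zero-fill, Fourier transform and phase an FID.

    Exponential apodization ``exp(-pi * LB * t)`` adds ``LB`` Hz of
    Lorentzian width; each zero-fill level doubles the record length.  The
    first point is halved (standard half-point correction for the one-sided
    transform) and a zero-order phase is applied so that the tallest
    resonance is pure absorption.
    """
    if line_broadening_hz < 0:
        raise InputError("line broadening must be >= 0")
    if zero_fill_levels < 0:
        raise InputError("zero-fill levels must be >= 0")
    data = fid.points.astype(complex)
    t = fid.times
    data = data * np.exp(-np.pi * line_broadening_hz * t)
    data[0] *= 0.5
    n = data.size * (2**zero_fill_levels)
    spec = np.fft.fftshift(np.fft.fft(data, n=n))
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=fid.dwell_s))
    ppm = fid.carrier_ppm + freqs / fid.sf_mhz

    # zero-order phase from the tallest point of the magnitude spectrum
    k = int(np.argmax(np.abs(spec)))
    if np.abs(spec[k]) > 0:
        phase = float(np.angle(spec[k]))
        spec = spec * np.exp(-1j * phase)
    else:
        phase = 0.0

    return Spectrum(
        ppm=ppm,
        intensity=spec.real,
        sf_mhz=fid.sf_mhz,
        provenance={
            "line_broadening_hz": line_broadening_hz,
            "zero_fill_levels": zero_fill_levels,
            "zero_order_phase_rad": phase,
            "n_scans": fid.n_scans,
            "dwell_s": fid.dwell_s,
            "carrier_ppm": fid.carrier_ppm,
        },
    )


def estimate_noise(spec: Spectrum, region: tuple[float, float] = (9.5, 10.0)) -> float:
    """Intensity standard deviation in a signal-free region."""
    idx = spec.window_slice(region, closed_upper=True)
    if idx.size < 4:
        return 0.0
    y = spec.intensity[idx]
    return float(np.std(y - np.mean(y)))


def calibrate_ppm(
    spec: Spectrum,
    reference_ppm: float,
    search_window: tuple[float, float],
    snr_threshold: float = 5.0,
    noise_region: tuple[float, float] = (9.5, 10.0),
) -> Spectrum:
    """Shift the ppm axis so the tallest peak in ``search_window`` sits at
    ``reference_ppm`` (internal-standard referencing)."""
    lo, hi = min(search_window), max(search_window)
    if lo < spec.ppm.min() or hi > spec.ppm.max():
        raise RangeError("search window outside axis range")
    idx = spec.window_slice(search_window, closed_upper=True)
    if idx.size == 0:
        raise CalibrationError("search window contains no points")
    y = spec.intensity[idx]
    k = idx[int(np.argmax(y))]
    peak = spec.intensity[k]
    noise = estimate_noise(spec, noise_region)
    floor = max(snr_threshold * noise, 1e-12 * max(np.max(np.abs(spec.intensity)), 1.0), 1e-300)
    if peak <= floor:
        raise CalibrationError("no peak above the noise threshold in the search window")
    shift = reference_ppm - float(spec.ppm[k])
    out = Spectrum(spec.ppm + shift, spec.intensity.copy(), spec.sf_mhz, dict(spec.provenance))
    out.provenance["calibration_shift_ppm"] = out.provenance.get("calibration_shift_ppm", 0.0) + shift
    return out


def integrate_region(
    spec: Spectrum,
    window: tuple[float, float],
    baseline: str = "none",
    edge_points: int = 1,
    closed_upper: bool = False,
) -> float:
    """Trapezoidal area (intensity x ppm) over ``window``.

    With ``baseline="endpoints_linear"`` a straight line through the window
    endpoints (each optionally averaged over ``edge_points`` grid points
    just inside the window) is subtracted first; a constant offset then
    integrates to zero.  Sign is preserved.
    """
    lo, hi = min(window), max(window)
    if lo < spec.ppm.min() - 1e-9 or hi > spec.ppm.max() + 1e-9:
        raise RangeError(f"window {window} outside axis range "
                         f"[{spec.ppm.min():.3f}, {spec.ppm.max():.3f}]")
    idx = spec.window_slice(window, closed_upper=closed_upper)
    if idx.size < 2:
        raise RangeError(f"window {window} spans fewer than 2 points")
    # axis is descending; integrate in ascending ppm order
    x = spec.ppm[idx][::-1]
    y = spec.intensity[idx][::-1]
    if baseline == "endpoints_linear":
        k = max(1, min(edge_points, y.size // 2))
        y_lo = float(np.mean(y[:k]))
        y_hi = float(np.mean(y[-k:]))
        base = y_lo + (y_hi - y_lo) * (x - x[0]) / (x[-1] - x[0])
        y = y - base
    elif baseline != "none":
        raise InputError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(y, x))


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

def write_spectrum(spec: Spectrum, path, fmt: str = "xy_text") -> None:
    """Write a spectrum as two-column ppm/intensity text or JCAMP-DX."""
    if fmt == "jcamp":
        from .jcampdx import write_jcamp

        write_jcamp(spec, path)
        return
    if fmt != "xy_text":
        raise FormatError(f"unknown format {fmt!r}")
    with open(path, "w") as fh:
        if spec.sf_mhz is not None:
            fh.write(f"# sf_mhz {spec.sf_mhz:.6f}\n")
        fh.write("# ppm intensity\n")
        for x, y in zip(spec.ppm, spec.intensity):
            fh.write(f"{x:.8g} {y:.10g}\n")


def read_spectrum(path, fmt: str = "xy_text") -> Spectrum:
    """Read a processed spectrum from JCAMP-DX or ppm/intensity text.

    The ppm axis is normalized to descending order.  A missing spectrometer
    frequency raises a warning and leaves ``sf_mhz`` unset.
    """
    if fmt == "jcamp":
        from .jcampdx import read_jcamp

        return read_jcamp(path)
    if fmt != "xy_text":
        raise FormatError(f"unknown format {fmt!r}")
    xs, ys = [], []
    sf = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#"):
                parts = s[1:].split()
                if len(parts) == 2 and parts[0] == "sf_mhz":
                    sf = float(parts[1])
                continue
            parts = s.replace(",", " ").split()
            if len(parts) != 2:
                raise FormatError(f"{path}: line {lineno}: expected two columns, got {s!r}")
            try:
                xs.append(float(parts[0]))
                ys.append(float(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if len(xs) < 2:
        raise FormatError(f"{path}: fewer than 2 data points")
    if sf is None:
        warnings.warn(f"{path}: no spectrometer frequency metadata; sf_mhz unset")
    return Spectrum(np.array(xs), np.array(ys), sf_mhz=sf, provenance={"source": str(path)})
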
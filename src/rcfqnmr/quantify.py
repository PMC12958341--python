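"""Internal-standard qNMR quantification of RCF-oil monomers.

The central relation is the standard internal-standard equation

    m_a = (I_a / I_IS) * (N_IS / N_a) * (MW_a / MW_IS) * m_IS

applied to region integrals of assigned resonances relative to the TTB
aromatic singlet, followed by the overlap-correction and interference rules
specific to RCF oils:

* 50 % of the PEG G2 integral is subtracted from the PG G2 integral (the
  PEG G5 doublet-of-doublets straddles the PG window);
* EG is never integrated directly (its G2 falls inside the PGOH window);
  it is estimated from the ES yield and the PS/PG ratio;
* phenol signal in 7.14-7.22 ppm marks every G2 quantification unreliable,
  and the side-chain (aliphatic) region is integrated instead to recover
  the G-type amounts by difference against the S-type quantifications.

Raw region integrals are additionally corrected for finite-window
truncation using the closed-form coverage of each assigned line shape
(linewidth measured from the TTB peak), and the three closely spaced S-band
singlets (PS/PSOH/ES) are resolved jointly through the same closed-form
window responses.  Every correction is logged per compound.

The module exposes a statsmodels-style pair: :class:`MonomerQuantifier`
(the model, built from a spectrum, prep and panel) and
:class:`QuantificationResults` (estimates, uncertainties, diagnostics,
``summary()``).  The flat functions below are thin wrappers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .lineshape import resonance_lines, window_response_grid
from .panel import Panel, S_BAND_GROUP, default_panel
from .processing import (
    CalibrationError,
    InputError,
    Spectrum,
    calibrate_ppm,
    estimate_noise,
)

__all__ = [
    "SamplePrep",
    "IntegrationResult",
    "QuantResult",
    "QuantifyOptions",
    "SideChainProfile",
    "MonomerQuantifier",
    "QuantificationResults",
    "quantify",
    "mass_from_integral",
    "correct_pg_integral",
    "estimate_eg_yield",
    "detect_phenol_interference",
    "aliphatic_crosscheck",
    "quantify_g_from_aliphatic",
    "InternalStandardError",
    "EstimationError",
]


class InternalStandardError(ValueError):
    """The internal standard is absent or unusable: quantification impossible."""


class EstimationError(ValueError):
    """A derived estimate (e.g. EG from ES) is undefined for these inputs."""


@dataclass(frozen=True)
class SamplePrep:
    """Sample-preparation bookkeeping for mass and yield scaling.

    ``basis_mass_mg`` is the explicit wt %% denominator (documented as the
    lignin mass in the charged biomass); it is never guessed.
    """

    aliquot_ml: float
    total_liquor_ml: float
    is_mass_mg: float
    basis_mass_mg: float

    def __post_init__(self):
        for name in ("aliquot_ml", "total_liquor_ml", "is_mass_mg", "basis_mass_mg"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.aliquot_ml > self.total_liquor_ml:
            raise InputError("aliquot cannot exceed total liquor volume")

    def yield_wt_pct(self, mass_in_sample_mg: float) -> float:
        return 100.0 * mass_in_sample_mg * (self.total_liquor_ml / self.aliquot_ml) / self.basis_mass_mg


DEFAULT_PREP = SamplePrep(aliquot_ml=0.5, total_liquor_ml=50.0, is_mass_mg=1.0, basis_mass_mg=500.0)


@dataclass
class IntegrationResult:
    abbrev: str
    window: tuple[float, float]
    raw_integral: float
    corrected_integral: float
    corrections: list[tuple[str, float]] = field(default_factory=list)
    reliable: bool = True
    reason: str = ""


@dataclass
class QuantResult:
    abbrev: str
    mass_in_sample_mg: float
    conc_mg_per_ml: float  # concentration in the original liquor
    yield_wt_pct: float
    flags: list[str] = field(default_factory=list)
    reliable: bool = True
    se_mass_mg: float = float("nan")
    se_yield_wt_pct: float = float("nan")


@dataclass
class QuantifyOptions:
    baseline: str = "endpoints_linear"
    edge_points: int = 3
    coverage_correction: bool = True
    sband_unmixing: bool = True
    calibrate: bool = True
    reference_ppm: float | None = None  # default: TTB primary center
    phenol_snr_threshold: float = 5.0
    aliphatic_presence_threshold: float = 0.05
    noise_region: tuple[float, float] = (9.5, 10.0)
    min_window_points: int = 8
    es_peak_tol_ppm: float = 0.005
    fallback: str = "auto"  # auto | never | force
    negative_tolerance: float = 0.05  # fraction of S amount, for fallback G


@dataclass
class SideChainProfile:
    """Per-proton aliphatic/alkene diagnostics, normalized to TTB."""

    per_proton: dict[str, float]        # window key -> per-proton integral
    relative: dict[str, float]          # window key -> ratio vs TTB per-proton
    flags: dict[str, bool]
    chain_mmol: dict[str, float]        # side chain -> total mmol in tube
    ttb_per_proton: float


# Diagnostic windows: key -> (window, protons, side_chain or None, panel ref)
# The panel reference names a compound/label whose line shape is used for the
# coverage correction of that window.
_DIAG_WINDOWS = {
    "propyl_gamma": ((0.86, 0.93), 3, "propyl", ("PS", "propyl-gamma")),
    "propyl_beta": ((1.53, 1.64), 2, None, ("PS", "propyl-beta")),
    "ethyl_beta": ((1.13, 1.20), 3, "ethyl", ("ES", "ethyl-beta")),
    "hydroxypropyl_gamma": ((3.45, 3.58), 2, "hydroxypropyl", ("PSOH", "hydroxypropyl-gamma")),
    "alkene_alpha": ((6.28, 6.35), 1, "propenyl", ("PES", "alkene-alpha")),
    "alkene_beta": ((6.06, 6.15), 1, None, ("PES", "alkene-beta")),
}


def _trapezoid_idx(spec: Spectrum, idx: np.ndarray, baseline: str, edge_points: int) -> float:
    """Trapezoidal area over the selected grid points (ascending ppm),
    with the optional endpoint-averaged linear baseline."""
    x = spec.ppm[idx][::-1]
    y = spec.intensity[idx][::-1].astype(float)
    if baseline == "endpoints_linear":
        k = max(1, min(edge_points, y.size // 2))
        y_lo = float(np.mean(y[:k]))
        y_hi = float(np.mean(y[-k:]))
        y = y - (y_lo + (y_hi - y_lo) * (x - x[0]) / (x[-1] - x[0]))
    elif baseline != "none":
        raise InputError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(y, x))


# ---------------------------------------------------------------------------
# Flat qNMR arithmetic
# ---------------------------------------------------------------------------

def mass_from_integral(i_a: float, i_is: float, n_a: int, n_is: int,
                       mw_a: float, mw_is: float, m_is: float) -> float:
    """Analyte mass (mg) from integrals relative to the internal standard."""
    if i_is <= 0:
        raise InternalStandardError("internal-standard integral must be positive")
    if min(n_a, n_is) <= 0 or min(mw_a, mw_is) <= 0 or m_is <= 0:
        raise InputError("proton counts, molar masses and IS mass must be positive")
    return (i_a / i_is) * (n_is / n_a) * (mw_a / mw_is) * m_is


def correct_pg_integral(i_pg_g2: float, i_peg_g2: float) -> float:
    """PG G2 integral after subtracting 50 % of the PEG G2 integral.

    Floored at zero; callers flag the flooring event.
    """
    if i_pg_g2 < 0 or i_peg_g2 < 0:
        raise InputError("integrals must be non-negative")
    return max(i_pg_g2 - 0.5 * i_peg_g2, 0.0)


def estimate_eg_yield(es_yield: float, ps_yield: float, pg_yield: float) -> float:
    """EG yield estimated as ES yield scaled by the NMR PG/PS ratio."""
    if ps_yield <= 0:
        raise EstimationError("EG estimate undefined: PS yield must be positive")
    return es_yield * (pg_yield / ps_yield)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MonomerQuantifier:
    """qNMR quantification model for one calibrated RCF-oil spectrum.

    Parameters
    ----------
    spectrum : Spectrum
        Frequency-domain trace (descending ppm axis).
    prep : SamplePrep, optional
        Aliquot/IS/basis bookkeeping; defaults to the standard prep
        (0.5 mL of 50 mL liquor, 1 mg TTB, 500 mg lignin basis).
    panel : Panel, optional
        Compound panel; defaults to the poplar panel.
    options : QuantifyOptions or keyword overrides.
    """

    def __init__(self, spectrum: Spectrum, prep: SamplePrep | None = None,
                 panel: Panel | None = None, options: QuantifyOptions | None = None,
                 **option_overrides):
        self.spectrum = spectrum
        self.prep = prep or DEFAULT_PREP
        self.panel = panel or default_panel()
        opts = options or QuantifyOptions()
        if option_overrides:
            opts = replace(opts, **option_overrides)
        self.options = opts

    @classmethod
    def from_file(cls, path, fmt: str = "jcamp", **kwargs) -> "MonomerQuantifier":
        from .processing import read_spectrum

        return cls(read_spectrum(path, fmt=fmt), **kwargs)

    # -- helpers -----------------------------------------------------------

    def _grid_window(self, spec: Spectrum, window: tuple[float, float]):
        idx = spec.window_slice(window)
        if idx.size < self.options.min_window_points:
            raise InputError(
                f"window {window} spans {idx.size} points "
                f"(< {self.options.min_window_points}); digital resolution too low"
            )
        lo = float(spec.ppm[idx].min())
        hi = float(spec.ppm[idx].max())
        return idx, (lo, hi)

    def _measure_linewidth(self, spec: Spectrum, ttb_res) -> float:
        """FWHM (Hz) of the TTB aromatic peak, by linear interpolation."""
        sf = spec.sf_mhz or 400.0
        idx = spec.window_slice(ttb_res.window, closed_upper=True)
        y = spec.intensity[idx]
        x = spec.ppm[idx]
        k = int(np.argmax(y))
        half = y[k] / 2.0
        # walk outward to the half-height crossings
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
        if left is None or right is None:
            return 1.3  # fall back to the nominal simulated width
        lw = abs(left - right) * sf
        return float(min(max(lw, 0.2), 10.0))

    def _response(self, spec: Spectrum, res, idx, lw_hz: float) -> float:
        sf = spec.sf_mhz or 400.0
        lines = resonance_lines(res, lw_hz, sf)
        x = spec.ppm[idx][::-1]  # ascending, same grid the data are integrated on
        return window_response_grid(lines, x, baseline=self.options.baseline,
                                    edge_points=self.options.edge_points)

    def _integrate(self, spec: Spectrum, idx: np.ndarray) -> float:
        """Trapezoid over exactly the grid points the response model uses."""
        return _trapezoid_idx(spec, idx, self.options.baseline, self.options.edge_points)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "QuantificationResults":
        opts = self.options
        panel = self.panel
        prep = self.prep
        spec = self.spectrum
        ttb = panel.internal_standard
        ttb_res = ttb.primary_resonance

        if opts.calibrate:
            ref = opts.reference_ppm if opts.reference_ppm is not None else ttb_res.center_ppm
            try:
                spec = calibrate_ppm(spec, ref, (ref - 0.05, ref + 0.05),
                                     noise_region=opts.noise_region)
            except CalibrationError as exc:
                raise InternalStandardError(f"TTB not detected: {exc}") from exc

        noise = estimate_noise(spec, opts.noise_region)
        global_max = float(np.max(np.abs(spec.intensity))) if spec.intensity.size else 0.0
        detect_floor = max(10.0 * noise, 1e-3 * global_max, 1e-300)

        # internal standard
        idx_is, win_is = self._grid_window(spec, ttb_res.window)
        if float(np.max(spec.intensity[idx_is])) <= detect_floor:
            raise InternalStandardError("TTB aromatic peak not detected above noise")
        lw_hz = self._measure_linewidth(spec, ttb_res)
        raw_is = self._integrate(spec, idx_is)
        r_is = self._response(spec, ttb_res, idx_is, lw_hz) if opts.coverage_correction else 1.0
        if raw_is <= 0 or r_is <= 0:
            raise InternalStandardError("TTB integral non-positive")
        area_is = raw_is / r_is
        integrations: list[IntegrationResult] = [
            IntegrationResult("TTB", win_is, raw_is, area_is,
                              corrections=[("lorentzian_coverage", area_is - raw_is)]
                              if opts.coverage_correction else [])
        ]

        def sigma_integral_for(n_pts: int, width_ppm: float) -> float:
            """Integral noise: trapezoid term plus (for the endpoint baseline)
            the subtracted-chord term; sqrt(2) covers zero-fill correlation."""
            var = spec.dx**2 * max(n_pts, 2)
            if opts.baseline == "endpoints_linear":
                var += width_ppm**2 / (2.0 * max(opts.edge_points, 1))
            return noise * math.sqrt(2.0 * var)

        sigma_is = sigma_integral_for(idx_is.size, win_is[1] - win_is[0])

        # ----- diagnostics -------------------------------------------------
        phenol_detected, phenol_evidence = detect_phenol_interference(
            spec, panel, snr_threshold=opts.phenol_snr_threshold,
            noise_region=opts.noise_region)
        profile = aliphatic_crosscheck(
            spec, panel, prep=prep, options=opts, _ttb_area=area_is, _lw_hz=lw_hz)
        ethyl_present = profile.flags.get("ethyl_beta", False)

        # ----- raw windows -------------------------------------------------
        # Direct integration set: every compound with a usable primary window.
        # EG and MP share windows with PGOH and PHBA and are never integrated
        # directly.
        direct = [c for c in panel.compounds
                  if c.abbrev not in ("TTB", "EG", "MP")]
        raw: dict[str, float] = {}
        grid: dict[str, tuple[float, float]] = {}
        gidx: dict[str, np.ndarray] = {}
        resp: dict[str, float] = {}
        npts: dict[str, int] = {}
        errors: dict[str, str] = {}
        for c in direct:
            res = c.primary_resonance
            try:
                idx, win = self._grid_window(spec, res.window)
            except InputError as exc:
                errors[c.abbrev] = str(exc)
                continue
            raw[c.abbrev] = self._integrate(spec, idx)
            grid[c.abbrev] = win
            gidx[c.abbrev] = idx
            npts[c.abbrev] = idx.size
            resp[c.abbrev] = (self._response(spec, res, idx, lw_hz)
                              if opts.coverage_correction else 1.0)

        areas: dict[str, float] = {}
        corrections: dict[str, list[tuple[str, float]]] = {a: [] for a in raw}

        # ----- S band: joint solve over PS / PSOH / ES ---------------------
        sband = [a for a in S_BAND_GROUP if a in raw]
        if opts.sband_unmixing and opts.coverage_correction and len(sband) > 1:
            sf = spec.sf_mhz or 400.0
            m = np.zeros((len(sband), len(sband)))
            for i, tgt in enumerate(sband):
                x_tgt = spec.ppm[gidx[tgt]][::-1]
                for j, src in enumerate(sband):
                    lines = resonance_lines(panel.get(src).primary_resonance, lw_hz, sf)
                    m[i, j] = window_response_grid(lines, x_tgt, baseline=opts.baseline,
                                                   edge_points=opts.edge_points)
            b = np.array([raw[a] for a in sband])
            sol = np.linalg.solve(m, b)
            for a, v in zip(sband, sol):
                areas[a] = max(float(v), 0.0)
                corrections[a].append(("sband_unmixing", areas[a] - raw[a]))
                if v < 0:
                    corrections[a].append(("floored_at_zero", -float(v)))
        else:
            for a in sband:
                areas[a] = raw[a] / resp[a]
                if opts.coverage_correction:
                    corrections[a].append(("lorentzian_coverage", areas[a] - raw[a]))

        # ----- PEG before PG (the 50 % rule uses the same spectrum) --------
        if "PEG" in raw:
            areas["PEG"] = max(raw["PEG"], 0.0) / resp["PEG"]
            if opts.coverage_correction:
                corrections["PEG"].append(("lorentzian_coverage", areas["PEG"] - raw["PEG"]))
        peg_dominant = False
        if "PG" in raw:
            i_peg = max(raw.get("PEG", 0.0), 0.0)
            i_pg = max(raw["PG"], 0.0)
            corrected_pg = correct_pg_integral(i_pg, i_peg)
            corrections["PG"].append(("peg_g2_50pct_subtraction", corrected_pg - i_pg))
            if corrected_pg == 0.0 and i_pg - 0.5 * i_peg < 0:
                corrections["PG"].append(("floored_at_zero", 0.5 * i_peg - i_pg))
            peg_dominant = i_pg > 0 and (0.5 * i_peg) / i_pg > 0.5
            g2 = [a for a in ("PG", "PGOH") if a in raw]
            if opts.sband_unmixing and opts.coverage_correction and len(g2) == 2:
                # adjacent G2 singlets: joint solve, tails handled mutually
                sf = spec.sf_mhz or 400.0
                corr_raw = {"PG": corrected_pg, "PGOH": raw["PGOH"]}
                m = np.zeros((2, 2))
                for i, tgt in enumerate(g2):
                    x_tgt = spec.ppm[gidx[tgt]][::-1]
                    for j, src in enumerate(g2):
                        lines = resonance_lines(panel.get(src).primary_resonance, lw_hz, sf)
                        m[i, j] = window_response_grid(lines, x_tgt, baseline=opts.baseline,
                                                       edge_points=opts.edge_points)
                sol = np.linalg.solve(m, np.array([corr_raw[a] for a in g2]))
                for a, v in zip(g2, sol):
                    areas[a] = max(float(v), 0.0)
                    corrections[a].append(("g2_unmixing", areas[a] - raw[a]))
                    if v < 0:
                        corrections[a].append(("floored_at_zero", -float(v)))
            else:
                areas["PG"] = corrected_pg / resp["PG"]
                if opts.coverage_correction:
                    corrections["PG"].append(("lorentzian_coverage", areas["PG"] - corrected_pg))

        # ----- remaining direct compounds ----------------------------------
        for a in raw:
            if a in areas:
                continue
            areas[a] = max(raw[a], 0.0) / resp[a]
            if opts.coverage_correction:
                corrections[a].append(("lorentzian_coverage", areas[a] - max(raw[a], 0.0)))

        # ----- ES distinguishability ---------------------------------------
        es_ok = False
        if "ES" in areas:
            es_ok = self._es_distinguishable(spec, panel, noise)

        # ----- gating -------------------------------------------------------
        g2_unreliable = phenol_detected
        pgoh_unreliable = phenol_detected or ethyl_present

        # ----- assemble results --------------------------------------------
        results: dict[str, QuantResult] = {}
        rel_is = (sigma_is / raw_is) if raw_is else 0.0

        def build(abbrev: str, area: float, flags: list[str], reliable: bool,
                  n_override: int | None = None) -> QuantResult:
            comp = panel.get(abbrev)
            res = comp.primary_resonance
            n_a = n_override if n_override is not None else res.n_protons
            mass = mass_from_integral(area, area_is, n_a, ttb_res.n_protons,
                                      comp.molar_mass, ttb.molar_mass, prep.is_mass_mg)
            if abbrev in grid:
                lo, hi = grid[abbrev]
                sig_a = sigma_integral_for(npts[abbrev], hi - lo)
            else:
                sig_a = sigma_is
            rel_a = (sig_a / area) if area > 0 else 0.0
            se_rel = math.sqrt(rel_a**2 + rel_is**2)
            y = prep.yield_wt_pct(mass)
            return QuantResult(abbrev, mass, mass / prep.aliquot_ml, y,
                               flags=flags, reliable=reliable,
                               se_mass_mg=mass * se_rel, se_yield_wt_pct=y * se_rel)

        for c in direct:
            a = c.abbrev
            if a in errors:
                results[a] = QuantResult(a, 0.0, 0.0, 0.0,
                                         flags=[f"window_error: {errors[a]}"], reliable=False)
                continue
            flags = [name for name, _ in corrections[a]]
            reliable = True
            if a == "ES":
                if not es_ok:
                    flags.append("not_distinguishable")
                    reliable = False
            if a in ("PG", "PGOH") and g2_unreliable:
                flags.append("phenol_interference_g2")
                reliable = False
            if a == "PGOH" and ethyl_present:
                flags.append("eg_overlap_suspected")
                reliable = False
            if a == "PG" and peg_dominant:
                flags.append("dominant_peg_correction")
                reliable = False
            if a == "PHBA":
                flags.append("sum_of_phba_and_mp_shared_window")
            results[a] = build(a, areas[a], flags, reliable)

        # internal standard self-check entry (not a monomer yield)
        # -- not added to results; TTB is bookkeeping only.

        # ----- MP ------------------------------------------------------------
        results["MP"] = QuantResult("MP", 0.0, 0.0, 0.0,
                                    flags=["not_independently_quantified_shared_window_with_PHBA"],
                                    reliable=False)

        # ----- EG estimate ---------------------------------------------------
        eg_flags = ["estimated_from_es_and_ps_pg_ratio"]
        eg_reliable = False
        eg_yield = 0.0
        if "ES" in results and "PS" in results and "PG" in results:
            ps_y, pg_y = results["PS"].yield_wt_pct, results["PG"].yield_wt_pct
            es_y = results["ES"].yield_wt_pct
            if ps_y > 0:
                eg_yield = estimate_eg_yield(es_y, ps_y, pg_y)
                eg_reliable = es_ok and results["PS"].reliable and results["PG"].reliable
                if not es_ok:
                    eg_flags.append("es_not_distinguishable")
            else:
                eg_flags.append("estimation_undefined_ps_zero")
        eg_mass = eg_yield / 100.0 * prep.basis_mass_mg * prep.aliquot_ml / prep.total_liquor_ml
        results["EG"] = QuantResult("EG", eg_mass, eg_mass / prep.aliquot_ml, eg_yield,
                                    flags=eg_flags, reliable=eg_reliable)

        # ----- aliphatic fallback for G types --------------------------------
        fallback_used = False
        if opts.fallback != "never" and (opts.fallback == "force" or g2_unreliable or pgoh_unreliable):
            s_results = [results[a] for a in ("PS", "PSOH", "ES") if a in results]
            fb = quantify_g_from_aliphatic(
                spec, s_results, prep, panel, options=opts,
                _profile=profile, _es_ok=es_ok)
            replace_set = {"PGOH", "EG"} if not g2_unreliable else {"PG", "PGOH", "EG"}
            for r in fb:
                if r.abbrev in replace_set:
                    direct_flags = results[r.abbrev].flags if r.abbrev in results else []
                    r.flags = r.flags + [f for f in direct_flags
                                         if f in ("phenol_interference_g2", "eg_overlap_suspected")]
                    results[r.abbrev] = r
            fallback_used = True

        # record per-window integration log (reliability per gating)
        for a in raw:
            rel = True
            reason = ""
            if a in ("PG", "PGOH") and g2_unreliable:
                rel, reason = False, "phenol interference in the G2 region"
            if a == "PGOH" and ethyl_present:
                rel, reason = False, "EG overlap suspected (ethyl side chains present)"
            if a == "ES" and not es_ok:
                rel, reason = False, "no distinct maximum in the ES window"
            integrations.append(IntegrationResult(
                a, grid[a], raw[a], areas[a], corrections[a], rel, reason))

        order = [c.abbrev for c in panel.compounds if c.abbrev != "TTB"]
        result_list = [results[a] for a in order if a in results]

        return QuantificationResults(
            model=self,
            spectrum=spec,
            results=result_list,
            integrations=integrations,
            sidechain=profile,
            phenol_detected=phenol_detected,
            phenol_evidence=phenol_evidence,
            params={
                "linewidth_hz": lw_hz,
                "noise_sigma": noise,
                "ttb_area": area_is,
                "sigma_integral_is": sigma_is,
                "fallback_used": fallback_used,
                "g2_gated": bool(g2_unreliable),
                "pgoh_gated": bool(pgoh_unreliable),
                "calibration_shift_ppm": spec.provenance.get("calibration_shift_ppm", 0.0),
                "options": self.options,
            },
        )

    def _es_distinguishable(self, spec: Spectrum, panel: Panel, noise: float) -> bool:
        """True iff the ES window shows a local maximum at the expected shift."""
        es = panel.get("ES").primary_resonance
        idx = spec.window_slice(es.window, closed_upper=True)
        if idx.size < 3:
            return False
        y = spec.intensity[idx][::-1]  # ascending ppm
        x = spec.ppm[idx][::-1]
        floor = max(3.0 * noise, 1e-3 * float(np.max(np.abs(spec.intensity))))
        peaks, props = find_peaks(y, prominence=floor)
        tol = self.options.es_peak_tol_ppm
        return any(abs(x[p] - es.center_ppm) <= tol for p in peaks)


@dataclass
class QuantificationResults:
    """Estimates, uncertainties and diagnostics from a fitted quantifier."""

    model: MonomerQuantifier
    spectrum: Spectrum
    results: list[QuantResult]
    integrations: list[IntegrationResult]
    sidechain: SideChainProfile
    phenol_detected: bool
    phenol_evidence: dict
    params: dict

    def get(self, abbrev: str) -> QuantResult:
        for r in self.results:
            if r.abbrev == abbrev:
                return r
        raise KeyError(abbrev)

    @property
    def yields(self) -> dict[str, float]:
        return {r.abbrev: r.yield_wt_pct for r in self.results}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "abbrev": [r.abbrev for r in self.results],
                "mass_mg": [r.mass_in_sample_mg for r in self.results],
                "conc_mg_per_ml": [r.conc_mg_per_ml for r in self.results],
                "yield_wt_pct": [r.yield_wt_pct for r in self.results],
                "se_yield_wt_pct": [r.se_yield_wt_pct for r in self.results],
                "reliable": [r.reliable for r in self.results],
                "flags": [";".join(r.flags) for r in self.results],
            }
        ).set_index("abbrev")

    def summary(self) -> str:
        p = self.params
        lines = [
            "qNMR monomer quantification",
            "=" * 64,
            f"linewidth (TTB)     : {p['linewidth_hz']:.2f} Hz",
            f"noise sigma         : {p['noise_sigma']:.4g}",
            f"calibration shift   : {p['calibration_shift_ppm']:+.4f} ppm",
            f"phenol interference : {self.phenol_detected}",
            f"G2 region gated     : {p['g2_gated']} (PGOH gated: {p['pgoh_gated']})",
            f"aliphatic fallback  : {p['fallback_used']}",
            "-" * 64,
            f"{'compound':<8}{'mass mg':>10}{'yield wt%':>12}{'+/-':>8}  flags",
        ]
        for r in self.results:
            se = f"{r.se_yield_wt_pct:.2f}" if np.isfinite(r.se_yield_wt_pct) else "--"
            mark = "" if r.reliable else " [unreliable]"
            lines.append(
                f"{r.abbrev:<8}{r.mass_in_sample_mg:>10.4f}{r.yield_wt_pct:>12.2f}{se:>8}"
                f"  {';'.join(r.flags)}{mark}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def detect_phenol_interference(
    spec: Spectrum,
    panel: Panel | None = None,
    snr_threshold: float = 5.0,
    noise_region: tuple[float, float] = (9.5, 10.0),
) -> tuple[bool, dict]:
    """Check for phenol signal in its 7.14-7.22 ppm window.

    Returns (detected, evidence).  When detected, G2-window quantifications
    must be considered unreliable.
    """
    panel = panel or default_panel()
    win = panel.get("PHENOL").primary_resonance.window
    idx = spec.window_slice(win, closed_upper=True)
    if idx.size == 0:
        return False, {"reason": "phenol window outside axis"}
    peak = float(np.max(spec.intensity[idx]))
    noise = estimate_noise(spec, noise_region)
    global_max = float(np.max(np.abs(spec.intensity))) if spec.intensity.size else 0.0
    floor = max(snr_threshold * noise, 1e-3 * global_max)
    detected = bool(global_max > 0 and peak > floor)
    return detected, {
        "window": win,
        "peak_intensity": peak,
        "noise_sigma": noise,
        "threshold": floor,
        "snr": peak / noise if noise > 0 else math.inf,
    }


def aliphatic_crosscheck(
    spec: Spectrum,
    panel: Panel | None = None,
    prep: SamplePrep | None = None,
    options: QuantifyOptions | None = None,
    _ttb_area: float | None = None,
    _lw_hz: float | None = None,
) -> SideChainProfile:
    """Side-chain profile from the diagnostic aliphatic/alkene windows.

    Integrals are normalized per proton and expressed relative to the TTB
    per-proton integral; a side chain is flagged present when its ratio
    exceeds the presence threshold.
    """
    panel = panel or default_panel()
    prep = prep or DEFAULT_PREP
    opts = options or QuantifyOptions()
    ttb = panel.internal_standard
    ttb_res = ttb.primary_resonance

    lw = _lw_hz if _lw_hz is not None else 1.3
    if _ttb_area is None:
        try:
            idx = spec.window_slice(ttb_res.window)
            raw_is = _trapezoid_idx(spec, idx, opts.baseline, opts.edge_points)
            sf = spec.sf_mhz or 400.0
            r = window_response_grid(resonance_lines(ttb_res, lw, sf), spec.ppm[idx][::-1],
                                     baseline=opts.baseline, edge_points=opts.edge_points)
            _ttb_area = raw_is / r if r > 0 else 0.0
        except Exception:
            _ttb_area = 0.0

    u_is = _ttb_area / ttb_res.n_protons if _ttb_area and _ttb_area > 0 else 0.0
    sf = spec.sf_mhz or 400.0

    per_proton: dict[str, float] = {}
    relative: dict[str, float] = {}
    flags: dict[str, bool] = {}
    chain_mmol: dict[str, float] = {}
    for key, (window, n_h, chain, (comp_ab, label)) in _DIAG_WINDOWS.items():
        try:
            idx = spec.window_slice(window)
            if idx.size < 2:
                raise InputError("too few points")
            raw_i = _trapezoid_idx(spec, idx, opts.baseline, opts.edge_points)
        except Exception:
            per_proton[key] = 0.0
            relative[key] = 0.0
            flags[key] = False
            continue
        res = next(r for r in panel.get(comp_ab).resonances if r.label == label)
        r_cov = window_response_grid(resonance_lines(res, lw, sf), spec.ppm[idx][::-1],
                                     baseline=opts.baseline, edge_points=opts.edge_points)
        area = max(raw_i, 0.0) / r_cov if r_cov > 0 else 0.0
        u = area / n_h
        per_proton[key] = u
        relative[key] = (u / u_is) if u_is > 0 else 0.0
        flags[key] = bool(u_is > 0 and relative[key] > opts.aliphatic_presence_threshold)
        if chain is not None and u_is > 0:
            # mmol of side chains in the tube, via the IS molar amount
            chain_mmol[chain] = (u / u_is) * (prep.is_mass_mg / ttb.molar_mass)

    return SideChainProfile(per_proton=per_proton, relative=relative, flags=flags,
                            chain_mmol=chain_mmol, ttb_per_proton=u_is)


def quantify_g_from_aliphatic(
    spec: Spectrum,
    s_results: list[QuantResult],
    prep: SamplePrep | None = None,
    panel: Panel | None = None,
    options: QuantifyOptions | None = None,
    _profile: SideChainProfile | None = None,
    _es_ok: bool | None = None,
) -> list[QuantResult]:
    """G-type masses from the side-chain windows, by difference against S.

    Each clean side-chain window (propyl gamma, ethyl beta, hydroxypropyl
    gamma) gives the total molar amount of that chain; subtracting the
    molar amount of the corresponding S-type compound leaves the G-type
    amount.  Only the hydroxypropyl gamma window (3.45-3.58 ppm) is used
    for PGOH because the alpha/beta windows overlap other chains.
    """
    panel = panel or default_panel()
    prep = prep or DEFAULT_PREP
    opts = options or QuantifyOptions()
    profile = _profile if _profile is not None else aliphatic_crosscheck(
        spec, panel, prep=prep, options=opts)

    s_by_ab = {r.abbrev: r for r in s_results}

    def s_mmol(abbrev: str) -> float:
        r = s_by_ab.get(abbrev)
        if r is None:
            return 0.0
        if abbrev == "ES" and _es_ok is False:
            return 0.0  # ES amount unknown: attribute the ethyl chain to EG
        return r.mass_in_sample_mg / panel.get(abbrev).molar_mass

    pairs = [("PG", "propyl", "PS"), ("PGOH", "hydroxypropyl", "PSOH"), ("EG", "ethyl", "ES")]
    out = []
    for g_ab, chain, s_ab in pairs:
        total = profile.chain_mmol.get(chain, 0.0)
        s_amount = s_mmol(s_ab)
        g_amount = total - s_amount
        flags = ["aliphatic_fallback"]
        reliable = True
        if g_amount < 0:
            if s_amount > 0 and -g_amount > opts.negative_tolerance * s_amount:
                flags.append("negative_g_inferred")
                reliable = False
            g_amount = 0.0
        mass = g_amount * panel.get(g_ab).molar_mass
        y = prep.yield_wt_pct(mass)
        out.append(QuantResult(g_ab, mass, mass / prep.aliquot_ml, y,
                               flags=flags, reliable=reliable))
    return out


# ---------------------------------------------------------------------------
# Pipeline wrapper
# ---------------------------------------------------------------------------

def quantify(
    spec: Spectrum,
    prep: SamplePrep | None = None,
    panel: Panel | None = None,
    options: QuantifyOptions | None = None,
    **option_overrides,
) -> QuantificationResults:
    """Full quantification pipeline on a spectrum; see MonomerQuantifier."""
    model = MonomerQuantifier(spec, prep=prep, panel=panel, options=options,
                              **option_overrides)
    return model.fit()
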
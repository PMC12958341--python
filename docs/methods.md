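# Methods

## The measurement being modelled

Reductive catalytic fractionation (RCF) converts the lignin in biomass into a
small family of 4-substituted phenolic monomers.  Quantifying them usually
requires chromatography with authentic standards that are hard to procure.
This package implements the alternative: a single 1D ¹H NMR experiment on the
crude reaction liquor.  An aliquot of the liquor (default 0.5 mL of a 50 mL
reaction) is dried and redissolved in 1 mL of deuterated solvent containing a
weighed internal standard, 1,3,5-tri-*tert*-butylbenzene (TTB, 1 mg/mL).
Because NMR signal is proportional to the number of nuclei, the mass of an
analyte *a* follows from region integrals alone:

    m_a = (I_a / I_IS) · (N_IS / N_a) · (MW_a / MW_IS) · m_IS

with `I` the integral of an assigned resonance, `N` its proton count and `MW`
the molar mass.  Yields are expressed as wt % of an explicit basis mass
(documented as the lignin content of the charged biomass, default 500 mg);
the package never guesses this denominator.  Whole-reaction masses are
recovered by scaling the in-tube mass by `total_liquor / aliquot`.

## The compound panel

Twelve compounds are encoded: 4-propyl-, 4-(3-hydroxypropyl)-, 4-ethyl- and
4-propenyl- syringol and guaiacol (PS/PSOH/ES/PES, PG/PGOH/EG/PEG),
*p*-hydroxybenzoic acid and methyl paraben (PHBA/MP), phenol, and TTB.
Molar masses are computed from molecular formulas with standard atomic
weights rather than stored as decimals, so they are auditable.

Quantification uses one designated resonance per compound: the S₂/₆ aromatic
singlets for the syringyl compounds (6.46–6.50 ppm band; PES well separated
at 6.66 ppm), the G₂ singlets for the guaiacyl compounds (6.77–6.82 ppm band;
PEG at 6.99 ppm), the H₂/₆ doublet at 7.87–7.93 ppm for the
*p*-hydroxybenzoates, and the 7.14–7.22 ppm multiplet for phenol.  The exact
shifts of PS, PSOH and ES inside their shared band are instrument- and
solvent-dependent; the defaults (6.462, 6.475, 6.490 ppm with windows
[6.450, 6.470], [6.470, 6.480], [6.480, 6.500]) are editable, since panels are
plain YAML files.  The TTB aromatic shift is set at 7.30 ppm by convention.
G-ring couplings are ~8 Hz (G₅/G₆); the ~2 Hz G₂ meta-coupling is unresolved
at the working linewidth, so G₂ resonances are encoded as singlets.

Known overlaps are first-class annotations, not incidental facts:

* the PEG G₅ doublet-of-doublets straddles the PG G₂ window;
* the EG G₂ (6.80 ppm) falls inside the PGOH G₂ window;
* the phenol 6.77–6.85 ppm multiplet covers the whole G₂ band;
* ES sits within a few Hz of the PS/PSOH singlets;
* PHBA and MP share both printed windows.

Aliphatic side-chain windows (propyl γ 0.86–0.93, propyl β 1.53–1.64, ethyl β
1.13–1.20, hydroxypropyl γ 3.45–3.58, alkene α 6.28–6.35 and β 6.06–6.15 ppm)
depend on the chain rather than the ring and serve as diagnostics and as the
fallback quantification route (below).  Of the hydroxypropyl windows only the
γ window is clean; α overlaps the ethyl α and β the propenyl γ resonances.

## Spectral processing

Raw FIDs are exponentially apodized (`exp(-π·LB·t)`, default LB = 0.3 Hz),
zero-filled (default one level), Fourier transformed with half-point
correction, and phased zero-order so the tallest resonance is pure
absorption.  First-order phase is out of scope: the synthetic data need none,
and real spectra are expected to arrive processed (JCAMP-DX or two-column
ppm/intensity text).  Axes are normalized to descending ppm.  Spectra are
re-referenced by shifting the axis so the tallest peak near the TTB position
lands exactly on it; the shift is recorded in the provenance log, as are all
processing parameters.  When frequency metadata are absent, 400 MHz is
assumed and flagged.

Integration is trapezoidal over the grid points inside a window.  Windows are
half-open (`[low, high)` in ppm) so adjacent windows never double-count a
point; a shared boundary belongs to the lower-ppm window.  The default
baseline subtracts a straight line through the window endpoints (each
averaged over 3 grid points), the minimal defensible correction for crude
oils whose oligomer background varies slowly; `none` is available for clean
synthetic spectra.  Quantification refuses windows spanning fewer than
8 points rather than returning silently under-sampled integrals.

## Line-shape-aware corrections

Finite integration windows clip Lorentzian tails, and the S-band singlets sit
close enough (5–10 Hz at 400 MHz) that each loses a few percent of its area
into its neighbours' windows.  Rather than widen windows or fit peaks, the
quantifier models each assigned resonance as its first-order line pattern
(Lorentzians of the linewidth measured from the TTB peak; Gaussian envelopes
for unresolved multiplets) and evaluates, in closed form on the same digital
grid the data are integrated on, the response of each window to each
resonance — including the effect of the endpoint baseline.  Three uses:

1. **Coverage correction** — every raw window integral is divided by the
   window's response to its own resonance, converting it to a full-area
   estimate.  Logged as `lorentzian_coverage`.
2. **S-band resolution** — the PS/PSOH/ES windows are solved jointly as a
   3×3 linear system (`sband_unmixing`), and PG/PGOH as a 2×2 system
   (`g2_unmixing`), so mutual tail contamination cancels.  This is a
   deterministic linear solve with centers and widths fixed by the panel,
   not a line-shape fit.
3. **Simulator ground truth** — the same closed forms give exact per-window
   integrals for synthetic mixtures.

Evaluating model responses on the actual grid (instead of the continuum
closed form) matters: at the default 0.25 Hz/point, trapezoidal quadrature of
a 1.3 Hz-wide peak differs from the continuous integral by ~2 %, and the
correction must be biased the same way the measurement is.

The overlaps the source method handles by rule are kept as rules:

* **PG − 0.5·PEG**: 50 % of the PEG G₂ integral is subtracted from the raw
  PG G₂ integral before coverage correction (the symmetric G₅ pattern
  centered on the PG window edge puts half its area inside).  If the
  subtraction exceeds half the PG integral, PG is flagged
  `dominant_peg_correction` and marked unreliable; flooring at zero is
  flagged.
* **EG is never integrated directly**: it is estimated as
  `EG = ES · (PG/PS)` from the same spectrum's NMR yields, flagged as an
  estimate, and undefined when PS is absent.
* **ES** is reported only when its narrow window contains a genuine local
  maximum within 0.005 ppm of the expected shift and above 3× noise;
  otherwise it is flagged `not_distinguishable` — at trace levels the
  PS/PSOH tails swamp it, and the joint solve returns a noisy number that
  should not be trusted.
* **PHBA + MP** share both windows; the H₂/₆ window is reported once, under
  PHBA with a `sum` flag (mass computed with the PHBA molar mass), and MP is
  reported as not independently quantifiable.  The phenol/G₂ overlap is
  deliberately *not* unmixed: a noisy three-proton multiplet envelope is not
  a reliable subtraction model, and the source method's prescription is to
  abandon the G₂ region instead (next section).

## Interference gating and the aliphatic fallback

Phenol is detected from its 7.14–7.22 ppm window: signal above 5× the noise
(estimated in the signal-free 9.5–10 ppm region) marks **every** G₂
quantification unreliable.  Ethyl side chains detected in the aliphatic
region (per-proton integral above 5 % of the TTB per-proton integral) mark
PGOH unreliable, since EG then sits inside its window.

When gated, G-type amounts are recovered from the side-chain windows: each
clean chain window gives the total molar amount of that chain
(`propyl γ` → PS+PG, `ethyl β` → ES+EG, `hydroxypropyl γ` → PSOH+PGOH), and
subtracting the S-type amount (known from the well-resolved S₂/₆ singlets)
leaves the G-type amount.  Negative inferred amounts beyond 5 % of the S
amount are flagged and floored at zero.  Fallback results carry an
`aliphatic_fallback` flag so downstream statistics can distinguish the route.

## Uncertainties

Per-compound standard errors propagate the frequency-domain noise (std of
the 9.5–10 ppm region) through the trapezoid and — when the endpoint baseline
is active — the subtracted chord, whose two averaged endpoints dominate the
variance for wide windows; a factor √2 accounts for zero-fill correlation.
Analyte and internal-standard relative variances add.  These are noise
floors, not total error bars: unmodelled interferences are reported as flags,
not variance.

## The simulator

Synthetic FIDs are sums of decaying complex exponentials: one line per
first-order multiplet component (amplitude ∝ molar concentration × proton
count / line count, decay rate π·r₂), Gaussian time envelopes for unresolved
multiplets, and seeded complex Gaussian noise.  Defaults — 400 MHz, 13 ppm
sweep, 2 s acquisition, r₂ = 1 Hz, noise σ = 0.5 — give 0.25 Hz/point after
one zero-fill and put the primary monomers at peak SNR well above 50 at
typical yields.  Six scenario presets emulate the selectivity regimes real
oils show: `propyl_selective` (the reference oil: PS 8.2, PSOH 3.8, PG 5.26,
PGOH 2.9 wt % with minor PES/PEG/ES/EG and pHBA/MP), `mixed_50_50`,
`oh_selective` (≥90 % hydroxypropyl), `h2free_propenyl` (PES/PEG dominant,
PS/PG ≈ 0.2 wt %), `pdc_three_chain` (ethyl/propyl/hydroxypropyl
co-produced) and `phenol_rich`.  Scenario EG values follow the `ES·(PG/PS)`
relation, i.e. the assumption that the syringyl/guaiacyl ratio is constant
across side chains, which is exactly the assumption the EG estimator makes.
Scenario yields map to tube concentrations through the default prep
(conc mg/mL = yield wt % / 20).

Ground-truth window integrals are computed from the closed-form line shapes
on the processing grid, so every downstream stage can be checked against
exact values, including the noise floor (window-integral standard deviation
scales as σ·√points across seeds).

What the simulator does **not** emulate — and hence what passing tests do not
demonstrate about real oils: the dimer/oligomer background (available only as
an optional broad Gaussian hump, off by default), T₁-saturation weighting of
amplitudes, ¹³C satellites, solvent peaks, shift variability with matrix, and
second-order (strong-coupling) multiplets.  Real-data accuracy is bounded by
those effects, not by the arithmetic verified here; the aromatic-region
shifts of higher-mass species overlapping monomer windows is the dominant
known risk.

## Numerical choices and degenerate inputs

* Linewidth for the correction model is measured from the TTB aromatic peak
  by interpolated half-height crossing, clamped to [0.2, 10] Hz, falling back
  to 1.3 Hz if the peak shape is unusable.
* Peak detection thresholds are taken relative to measured noise, with an
  absolute floor of 10⁻³ of the global maximum so that noise-free synthetic
  spectra do not produce false detections.
* An all-zero spectrum yields no phenol detection, no side-chain flags, and a
  fatal internal-standard error from `quantify` (TTB undetectable).
* Joint-solve or corrected integrals that come out negative are floored at
  zero and flagged.
* The 50 % PEG subtraction operates in integral space, on the same spectrum's
  raw PEG G₂ integral, and PEG is quantified before PG.

## Validation problem sizes

The parameter-recovery study quantifies 50 synthetic oils (one per seed,
cycling through all six scenarios with ±15 % log-normal concentration
jitter, noise σ = 0.5).  Compounds quantified from isolated singlets at peak
SNR ≥ 50 recover with ~2 % median absolute relative error; the mean absolute
yield deviation over all reliably reported compounds is ~0.15 wt %.  These
figures are computed fresh by `scripts/acceptance.py` and by the test suite
on every run; nothing in this note is asserted that the code does not
recompute.

## Known limitations

* Accuracy claims transfer to real oils only to the extent the simulator's
  idealizations hold; the oligomer background is the main gap.
* The EG estimate inherits the constant-S/G-ratio assumption and is reported
  as an estimate, never as a measurement.
* PHBA/MP cannot be separated by this experiment; their sum is reported with
  the PHBA molar mass, which understates the paraben share by ~9 % of the MP
  mass.
* Bruker/Varian raw directories are not parsed; convert to JCAMP-DX or
  ppm/intensity text first (the reader functions are the documented hook
  point).
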
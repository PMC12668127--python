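# Methods

## Signal and transfer model

The simulator abstracts magnetization-transfer physics to amplitude
bookkeeping.  A resonance is a separable product over dimensions: the
direct dimension contributes `a·exp(iΩt − Rt)`; an indirect dimension
contributes, per hypercomplex component,

* **CP / States**: `cos(Ωt)·e^(−Rt)` or `sin(Ωt)·e^(−Rt)` — a single
  transverse component survives the transfer, at unit amplitude (CP defines
  the reference scale).  States-TPPI additionally alternates the sign with
  `(−1)^k` per increment `k`.
* **TROP / echo-antiecho**: `b·exp(±iΩt − Rt)` — both components survive at
  bulk efficiency `b` relative to CP; the `+Ω` (p-type) pathway is the echo.

No spin dynamics is simulated: the enhancement and time-equivalent calculus
depends only on the component count and the bulk amplitude `b`, so this
bookkeeping reproduces it exactly while keeping 5D simulations desk-scale.
Offsets are given in Hz (converted to ppm through each dimension's observe
frequency and carrier).  TROP imperfection is modelled only through the
scalar `b`; phase errors and site-specific variation are not modelled.

Thermal noise is iid complex Gaussian with standard deviation `sigma` per
recorded point, identical for every hypercomplex component FID and for both
experiment types — receiver noise does not depend on the pulse sequence.
All randomness flows through `numpy` Generators seeded explicitly; identical
inputs and seeds give bit-identical grids.

## Quadrature conventions

Rance-Kay recombination is fixed to

```
cos = (E + A) / 2      sin = (E − A) / (2i)
```

with the division by `i` acting as the 90° zero-order phase correction on
the difference component.  This scale makes a noiseless echo/antiecho
acquisition numerically identical to the States acquisition of the same
resonances (the basis of the equivalence tests) and maps component noise
`σ → σ/√2`.  The convention and the per-grid cumulative noise-scale factor
are recorded in provenance metadata; the noiseless-limit "analytic
enhancement" reported by the pipeline is the peak ratio divided by the
noise-scale ratio, which equals `b·2^(n/2)` exactly.

States-TPPI is simulated as `(−1)^k`-modulated cos/sin components; the
conversion to plain States re-applies the alternation, after which peaks
appear at their true offsets with no axis shift.  (The equivalent textbook
convention shifts the axis origin by `sw/2` instead; the two differ only in
where the alternation is undone.)

The hypercomplex Fourier transform keeps one length-2 component axis per
dimension (the direct dimension's complex pair included) in a purely real
array; transforming a dimension pairs its two components into a complex
interferogram, FFTs along that dimension's time axis, and splits the result
back.  Each step touches only its own axes, so per-dimension transforms
commute — this is what makes States and echo/antiecho processing
order-independent, and it is asserted as a test.  The all-real component of
the fully transformed array is the absorptive spectrum.

Axes are strictly increasing ppm arrays, `ppm = carrier + offset/observe`;
grid indices are 0-based; indirect dimensions are ordered as acquired with
the direct dimension last.  Default processing: zero-fill ×2, no
apodization, no first-point scaling (`em` and half-cosine windows are
available but off by default — determinism and exact linearity matter more
here than cosmetic baselines, and the small constant baseline offset from
the uncorrected first point cancels in the mean-subtracted SNR estimator).

## Non-uniform sampling

A schedule is a set of multi-indices over the indirect time grid; one
sampled "point" covers all `2^n` hypercomplex components of that increment,
and the origin (first FID) is always included.  Modes: `uniform_random` and
`exponential_biased` (weight `exp(−Σ bias_i·k_i/N_i)`, default rate 2 per
dimension), drawn without replacement from a seeded Generator.  The
interchange format is plain text, one index tuple per line, `#` comments.

The nuFT is simply the hypercomplex FT of the masked (zero-filled) grid, so
a full schedule reproduces the plain transform bit-for-bit.  The point
spread function is the spectrum of the indicator mask normalized to 1 at
zero frequency; it is the one complex-valued `SpectrumGrid` the package
produces (a random mask has no symmetry), and the nuFT of a noiseless
on-grid peak equals the peak height times the circularly shifted PSF — an
identity the tests check to 1e−10 using on-grid, non-decaying oracle
resonances (off-grid peaks would add leakage terms that obscure the exact
identity without changing the physics).

## Iterative thresholding reconstruction

The reconstruction stage is a generic, deterministic
iterative-thresholding scheme in the spirit of the hypercomplex IST family:
per iteration, the residual's spectrum (after the fully-sampled direct
dimension is transformed; hyperplanes per direct-frequency point by
default) is thresholded at a constant fraction (default 0.98) of its
current per-plane hypercomplex-magnitude maximum; the part above threshold
accumulates into a spectral model; the residual is re-derived as
measured-minus-model at sampled points and zero elsewhere.  The returned
object is the spectrum of the *completed* FID — model prediction at
unsampled increments, measured values (with the final residual re-inserted)
at sampled ones — processed like any conventional data set.  Consequences:

* data consistency is exact by construction (`ist_complete` exposes the
  completed grid; a test verifies sampled increments are untouched),
* a full schedule returns the plain FT to numerical precision,
* reconstruction is deterministic given data + schedule,
* all knobs (iterations, threshold fraction and decay, stop tolerance,
  per-plane flag) live in `ISTConfig` and are logged in provenance.

No parity with any external reconstruction program is claimed; the stage
exists to reproduce reconstruction *phenomenology*.  Convergence of the
constant-fraction threshold is geometric and slows as the sampled fraction
drops: on the sparse 2D test fixture, 300 iterations suffice at 50%
sampling (off-peak artifacts >10× below nuFT) while 25% sampling needs
~1000 iterations for 1%-accurate peak heights.  Defaults (100 iterations)
favour speed; the tests pass explicit budgets.  Signals that are not sparse
on the acquisition grid (broad Lorentzians on very short grids) converge to
data-consistent but biased completions — an inherent property of
underdetermined reconstruction, visible in the toy fixtures if pushed.

## SNR estimation

High-dimensional spectra are evaluated as stacks of 2D planes.  For one
peak: sample 100 random grid points (without replacement, seeded) outside
an exclusion rectangle around the peak — defaults ±1.0 ppm along an
amide-proton-type axis and ±2.5 ppm along a nitrogen-type axis, generalized
to arbitrary per-axis half-widths since other plane types need other
windows — subtract their mean from the peak intensity, and divide by their
standard deviation.  Mean subtraction makes the estimator exactly invariant
to constant offsets; a zero-variance sample raises a dedicated error rather
than returning infinity.  With NUS data this "effective noise" deliberately
mixes thermal noise and sampling artifacts; comparing it before (nuFT) and
after reconstruction, for enhanced versus conventional experiments,
quantifies the non-linear reconstruction gain.  Peaks undetected in the
conventional experiment are flagged and excluded from mean enhancements.

The Monte-Carlo studies in the test suite use a dense-grid variant
(standard deviation over all off-peak points, optionally of the difference
to the noiseless reference spectrum) where estimator sampling error would
otherwise dominate, and compare ratios of per-peak mean SNRs, which is free
of the convexity bias of averaging per-realization ratios.

## Enhancement calculus and the reference table

`E = b·2^(n/2)`, break-even `b = 2^(−n/2)`, conventional-time fraction
`1/E²` — all computed from unrounded intermediates with final-step
rounding.  The hNH-time multiple is composed as
`2^(n_ind − 1)/(s·E)²`: each indirect dimension beyond the hNH's single one
doubles the hypercomplex FID count per sampled grid point, and the
inverse-square factor converts the first-FID SNR deficit `s·E` into time.
This composition reproduces every reference-table cell and is kept in a
single documented function.

Rounding ledger: printed enhancements use two significant figures,
conventional-time fractions two decimals, and hNH multiples the precision
at which each reference value is quoted (two significant figures
throughout, three for the 319 cell).  The one quantity quoted from rounded
intermediates — the headline time saving 7.8 = 2.8², squaring the printed
enhancement — lives in its own function (`headline_time_saving`) so the
two conventions can never mix silently.  The improved-NH-transfer variant
of the table uses the measured alternative bulk values where available and
otherwise a uniform 1.35× improvement factor, capped at the quoted value.

## Synthetic fixtures: what they emulate and what they do not

The fixture library (`toy2d`, `toy3d_mixed_encoding`, `toy4d_3enh`,
`toy5d_3enh_smallgrid`) generates few-peak spectra with realistic sweep
widths and carriers for ¹H/¹⁵N/¹³C at 800 MHz, sized to run end-to-end in
seconds (the 5D uses 6 complex points per indirect dimension; dimensions
under 16 points snap peak offsets onto grid frequencies, since at that
resolution off-grid sinc loss across four dimensions would leave
unrepresentative spectra).  Monte-Carlo problem sizes in the tests — 200
noise realizations for the √2 studies, 4 amplitude levels × 20 seeds for
the reconstruction-gain trend — were chosen as the smallest designs whose
standard errors cleanly resolve the effects.

What passing tests show: the quadrature algebra, transform identities, NUS
convolution contract, enhancement calculus and the *direction and shape* of
the reconstruction non-linearity are correct.  What they do not show:
agreement with any measured spectrum — real data add site-specific transfer
efficiencies, phase errors, t₁-noise, water/solvent artifacts and
non-Lorentzian lineshapes that this generator deliberately omits, and
observed enhancements of real experiments depend on the reconstruction
program and schedule actually used.

## Known limitations

* The transfer model cannot predict `b`; it is an input, not an output.
* Scan counts and recycle delays are not modelled; time equivalents are
  analytic.
* Water-suppression constraints are documented (a suppression block
  retains one component, so it can only precede States-encoded evolution)
  but not simulated.
* The reconstruction stage is one member of a family; quantitative artifact
  levels are specific to it.
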
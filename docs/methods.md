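# Methods

## The matching model

`cdmatch` treats spectral comparison as a nearest-neighbor search under
the normalized root-mean-square deviation

NRMSD = sqrt( Σ(θ_exp − θ_cal)² / Σ(θ_exp)² ),

where θ_exp are the query's CD values and θ_cal a reference's, evaluated
on a grid the two spectra share. The statistic is deliberately
asymmetric: the query supplies the denominator, so it fixes the scale
against which every reference is judged, and swapping query and test
changes the score. NRMSD is 0 for identical spectra; a reference no
better than a flat zero line scores exactly 1; values above 1 are
possible for anti-correlated spectra.

The assumption underlying the whole approach is that far-UV CD spectra
of proteins with similar secondary-structure content and fold are close
in this metric. The method compares spectra, not structures; matches
reflect spectral proximity, which usually — but not provably — tracks
structural similarity.

### Preprocessing

Before scoring, both spectra are restricted to the intersection of
their native wavelength ranges, any user-requested window, and — when
the user requests no window — the standard far-UV region 190–250 nm.
The windowed spectra are resampled by linear interpolation onto the
grid `wl_min, wl_min + step, …, ≤ wl_max`. Extrapolation is never
performed.

- **Grid step** (`grid_step`, default 1.0 nm): typical deposited-data
  granularity; configurable down to the instrument step.
- **Interpolation**: linear. CD spectra are smooth and densely sampled;
  linear interpolation is exact on the line segments between points and
  can never overshoot the data envelope, unlike splines.
- **Minimum usable overlap**: 10 grid points. A pair whose shared
  window holds fewer points is reported as *skipped* (with a reason)
  rather than scored — an NRMSD over a near-empty window is
  meaningless — and a skip never aborts a batch search.

### The four methods

1. **Simple Fit** — NRMSD of the unmodified spectra over the shared
   window. The conventional reading is that NRMSD ≤ 0.10 indicates
   strong spectral similarity; the package surfaces this figure as an
   annotation on Simple Fit reports, never as a filter.
2. **Normalized Comparison** — the test spectrum is multiplied by
   (query's scaling peak)/(test's scaling peak) before scoring, where
   the scaling peak is the extremum of largest *absolute* magnitude
   within the window, sign preserved. "Largest absolute magnitude" is
   the deliberate design choice here: for many proteins the dominant
   CD feature is a negative band, and scaling at a signed maximum would
   misbehave on all-negative windows. A zero scaling peak raises a
   degenerate-spectrum error (a skip in batch mode). The applied scale
   factor is recorded in the result.
3. **Ratio Comparison** — each spectrum is reduced to the ratio vector
   (v208/v222, v195/v222, v195/v208) of its values at the three
   diagnostic secondary-structure bands, obtained by linear
   interpolation at exactly 195, 208 and 222 nm, and the two ratio
   vectors are scored with the same NRMSD formula. Two open design
   points were settled as follows: the three pairwise ratios in fixed
   order (symmetric, uses all three bands), and band *values at* the
   stated wavelengths rather than local-extremum detection near them
   (deterministic; extremum hunting is ill-defined on noisy spectra).
   Denominators whose magnitude falls below 1e-6 × max|values| of the
   spectrum raise a degenerate-ratio error; the threshold is
   scale-aware so unit choice cannot change the outcome.
4. **Wavelength Shift** — the query's wavelength axis is displaced by
   each δ in {−max_shift, …, 0, …, +max_shift} stepped by
   `shift_step`; for every candidate the overlap window, grid and
   NRMSD are recomputed, and the minimum NRMSD is returned together
   with its δ. Ties break toward smaller |δ|, then toward negative δ,
   so a self-match always reports shift 0.0. Defaults: max_shift 3.0
   nm, shift_step 0.1 nm — CD calibration offsets are rarely beyond
   ~2 nm, and the fine step keeps the reported shift magnitude
   meaningful. With max_shift = 0 the method reduces exactly to Simple
   Fit. Note that different candidate shifts can legitimately score
   over slightly different windows (the overlap moves with the query);
   this mirrors the "recompute the overlap per shift" definition
   rather than freezing one grid.

### Search semantics

A search converts every reference to the query's units (references
move, the query — and hence the NRMSD denominator — stays fixed),
scores each pair, turns per-pair failures (no overlap, degenerate
peak/ratio, all-zero query window) into skipped entries with reasons,
filters by the optional NRMSD cutoff, sorts ascending by (NRMSD,
reference id) and truncates to `max_matches`. Sorting on the id as
tie-break makes output order total and deterministic. Defaults:
`max_matches` 10, no cutoff — the 0.10 figure is interpretive advice,
and informative matches well above it exist, so nothing is dropped
silently.

## File formats and units

Three dialects are read: plain two-column ASCII (whitespace or comma
separated, `#` comments and unparseable header lines skipped),
CDtools-style generic files (free-text headers, then a numeric block
whose first two columns are wavelength and CD; extra columns such as
the HT trace are ignored), and PCDDB flat-file entries, parsed
tolerantly: tagged lines supply the PCDDB ID, protein name and units,
and the final contiguous numeric block is taken as the processed
spectrum. The PCDDB parser extracts only the fields that feed matching
and ignores the rest of the entry; the tag layout accepted ("tag, two
or more spaces or a colon, value") is this package's own tolerant
dialect, written to survive layout drift. Files that state no units
default to delta epsilon with a logged warning (the processed-spectrum
convention). Unit conversion uses the standard per-residue relation
[θ] = 3298.2 × Δε, a bijection to machine precision.

Wavelength grids are canonicalized ascending on parse regardless of
scan direction; duplicate wavelengths are averaged with a warning
(deterministic and order-independent). The two-column writer emits
descending wavelengths (instrument-scan convention) at full float
precision, so write→parse round trips are lossless.

## The synthetic generator

Test spectra are mixtures of three fixed secondary-structure basis
shapes, each a documented sum of Gaussian bands (center, width,
amplitude in Δε): helix = +11.0 at 193 nm (σ 6.5) − 9.3 at 208 nm
(σ 7.5) − 9.8 at 222 nm (σ 9.5); sheet = +5.5 at 195 nm (σ 7.0) − 4.2
at 218 nm (σ 9.0); coil = −6.5 at 198 nm (σ 7.0). A recipe mixes the
bases by secondary-structure fractions, scales the magnitude, offsets
the wavelength axis, and adds Gaussian noise with standard deviation
expressed as a fraction of the clean spectrum's peak magnitude —
additive, so the NRMSD floor it induces is analytically predictable.
Everything is a pure function of the recipe (including the seed), so
generated fixtures are bit-stable. The default synthesis grid is
175–260 nm at 0.5 nm; family generation perturbs the base fractions by
a uniform ±jitter per component (clipped, renormalized) with member
seeds derived from `base.seed + index`. Default test conditions — 2%
noise, 5% fraction jitter, 20-member families — sit at the
well-behaved end of real measurement conditions.

These band constants are test fixtures, not physics: they give spectra
with realistic band positions, signs and relative magnitudes, so the
*relative* behavior of the methods (scale invariance, shift recovery,
within- vs between-family separation) transfers to real data, but
absolute NRMSD values do not. The generator omits aromatic side-chain
contributions, membrane-protein band shapes, wavelength-dependent noise
and HT-related low-wavelength artifacts; passing tests therefore
demonstrate correctness of the algorithms, not calibration against
measured spectra.

## Numerical choices and degenerate inputs

- All interpolation is `numpy.interp`; no extrapolation anywhere.
- Grid construction uses a 1e-9 slack when counting steps so that
  windows whose width is an exact multiple of the step include the
  endpoint despite floating-point representation.
- An all-zero query window makes the NRMSD denominator zero: an
  undefined-statistic error (a skip in batch mode), never a division
  by zero at runtime.
- `Spectrum` construction validates everything once (finite positive
  ascending wavelengths, finite values, length ≥ 2), so downstream code
  can assume a valid spectrum.
- Ties in the shift search and in report ordering are broken by fixed
  documented rules (smaller |δ| then negative δ; reference id), making
  every output byte-reproducible.

## Problem sizes

The test suite and the acceptance script run on synthetic sets of 40–50
spectra (~170 points each), 100-pair oracle comparisons, and 200-file
I/O round trips — comfortably representative of a PCDDB-scale search
(hundreds of entries), which the implementation handles by the same
O(refs × grid) path.

## Known limitations

- The original web tool's unpublished defaults (wavelength window, grid
  step, match count, cutoff) may differ from this package's documented
  choices; windowed NRMSD values are only comparable between runs using
  the same window and step.
- Ratio Comparison reads band *values* at 195/208/222 nm; an
  implementation that hunts local extrema near those wavelengths would
  score noisy spectra differently.
- No smoothing, baseline subtraction or zeroing is applied; inputs are
  assumed to be processed spectra.
- Secondary-structure deconvolution, significance testing of NRMSD
  values and reference-set curation are out of scope.
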
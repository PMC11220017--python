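# Methods

## Spectral box counting

All structure metrics act on *spectral* space, not the image plane. For an
*n*-band frame analysed at depth *S* bits, a pixel is a point in the
*n*-cube of band values `[0, 2^S)^n`. At level *j* (1 ≤ *j* ≤ *S* − 1) the
cube is partitioned into `(2^j)^n` boxes of edge `2^(S−j)`; the box holding
a pixel is found by keeping the top *j* bits of each band value
(`v // 2^(S−j)`). This halves the box edge per level — the standard
box-counting refinement — and makes box membership a pure quantisation, so
occupied boxes at level *j* + 1 can never merge at level *j*: SBM_j is
non-decreasing in *j*, which the property tests assert.

Two normalisations of the box-count ratio are exposed, because the
literature prints both:

- **ESR** divides `log SBM_j` by the constant `log (2^S)^n` at every level;
- **DSR** divides by the level's own grid size `log (2^j)^n`.

DSR is the form with box-counting-dimension semantics (constant frame → 0,
full occupancy → *n*) and is the default downstream; ESR is kept verbatim
as its own metric. The log base cancels in these ratios; the
implementation uses natural logs there and base-2 logs for entropies
(which are reported in bits).

## Entropy weighting

The entropy weight of level *j* is `f_j = H_j / (j·n)`, where `H_j` is the
Shannon entropy of the level-*j* quantised histogram taken over **all**
pixels of the ROI, and `j·n` is the maximum entropy of an *n*-tuple of
*j*-bit symbols. The per-sample (whole-ROI) histogram is the reading under
which the `j·n` normaliser is actually the maximum, which is why it was
adopted over a per-box histogram; for *n* = 1 it reduces to the familiar
`H_j / j`. `f_j` is clipped to [0, 1] against floating-point drift.

The EW-SFD term at level *j* is `log(f_j · SBM_j) / log (2^j)^n`. When
`f_j · SBM_j < 1` the logarithm would be negative (−∞ for a constant
region); such a level carries no structural information, so its term is
defined as zero. The number of floored levels is reported in every
`MetricResult` and CSV row, so a curve dominated by the floor rule is
visible as such. Consequences asserted by tests: EW-SFD ≤ SFD-DSR
everywhere, with equality exactly when every level histogram is uniform.

## Analysis depth

Recordings are stored in 16-bit containers but the data are far shallower;
the two study-scale experiments the package's defaults mirror had 6- and
8-bit effective depths. The analysis depth defaults to the *effective data
depth* of the corrected ROI sub-stack — the smallest *S* with all values
below `2^S`, floored at 2 so the level range 1 … *S* − 1 is non-empty — and
can be fixed per run. Values are never rescaled when the depth changes;
only the level range moves, so a *j*-level census at one depth equals the
(*j* + Δ)-level census at a depth Δ bits larger (tested).

"Valuable pixel" means every pixel inside the ROI after correction, zeros
included: no validity mask is defined for this kind of data, and excluding
zeros would leave the background window's metrics undefined. An opt-in
`exclude_zeros` flag drops all-zero pixels for users who want it; a window
that empties under it yields an all-zero result rather than an error.

## Processing chain

Order: per-pixel dark correction → integration-time rebinning → ROI
extraction → pixel-by-pixel background correction → per-frame metrics.

- **Dark correction** subtracts a per-pixel reference (a dark stack is
  reduced to its per-pixel mean, rounded to the nearest count so frames
  stay integral) and clamps at zero: photon counts are non-negative, so
  clamping, not recentring, is the physically meaningful choice.
- **Background correction** pairs pixels positionally between two
  same-size, disjoint windows and subtracts, clamped at zero. A scalar
  mode (subtracting the background window's per-frame mean) exists but is
  off by default. The background window is its own reference: its series
  is computed without background subtraction, which is what makes the
  background curve comparable to published background traces.
- **Rebinning** sums runs of *k* frames into one (emulating a *k*-times
  longer integration time), accumulates in 64-bit integers, drops a
  trailing partial bin so all output frames cover equal intervals, and
  re-declares the container depth from the largest summed value (capped at
  a 32-bit accumulator).

The analysis path contains no randomness: identical inputs produce
byte-identical CSV output, which the CLI tests check literally.

## Synthetic scenarios

The generator draws each pixel of each frame independently as
`Poisson(dark_mean + a(t) · source(p))` — the minimal model for a cooled
single-photon-sensitive sensor: a dark rate plus localized emission. It
deliberately omits optics (no PSF), read-noise and gain structure, pixel
cross-talk, and any temporal correlation of the biological signal, so
passing tests demonstrate that the metrics and pipeline behave as
specified on Poisson photon fields — not that real embryos are separable
at any particular signal level.

Defaults, chosen once as realistic desk-scale study conditions: 60 frames
of 60 s integration (1 h of the study's 1-min cadence), 64×64 pixels in a
16-bit container, dark mean 3 counts/frame/pixel, one Gaussian-profile
source (peak 30 counts/frame/pixel, radius 8, σ = radius/2) centred in the
embryo window, and 21×21 sampling windows matching the study's ROI size.
Temporal profiles: `constant`/`live` hold the source steady;
`degenerate` multiplies it by `exp(−(t − t*)/τ)` after the changepoint
(default t* = 30, τ = 3 frames). An optional `multiscale` texture
modulates the rate field with an octave-mixed random surface for tests
needing tunable spectral occupancy. Seeding: one root `SeedSequence`,
per-frame child seeds spawned by counter, so stacks are bit-reproducible
regardless of generation order; rates that clip more than 1% of pixels at
the container ceiling trigger a warning recorded in the stack metadata.

`generate_structured_frame(S, q)` builds single-band frames whose level-*j*
occupied-box count is `⌈q · 2^j⌉` *by construction*, by growing the prefix
tree of box addresses so every coarser box keeps at least one child. Its
DSR SFD therefore equals the closed form
`Σ_j log⌈q·2^j⌉ / log 2^j / (S−1)` exactly, giving the metric code an
analytic acceptance surface.

## Numerical conventions and edge cases

- `p · log₂(1/p) → 0` as `p → 0`; zero-count symbols contribute nothing.
- Entropy of an empty histogram is an error, not 0: it is undefined.
- Stacks are validated on construction (shape, integrality,
  non-negativity, container fit); ROIs must lie fully inside the frame —
  out-of-bounds windows raise instead of clipping silently.
- ROI coordinates are 0-based and half-open, stated once and used
  everywhere.
- `.btf` batch files are treated as the multi-page TIFF dialect they are;
  BigTIFF is accepted, page order is acquisition order, and no timestamp
  parsing is attempted (acquisition is contiguous at fixed integration
  time). Stacks written by this package carry a JSON description with the
  declared container depth and frame interval so round trips preserve
  them; foreign files fall back to the file's sample depth.

## Verification strategy

The fast metric path is cross-checked against a deliberately naive oracle
(in `tests/oracle.py`, with a second independent copy behind
`ewsfd selfcheck`) that materialises every spectral box as an explicit
value range and counts by membership: exhaustively on all 256 single-band
2×2 frames at 2-bit depth, and on seeded random frames at 4-bit depth,
to 1e−12. Pipeline-level behaviour is checked on generator ground truth:
dark/background corrections recover known source means, the
live/degenerate EW-SFD ordering and embryo/background entropy ordering
hold in ≥ 95 of 100 seeded replicates, and a CUSUM split of the EW-SFD
series locates the programmed collapse within ±5 frames. Problem sizes in
the test suite and acceptance script (tiny frames for exhaustive checks,
60-frame 64×64 stacks for scenario statistics) were chosen as the smallest
at which each property is meaningfully exercised.

## Known limitations

- No spatial (image-plane) fractal dimension or lacunarity; the metrics
  are spectral-space only, and no two-image SFD distance is provided.
- No embryo detection or viability classification: ROIs are user-supplied
  and the output is metric curves.
- The Poisson generator cannot establish real-data effect sizes; it
  validates the algorithms, not the biology.
- Multi-band input is supported throughout (the `j·n` normalisation
  generalises the single-band weighting), but the motivating data are
  monochrome; multi-band behaviour is exercised only against the
  brute-force oracle.
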
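# Methods

## Model

A riverscape is a binary habitat raster on a square metric grid: each
cell is suitable (1), unsuitable (0) or outside the active river channel
(nodata). A *patch* is a maximal contiguous group of suitable cells.
Seed dispersal is isotropic and negative exponential: the seed fraction
an ideal source delivers at distance *x* metres is proportional to
(1 − decay)^x. All metrics are relative to an *ideal cell* — one whose
entire dispersal neighbourhood consists of donor cells — which receives
the value 1. The model deliberately excludes long-distance and secondary
(hydrochorous) dispersal, barriers/cost paths, occupancy and graded
habitat quality; the last two can be layered on through the
`weighted_seed_rain` hook (receiver side) or by masking the habitat
input (donor side).

### Kernel discretisation

The kernel is a square matrix of odd dimension 2·⌈SDD/cell⌉ + 1, so the
window radius in metres always covers the short-distance dispersal range
even when SDD/cell is non-integral. Element values are
(1 − decay)^(cell · √(Δr² + Δc²)) with Euclidean distances between cell
centres in map units; the centre is zeroed *before* normalisation and
the matrix divided by its sum. Corner cells farther than the SDD keep
their exponential value — the matrix boundary is the only cutoff, and
the normalisation absorbs the tail. The decay rate derived from an SDD
(decay = 1 − (1 − q)^(1/SDD), q = 0.95 by default) is used at full
precision; rounding to two decimals is presentation only. The 0.95
quantile is the field convention and reproduces the published example
decays (0.19 for 14 m, 0.10 for 30 m); 0.99 is selectable. User-supplied
matrices (e.g. wind-biased) of any odd dimension are accepted after
centre-zeroing and optional renormalisation; isotropy is then not
assumed.

### Metrics

- eS(i) = Σ over suitable cells j of other patches within the window of
  K[offset(i, j)]. Cells outside the raster and nodata cells contribute
  and receive nothing; there is no wrap-around.
- eC(patch) = Σ eS over its cells; eC(A, B) = Σ over (a ∈ A, b ∈ B) of
  K[offset(a, b)]. By construction eC(patch) equals both the sum of its
  pairwise row and the patch's share of total eS (conserved to 1e-9,
  asserted in tests).
- eD = log₍₁₋decay₎(eC), clamped at 0 (eC ≥ 1), infinite at eC = 0.
- nC counts other patches with pairwise eC ≥ threshold (default 0.01);
  cC = eC/nC with the *un-thresholded* eC in the numerator —
  sub-threshold seed rain is retained in eC and cC, it just does not
  add a connection. cC = 0 for unconnected patches.
- Riverscape level: cP = mean patch eC over all patches; eDm and its sd
  are computed over finite eD only (clamped zeros included) and must be
  read together with the percentage of connected patches; nCm/cCm are
  means over all patches, including unconnected ones. Reported sds are
  sample standard deviations (ddof = 1, NaN for a single patch) and the
  relative sd is the plain ratio sd/mean (not ×100), NaN when the mean
  is 0.

## Numerical choices

The fast path computes eS as one correlation of the suitability mask
with the kernel minus, per patch, a correlation of the patch's own mask
restricted to its kernel-padded bounding box. Correlation (not
convolution) is used so that user-supplied anisotropic kernels keep
donor-relative-to-receiver semantics; for the isotropic exponential
kernels the two coincide. The semantics are *defined* by the brute-force
per-cell-pair sum in `riverconnect.synthetic`, and the suite asserts
agreement to an absolute 1e-9 on every cell across 100+ seeded random
landscapes; the fast path is an optimisation, never a semantic choice.
Tiny negative residuals from the subtraction (≈1e-16) are clipped to 0.
Patch labeling uses 8-neighbour adjacency by default — the default of
common raster clumping tools — with 4-neighbour selectable, because the
choice changes patch counts and hence every per-patch metric. Labels are
remapped to row-major order of first occurrence so labeling is
deterministic. Degenerate inputs: a landscape with zero suitable cells
yields an empty patch map; a single-patch landscape yields eS ≡ 0,
eC = 0, eD = ∞ and an undefined (NaN/null) eDm; an all-nodata raster is
rejected.

## Synthetic landscapes

The generator stands in for real braided-river corridors, which are not
distributed with the package. It emulates their load-bearing features:
many small patches of varying shape and spacing inside an active-channel
boundary (the `nodata_margin`), with patch geometry controllable through
rectangle/ellipse primitives. Default cell size is 5 m, matching the
resolution the metrics were designed around; random landscapes default
to 40×40 cells (200 m × 200 m) with primitives of 1–6 cells, giving
patch sizes and gaps on the order of the example species' 14–30 m
dispersal ranges so that landscapes contain a realistic mix of connected
and isolated patches. A single explicit integer seed determines a
landscape bit-exactly; there is no global RNG state. What the generator
does *not* emulate: hydrologically realistic braided-channel geometry,
spatial autocorrelation of real gravel bars, and temporal habitat
turnover — so passing tests demonstrate correctness of the computation
on arbitrary patch mosaics, not ecological realism of any particular
landscape.

The brute-force oracle is guarded at 10,000 suitable cells; test
landscapes stay at or below 50×50 cells, which keeps the full suite and
the oracle-equivalence sweep (100 landscapes) within seconds on one CPU.

## Design decisions

- GeoTIFF I/O reads and writes the GDAL nodata and pixel-scale/tiepoint
  tags directly via tifffile; the ESRI ASCII grid format is parsed by
  hand. Non-square pixels are rejected rather than resampled.
- The CLI requires exactly one dispersal specification (`--sdd`,
  `--decay` or `--kernel-file`). With a bare `--decay` the window radius
  defaults to covering the distance at which 95% of seeds have landed,
  mirroring the SDD convention.
- Infinite eD serialises as `inf` in CSV and `null` in JSON; the summary
  JSON embeds all effective parameters (decay, SDD, quantile, threshold,
  adjacency rule, kernel dimension) so any output is reproducible from
  the sidecar alone. Outputs contain no timestamps; repeated runs are
  byte-identical.
- Whether riverscape sds for nC/cC should include unconnected patches is
  a genuinely open convention; they are included here, consistently with
  cP averaging over all patches.

## Limitations

eS is a relative colonization-probability surface, not an absolute seed
count; converting it to expected colonization events needs fecundity and
occupancy data. The ideal-cell reference (eS = 1) is a theoretical
anchor: under connected-component labeling a suitable cell's immediate
neighbours always belong to its own patch, so real cells approach but
cannot attain it (the package's tests realise it with an explicitly
constructed patch map). Metrics compare riverscapes only for a common
cell size and kernel; results are not invariant under resampling.
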
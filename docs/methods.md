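# Methods

## Charge model

Peptide net charge is the standard Henderson–Hasselbalch sum over
ionizable groups. Every peptide contributes a free N-terminus (basic) and
free C-terminus (acidic); each occurrence of H, K, R adds a basic group
and each D, E, C, Y an acidic one:

Q(pH) = Σ_basic 1/(1 + 10^(pH − pKa)) − Σ_acidic 1/(1 + 10^(pKa − pH)).

Q is strictly positive as pH → 0 (where it approaches the basic-group
count), strictly negative as pH → 14, and monotone non-increasing, so it
has a single root — the isoelectric point.

**pKa values are a model choice, not constants of nature.** The default is
the EMBOSS free-amino-acid set (N-term 8.6, C-term 3.6, C 8.5, D 3.9,
E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1, all pH units); published sets differ
by up to ~1 pH unit and every derived quantity (pI, flat-charge range)
shifts with them. The table is user-replaceable via a YAML config
(`PkaTable.from_file`). Because most proteomics digests are alkylated,
`ionize_cysteine: false` removes cysteine from the acidic groups; the
default keeps it ionizable.

### Numerical choices

- **pI** is solved on the continuous charge function by bisection over
  (0, 14). The bracket is guaranteed by the sign behaviour above. The
  nominal tolerance parameter is 1e-4 pH, but the bisection always runs to
  a width of min(tol, 1e-11): the charge slope is at most
  ln(10)/4 ≈ 0.58 per group per pH unit, so at 1e-11 width the residual
  charge is far below the 1e-6 contract even for peptides with hundreds of
  ionizable groups. ~51 iterations; cost is negligible.
- **Titration curve**: the grid is fixed at pH 1.0–14.0 in 0.1 steps
  (131 points), evaluated vectorised.
- **Flat-charge range** uses the grid-count convention: 0.1 × the number
  of grid points with |Q| ≤ threshold (default 0.01, inclusive). A
  saturating threshold therefore yields 13.1 (131 points), not the
  interval length 13.0; we keep the literal grid measure rather than
  interpolating interval endpoints, and document the 13.1 cap so users are
  not surprised. Inclusive vs exclusive at the boundary is immaterial off
  a measure-zero set; inclusive is chosen.
- **Mass** comes from `pyteomics.mass` (monoisotopic by default, average
  on request). **GRAVY** is the mean Kyte–Doolittle hydropathy; the scale
  is replaceable.

## Span accounting

A peptide seen in *n* distinct fractions is *n*-spanned; *n* = 1 is
unique. Duplicate (sequence, fraction) rows in the input collapse to one
observation keeping the maximum score — the usual proteomics convention
for repeated identifications of the same peptide in the same well. The
"contiguous spreads" statistic is defined per peptide: a non-unique
peptide counts as contiguous iff its fraction set is one unbroken run of
adjacent indices. Identifier assignment (used to stack the span-bitmap
rows) sorts by (n_span, first fraction, pI, sequence); the figure is
thereby deterministic for a given dataset.

## Lens geometry

The overlap diagram is area-proportional with a single global constant k
(layout area per peptide), chosen so the largest fraction's circle has the
configured maximum radius. For each adjacent pair, the centre distance d
solves lens_area(r1, r2, d) = k · shared, where the lens area is the
closed two-circle form. The function decreases strictly and continuously
from π·min(r1,r2)² at d = |r1−r2| to 0 at d = r1+r2, so Brent's method on
that bracket converges to machine precision; the implementation enforces
|A(d) − target| < 1e-9·max(1, target). Degenerate targets bypass the
solver: shared = 0 places the pair tangent (keeps the chain compact;
separated placement would convey nothing extra), and a saturated target
clamps to containment. Intersection points, used to draw the two lens
arcs, are computed in the left circle's frame as
x = (d² + r1² − r2²)/(2d), y = ±√(r1² − x²). Only adjacent pairs are
solved; the chain accumulates the pairwise distances left-to-right on a
common baseline, so non-adjacent circles can overlap on the page without
meaning — a documented property of the pairwise-only semantics. Empty
fractions render as zero-radius markers to preserve the well axis.

## Report

Each panel builder returns a plain data structure (cells, segments,
lines, circle specs); rendering is a separate pass, so every numeric
claim about the figure is tested on the data layer without rasterising.
Colour maps (fraction → colour and n-span → colour) are injective and
shared across panels C, D, E. Panel E maps the sort value (default pI)
linearly onto [0.2, 1.0] of the column width so near-minimal values stay
visible, sets column width proportional to the fraction's peptide count,
and grades connecting lines from light to dark over the dataset's
flat-range min/max (configurable fixed bounds). Output formats are PNG,
PDF and SVG; SVG keeps label text as text (`svg.fonttype: none`) so
labels remain machine-readable. Files are written atomically via a
temporary file and rename. With fewer than two fractions, panels D and E
are replaced by a notice.

## Synthetic data generator

No public peptide-level dataset accompanies the kind of experiment this
package diagnoses, so the test bed is generated: uniform-residue random
proteins (default 50 proteins of 150–400 residues) are digested with the
trypsin rule (cleave after K/R, not before P; peptides ≥ 6 residues
reported), and each peptide is deposited on a 24-well pH 3–10 gradient
partitioned evenly. The carry-over model:

- apparent pI = computed pI + Gaussian(0, noise_sigma), default σ = 0.1 pH
  (the typical scale of disagreement between pI predictors);
- the peptide appears in every fraction whose pH interval intersects
  [apparent pI − w, apparent pI + w] with w = spread_alpha · flat_range/2,
  default α = 0.5;
- a zero-width window resolves by half-open interval membership, so the
  degenerate generator (α = 0, σ = 0) places every peptide in exactly one
  fraction by construction rather than up to edge ties;
- off-gradient peptides accumulate in the nearest end well, as in the
  physical device.

This is a test harness, not an electrophoretic transport model: it
reproduces the qualitative mechanism (flat titration curves ⇒ wide
spreads, concentrated at neutral pH) and the format of real data, but not
MS detectability, intensity, FDR structure, or the asymmetric well
geometry of real gradients. Passing pipeline tests therefore demonstrate
correct accounting and the recoverability of a planted mechanism — not
quantitative agreement with any wet-lab run. With the default α the
generator yields ~80–85% unique peptides and maximum spans of ~3; larger α
values produce the heavier carry-over seen in mid-gradient regions of
real experiments.

## Problem sizes

The test suite checks the charge model against a 0.001-pH brute-force
grid on 500 seeded random peptides, the lens solver against 10⁶-sample
Monte-Carlo area estimates on 500 random feasible layouts (shared counts
drawn to cover 20–95% of the smaller circle so the Monte-Carlo relative
standard error stays ≈2·10⁻³ and both the 1% and 4-SE bands are
meaningful), the generator sweep over α ∈ {0, 0.25, 0.5, 1, 2} × 3 seeds
with a 999-permutation test for the flat-range/span rank correlation, and
an end-to-end ~2000-peptide 24-fraction render. The full suite runs in
about a minute on one CPU.

## Known limitations

- PTM-annotated sequences are rejected rather than parsed; charge
  corrections for modifications are out of scope.
- pKa values are treated as temperature- and ionic-strength-independent.
- The identifier ordering and the panel-E width/length mappings are
  declared conventions where the underlying visualisation idea admits many
  choices; they are fixed for reproducibility, not claimed optimal.
- The acceptance script's quantities describe the synthetic conditions
  above; they are not estimates of any particular laboratory dataset.
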
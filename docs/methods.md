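# Methods

## The problem

CTCF is an architectural DNA-binding protein whose oriented, ~19-bp motif
organises phased nucleosome arrays on both sides of its binding sites: up to
~20 nucleosomes per side, a nucleosome-depleted region (NDR) shifted ~41 bp
5' of the motif centre, a strong first downstream nucleosome at +105 bp, and
an inter-nucleosome spacing (nucleosome repeat length, NRL) that shrinks as
CTCF binds more strongly.  `nrlkit` implements the analysis stack needed to
measure these quantities from nucleosome maps — dyad positions derived from
MNase-seq fragment centres or chemical-mapping cut starts — around any set of
oriented, scored anchor sites, together with a synthetic generator so the
whole pipeline is testable end to end without external data.

## NRL estimation by phasogram regression

For each anchor, dyads whose strand-oriented offset falls in a window
(canonically [100, 2000] 3'-downstream or [-2000, -100] 5'-upstream of the
motif centre; offsets are mirrored for minus-strand motifs) are collected,
and all unordered within-window pair distances are histogrammed at 1 bp
resolution.  Pairs never cross anchor windows; a dyad inside two overlapping
windows contributes to both, matching per-region pooling.  Regular spacing d
produces peaks at d, 2d, 3d, ….  The histogram is smoothed with a centred
moving average (window 20 bp, i.e. half-width 10; edges use the truncated
window mean), peaks are picked automatically (below), and the NRL is the
ordinary-least-squares slope of peak position on peak order.  Significance is
the regression F-test ("ANOVA p-value of the slope", df = (1, n-2),
identical to the two-sided t-test on the slope); estimates with p >= 0.05 are
flagged as failed, and a perfect (zero-residual) fit reports p = 0.  At
least three peaks are required.  The regression is unweighted: peak heights
fall roughly linearly with order (fewer pairs at longer range) while peak
positions stay equally sharp, so weighting would add a tuning knob without a
clear error model.

### Automated peak picking

The interactive peak annotation of the original NRL tooling is replaced by a
deterministic rule.  Candidate maxima are strict local maxima of the
smoothed histogram (flat-topped runs count once, reported at their leftmost
index; array ends never qualify).  Two guards make the scan robust to
counting noise:

- **Prominence floor.** Candidates whose topographic prominence is below 3%
  of the largest prominence are discarded.  True phasogram peaks scale
  linearly with the number of dyad pairs while shot-noise wiggles scale with
  its square root, so the floor is scale-free; at the default study
  conditions (500 anchors, depth 5, 15 bp jitter) noise maxima reach ~2% and
  the faintest true peak ~4%.
- **Replace-if-better.** Scanning left to right from `min_first` (default
  100 bp, the inner edge of the canonical window), a candidate closer than
  `min_sep` (default 120 bp, safely below one repeat) to the last kept peak
  replaces it when more prominent and is skipped otherwise.  Pure
  leftmost-first greed would let a minor shoulder just past `min_first`
  displace the true first peak and shift every rank.

Up to `max_peaks` (default 10) peaks are kept.  A histogram holding fewer
than one dyad pair per region is refused outright (no estimate): on
featureless noise the minimum-separation scan spaces maxima almost
arithmetically and would otherwise manufacture a spuriously significant
slope that the F-test cannot catch.

### The spanning-window artefact

Estimating the NRL in a window that spans the anchor, e.g. [-500, 500],
mixes two distance families: same-side pairs (a comb at multiples of d) and
cross-NDR pairs (the same comb shifted by the depleted gap width).  Their
superposition adds extra peaks and a fit through all peaks lands far below
d.  `interference_diagnostic` quantifies this: the one-sided flanking window
is fitted with the routine picker as the honest reference, the spanning
window is scanned with fine separation (40 bp) and a stiffer 10% prominence
floor (interference peaks carry a substantial share of the histogram mass;
noise does not), and every spanning peak without a flanking counterpart
within 10 bp is reported.  The spanning estimate is flagged artefact-prone
whenever such peaks exist.  On one-sided arrays the diagnostic is silent and
both estimates agree.  Windows for honest NRL estimation must therefore
exclude the anchor, which is why [100, 2000] is the canonical choice.

## Aggregate profiles, NDR localisation and asymmetry

Profile values are per-offset means over strand-oriented anchor windows
(minus-strand windows mirrored through the centre, so negative offsets are
always 5' of the motif).  Three occupancy modes exist: dyad counts per bin,
fragment coverage per bp, and interval-midpoint density per bin (used for
remodeller peaks, and for motif density near TAD boundaries at 5 kb bins).
Means are edge-aware — each offset divides by the number of anchors whose
window covers it — and per-region rather than raw counts, so datasets of
different depth are comparable.  `occupancy_profile` reconstructs an
MNase-like occupancy from a dyad map by widening each dyad to the 147 bp
protected footprint before computing coverage.

The NDR is the argmin of the smoothed occupancy profile within a search band
(default [-300, 300]; leftmost on ties; a flat profile returns the left band
edge with a warning).  The NDR smoothing window defaults to 101 bp, about
two thirds of a footprint: depleted regions are flat-bottomed at footprint
scale, so averaging at slightly narrower scale turns the flat bottom into a
V with a unique minimum at the depletion centre, while much wider windows
import the asymmetric occupancy further out and drag the argmin sideways
(measured drift of tens of bp at window >= 200).

`asymmetry_report` bundles the NDR offset, both per-side NRLs (absent, with
a flag, when a side yields fewer than three peaks or fails the significance
filter), their difference, and the smoothed occupancy at the two
characteristic downstream offsets +105 and +165 bp.

## Motif affinity and stratification

PWM scanning uses log2 odds with a background-distributed pseudocount (0.8,
the common scanning-tool convention) and reports every window, on both
strands, whose score reaches 80% of the achievable range:
`(S - S_min) / (S_max - S_min) >= 0.8`, the documented meaning of a
"similarity threshold".  Overlapping hits on opposite strands are both kept,
since the orientation analyses need them.  Windows containing non-ACGT bases
never match.

TRAP converts the position frequency matrix (pseudocount 1, distributed by
background) into per-column mismatch energies
`E = (1/lambda) * sum_j ln(p_max,j / p_b,j)` and sums Fermi-Dirac occupation
terms `R0 e^-E / (1 + R0 e^-E)` over every window of the motif interval
extended by 30 bp each side, both strands.  Defaults are `lambda = 0.7` and
`ln R0 = 0.584 L - 5.66` (the reference implementation's defaults); at
L = 19 a perfect-match window contributes 0.99566.  The affinity is summed
over both strands, making it reverse-complement invariant, and any single
mismatch can only lower a window's term.

Sites are stratified into five equal-size quintiles by ascending key (ChIP
peak height or TRAP affinity; ties broken by chromosome then position);
when the count does not divide by five the larger blocks sit at the weak
end, so Q5 ("strongest") is never padded.  Site filtering keeps motifs that
overlap at least one experimental evidence set by >= 1 bp and lie >= 1000 bp
from the nearest TSS (TSS position = interval midpoint; absent TSS tracks
impose no constraint).

## Interval annotation

TAD turnover uses fractional coverage with union semantics (no double
counting) over the query TAD's own length: > 0.90 common, < 0.80 lost (A
against B) or gained (B against A), and the literature's [0.80, 0.90] gap is
labelled `other` explicitly rather than silently joined to a class.
Enrichment is the per-quintile fraction of sites overlapping a feature by
>= 1 bp (site interval, not centre).  Flank read counting applies the same
>= 1 bp rule to the strand-oriented [-1000, 0] and [0, 1000] windows;
half-open coordinates mean a read ending exactly at a window start does not
count, and a read straddling the anchor counts in both flanks.

## The synthetic generator

`ArrayModel` emulates the dyad-level structure the analyses assume.  For a
plus-strand anchor at position a, true downstream dyads sit at
`a + first_dyad_down + (k-1) * nrl_down` (k = 1..n_down) and the upstream
array is anchored at the 5' NDR edge, `a + ndr_offset - ndr_halfwidth -
(k-1) * nrl_up`, propagating away from the motif; minus-strand anchors
mirror the whole construction.  Each true nucleosome emits Poisson(depth)
dyads displaced by Gaussian jitter (per sampled dyad, so depth sharpens
phasogram peaks the way deeper MNase sampling of a positioned nucleosome
does); uniform background dyads are added genome-wide.  A `fixed` depth law
(exactly round(depth) dyads, for exact zero-noise constructions) and an
optional linearly position-dependent jitter (stress tests for phasing decay)
are provided.

Defaults are the measured CTCF geometry: `nrl = 186` bp, `ndr_offset = -41`,
`first_dyad_down = 105`, `n_per_side = 20`, jitter 15 bp, depth 5,
background 2e-4 dyads/bp.  `ndr_halfwidth` defaults to
`first_dyad_down - ndr_offset` (146), the unique value placing the NDR edges
symmetrically about its centre given the first downstream dyad — so the gap
centre equals `ndr_offset` for any parameter choice, including the
symmetric `ndr_offset = 0` case.

Anchor placement draws inter-anchor gaps as `min_spacing` (4 kb) plus a
Gamma(4, 150) excess.  The gap distribution must be smooth with sd larger
than one repeat: a hard minimum with exponential excess (the natural
sorted-uniform construction) leaves a sawtooth periodicity in cross-anchor
dyad distances that contaminates fine-grained peak scans.  Scores are
lognormal, the usual shape of ChIP peak heights.  Planted genomes are
i.i.d. background at a configurable GC fraction with motif consensus words
(reverse-complemented on minus) at chosen positions; flank reads are
Poisson per flank, placed uniformly and wholly inside the oriented
[-1000, 0] / [0, 1000] windows.

What the generator does **not** model: sequence-dependent nucleosome
energetics, MNase sequence bias, fragment-length distributions, phasing
decay with distance (constant jitter by default), chromatin-state
heterogeneity between sites, and real CTCF site density (anchors are placed
sparsely enough that neighbouring arrays rarely overlap windows).  Passing
recovery tests therefore demonstrates correctness of the estimators on data
satisfying the stated model, not robustness to every artefact of real
MNase-seq; conversely the interference diagnostic and density effects (see
below) reproduce genuinely data-driven failure modes.

## Numerical choices and degenerate inputs

- All coordinates are 0-based half-open (BED-native); fragment centres of
  even-length fragments round down.
- Integer histograms are smoothed in exact integer arithmetic before the
  final division, so equal-count plateaus stay exactly equal and the
  plateau tie rule (leftmost) is well defined in floating point.
- Unknown chromosomes in one track relative to another are kept; region
  queries against absent chromosomes return empty.
- Anchors with strand "." are treated as plus (logged).
- Profile bins at chromosome edges are excluded per anchor, not imputed.
- Reflection helpers (`DyadMap.reflected`, `reflect_anchors`) implement the
  exact reverse-complement coordinate transform used by the
  mirror-invariance tests; with odd motif lengths the reflected centre is
  exact, so strand-aware statistics are bit-identical under reflection.

## Known limitations

- At realistic site density the [100, 2000] window of one anchor can reach
  the neighbouring site's array; phasogram peaks are then a mixture, which
  is a property of the data, not the estimator.  The one-sided degeneracy
  checks (e.g. "upstream estimate absent when no upstream array exists")
  hold only for anchors spaced beyond twice the array extent.
- The sparse-histogram guard (one pair per region) is a heuristic; between
  roughly 1 and ~10 pairs per region, estimates are produced but noisy, and
  the significance filter alone is a weak guard there.
- The NDR argmin is reported at 1 bp resolution but its seed-to-seed spread
  at study conditions is ~±2 bp (asymmetric geometry) to ~±15 bp
  (symmetric, shallow-V geometry).
- TRAP affinities use a uniform background; dinucleotide backgrounds and
  p-value calibration of motif scores are out of scope, as are motif
  discovery, BAM parsing and bigWig output.

## Problem sizes

The shipped tests and the acceptance script run the full pipeline at 500
anchors on a 2.6 Mb synthetic chromosome (about 10^5 dyads, 10^6 phasogram
pairs per window set), which reproduces every stated recovery property; all
estimators are linear or n log n in the number of dyads and scale to
genome-size inputs via the same code paths.
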
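# Methods

## Coordinates and the segment-map algebra

All intervals are 0-based half-open internally; printed `chrom:start-end`
strings use the 1-based inclusive convention and are converted at I/O
(`parse_region`/`format_region`).  A rearranged genome is an ordered list
of oriented reference segments plus optional non-reference payload
(knock-in) segments.  Projection of a rearranged position through a
forward segment at offset *o* gives `ref.start + o`; through a reverse
segment, `ref.end − 1 − o`; payload positions are unmappable and any
contact pair touching them is dropped at projection.  This mirrors what a
reference-only short-read mapper does with mutant DNA, and it is the
mechanism by which duplication coverage doubles, inversions produce
bow-ties, and knock-ins lose contact mass.

Structural variants are declared, not hand-built: a tandem duplication
with breakpoints `(b1, b2)` yields segments `[0,b2)+, [b1,L)+` (direct,
head-to-tail); an inversion flips `[b1,b2)`; an insertion interposes a
payload segment.  Per-base reference copy number is the count of
non-payload segments covering the base; tests pin it against exhaustive
enumeration of every rearranged base.

In-silico digestion (`digest`) places the cut at the motif start (for
DpnII/GATC, before the G), scanning non-overlapping left-to-right; any
fixed convention works because all downstream arithmetic is
fragment-interval based.  The default restriction map of the model locus
is drawn as a Poisson process of cut sites with mean spacing 256 bp — the
expected GATC spacing under uniform base composition — so a 2 Mb sequence
never needs materializing; `digest` accepts either real sequence or
precomputed sites.

## The model locus

A 1.96 Mb capture region (the size of the study interval) holds two TADs
with the geometry of the Lbx1/Fgf8 locus: a ~350 kb centromeric TAD with
the *Lbx1* and *Btrc* model genes (*Lbx1* ~90 kb inside its centromeric
boundary) and a ~480 kb telomeric TAD with *Fbxw4*/*Fgf8*; the 40 kb AER
enhancer cluster sits in *Fbxw4* introns ~390 kb from *Lbx1* and ~120 kb
from *Fgf8*.  CTCF sites in convergent orientation anchor the corner loop
of each TAD and one larger loop joining the two TADs (the boundary-
to-boundary interaction).  Boundary insulation is per-boundary: the
centromeric boundary carries a single CTCF site and gets leakiness 0.5,
against the global default 0.3 of the divergent mid boundary — so when a
duplication copies it next to the neo-TAD, the ectopic enhancer→*Lbx1*
contacts cross a weak boundary, as at the real locus.

The named model SVs (breakpoints invented; the true coordinates are not
published and everything is configurable):

| name | kind | breakpoints | consequence |
|------|------|-------------|-------------|
| dup  | tandem duplication | 590–1,130 kb | neo-TAD; enhancer copy ~150 kb from the second *Lbx1* copy (vs ~390 kb in wild-type) |
| inv1 | inversion | 800–1,130 kb | enhancers reposition next to *Btrc*/*Lbx1*; *Fgf8* stranded |
| inv2 | inversion | 700–1,130 kb | *Btrc* carried into the *Fgf8* TAD; only *Lbx1* gains the enhancers |
| ki   | insertion | 690 kb, 2 kb payload | unmappable knock-in sequence |

## The contact model

Expected contacts on any genome (reference or rearranged) are

E[i,j] = λ · (|i−j|+1)^(−α) · t(i,j) · (1 + Σ loop bumps)

with bins of the sampling grid indexed by i, j; t(i,j) = `tad_boost` times
the product of the leakiness of every boundary between the bin centers
(reducing to `tad_boost · leakiness^k` for uniform leakiness); Gaussian
loop bumps of strength `loop_strength` and width `loop_width` at every
convergent CTCF pair (orientation honored, so an inversion that flips a
site changes the loop set); and λ fixed so the matrix totals `n_pairs`.
Defaults: α = 1.0, `tad_boost` = 3.0, `leakiness` = 0.3,
`loop_strength` = 2.0, `loop_width` = 20 kb, `n_pairs` = 5×10⁵ per
library.  For a rearranged genotype, the annotation (boundaries, CTCF and
therefore loops) is first carried through the segment map and the model is
built on the rearranged genome; neo-TADs and repositioned enhancers emerge
from the coordinate algebra rather than being painted on.

Pair sampling is multinomial over tile pairs with probability proportional
to expected weight; end positions are uniform within their tile and
mapping qualities follow a two-point distribution (60 with probability
0.9, else 3) so the MAPQ ≥ 30 filter has work to do.  `sample_pairs`
accepts any tiling, including the restriction fragments themselves (the
contract used in the tests).  The simulation pipeline evaluates the model
on a 2 kb sampling grid rather than per fragment pair: the model has no
structure below a few kb, and a fragment-pair weight matrix over ~7,700
DpnII fragments would be ~60 M entries for no gain in fidelity.  Fragment
indices are assigned from sampled positions afterwards, at full fragment
granularity.

## Normalization

`bin_pairs` accumulates symmetric counts at 5 kb (a pair adds 1 to (i,j)
and, off-diagonal, to (j,i)); the last bin may be short and marginals are
not length-corrected.  Bins whose raw marginal falls below 10% of the
median marginal are masked before balancing — a relative version of the
ad-hoc removal of a handful of low-coverage rows that such maps need —
and masked bins carry NaN in normalized outputs.  Mask growth is monotone:
the rule only ever removes bins.

Both normalizations are symmetric iterative proportional fitting on the
valid submatrix, differing only in the target marginal: uniform for
`kr_balance`, proportional to the copy-number track for `loic_normalize`
(`b ← b / sqrt(s / (cn·s̄))` per iteration).  The contract is the marginal
postcondition — row-sum coefficient of variation, or marginal-to-cn
proportionality, below `tol` (default 1e-6, max 1000 iterations) — not a
particular inner iteration; a Newton-based balancer would satisfy the same
contract.  Outputs are rescaled to preserve the raw total over valid bins,
making both maps and biases scale-comparable; on non-convergence the best
iterate is returned with the residual recorded in metadata and the bias
flagged, never silently.  With constant copy number, `loic_normalize`
reproduces `kr_balance` exactly (tested), which is the uniform-correction
limit.

The duplication copy-number track is 4 on bins overlapping the duplicated
interval and 2 elsewhere (diploid baseline).

## Subtraction maps

Per-sub-diagonal sums are taken over the full symmetric matrix (both
triangles; the convention is pinned by enumeration tests and cancels in
the joint factors since both maps share it).  An entry is excluded from
factor computation iff either of its bins overlaps an excluded interval by
≥ 1 bp or is masked; excluded entries are still multiplied by the diagonal
and global factors and appear in the output.  Diagonals with zero support
in a map are set to zero there; no non-finite values reach any output.
The exclusion applies to both the per-diagonal and the global 10⁶ factors.
Orientation is mutant − wild-type, so gains are positive; swapping the
arguments negates the map exactly.  Rendering clips at the 99th percentile
by default, with a symmetric diverging scale for signed maps.

With a large excluded interval the non-excluded bins form two blocks, and
intermediate diagonals can lose support entirely (they are then zeroed in
both maps).  At the default geometry — SVs of 330–540 kb inside a 1.96 Mb
map — every diagonal keeps support; configurations where an exclusion
covers most of the capture region will not, which is a limitation of the
per-diagonal matching itself.

## Virtual 4C

Order of operations is count → bin → smooth → scale, with the scaling sum
computed on smoothed values.  A pair qualifies when min(MAPQ) ≥ 30 and
exactly one end position (not fragment) lies in the viewpoint interval;
the distal end's fragment is incremented, except that fragments
overlapping the viewpoint itself never carry counts (this keeps the
conservation invariant Σ binned = total counted exact; with
fragment-aligned viewpoints the exception is vacuous).  Fragment counts
are spread onto the 1 kb grid proportionally to base overlap, smoothed
with a centered 5-bin mean whose edge windows shrink, and scaled by
10³ / S where S sums the smoothed values over bins overlapping the
enriched region minus bins overlapping the viewpoint ± 5 kb.  Bins
partially overlapping the enriched region contribute their full value to S
(bin-level membership); viewpoint bins are scaled, not zeroed —
suppressing them is a rendering concern.  The enriched region defaults to
the whole capture region, as no finer coordinates are published for it.
`integrate` weights partial bins by overlap fraction; `merge_replicates`
takes the per-bin mean of scaled profiles, which preserves the 10³
eligible-set sum by linearity.

## What the simulator does and does not show

The generator reproduces the features the analysis depends on: power-law
decay, TAD/boundary/loop structure, restriction-fragment granularity,
MAPQ mixtures, copy-number-driven coverage, and the reference-projection
artifacts of SVs.  It deliberately omits capture-efficiency bias along the
probe tiling, ligation-junction and duplicate-read artifacts, trans
contacts, cell-population heterogeneity, and sequence-level read
simulation.  Passing tests therefore demonstrate that the computations are
correct on data with known truth — not that real libraries are free of the
biases the simulator omits; on real data the normalizations themselves are
the defense against the first of these.

## Problem sizes and numerics

Default study conditions: 5×10⁵ pairs per library (10⁶ for the
decay-recovery check), 392 bins at 5 kb, ~7,700 fragments at mean spacing
256 bp, five seeds for the sign tests of the qualitative SV signatures.
The decay exponent is fitted by log-log OLS of per-diagonal mean counts at
bin distances 5–60, restricted to same-TAD bin pairs in the telomeric TAD
interior where the model's decay is a pure power law.  Balancing
tolerances are relative (1e-6 default); map I/O uses `repr` round-tripping
so raw counts survive exactly and normalized values to < 1e-12.  Ties and
degenerate inputs: zero-signal profiles and all-zero maps raise rather
than return NaN; empty diagonals stay zero; the truncated last bin is
handled by clipping bin ends to the region end throughout.
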
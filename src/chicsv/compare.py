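"""Pairwise subtraction maps with distance-decay-matched joint scaling.

Two normalized maps cannot be subtracted directly: library depth and the
distance-dependent contact decay differ between samples.  The procedure here
matches the two maps sub-diagonal by sub-diagonal — the values of each
sub-diagonal of a map are divided by that sub-diagonal's sum and multiplied
by the average of the two maps' sums — and then fixes each map's total to
10^6.  Bins overlapping the structural variant (the duplicated or inverted
interval) are excluded from every scaling-factor computation, because their
copy-number-driven signal would otherwise distort the decay matching; the
excluded entries are still scaled and kept in the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_map import BinnedContactMap, write_map
from .locus_sv import GenomicInterval

__all__ = [
    "DistanceScalingFactors",
    "SubtractionMap",
    "diagonal_sums",
    "joint_distance_scale",
    "subtract",
    "render_heatmap",
    "MAP_SCALE_TOTAL",
]

#: fixed total each jointly scaled map is brought to
MAP_SCALE_TOTAL = 1e6


@dataclass
class DistanceScalingFactors:
    """Per-sub-diagonal sums of both maps and their joint means."""

    sums_a: np.ndarray
    sums_b: np.ndarray
    excluded_bins: np.ndarray

    @property
    def joint_means(self) -> np.ndarray:
        return 0.5 * (self.sums_a + self.sums_b)


@dataclass
class SubtractionMap:
    """Signed difference map (minuend − subtrahend)."""

    region: GenomicInterval
    bin_size: int
    matrix: np.ndarray
    orientation: str  # e.g. "dup - wildtype"
    excluded: list = field(default_factory=list)
    clip_percentile: float = 99.0


def _good_bins(m: BinnedContactMap, exclude) -> np.ndarray:
    """Bins usable for scaling factors: valid and not overlapping exclusions."""
    return m.valid_mask & ~m.bins_overlapping(exclude)


def _finite(m: BinnedContactMap) -> np.ndarray:
    """Matrix with masked-bin NaNs replaced by 0 (masked bins carry no signal)."""
    return np.nan_to_num(m.matrix, nan=0.0)


def diagonal_sums(m: BinnedContactMap, exclude=()) -> np.ndarray:
    """Sum of each sub-diagonal d = |i-j| over non-excluded valid entries.

    Convention: sums run over the full symmetric matrix, i.e. every
    off-diagonal entry is counted in both triangles; any consistent
    convention cancels in the joint scaling since both maps share it.
    """
    good = _good_bins(m, exclude)
    M = _finite(m) * np.outer(good, good)
    n = m.n_bins
    sums = np.zeros(n)
    for d in range(n):
        s = np.trace(M, offset=d)
        sums[d] = s if d == 0 else 2.0 * s
    return sums


def joint_distance_scale(a: BinnedContactMap, b: BinnedContactMap,
                         exclude=()) -> tuple[BinnedContactMap, BinnedContactMap]:
    """Jointly rescale two maps across their sub-diagonals, then to a 10^6 total.

    Each entry of map X on sub-diagonal d is multiplied by m(d)/s_X(d),
    where s_X(d) is X's sub-diagonal sum over non-excluded valid entries and
    m(d) the average of the two maps' sums; entries on diagonals with
    s_X(d) = 0 are set to 0.  Each map is then multiplied by
    10^6 / (its total over non-excluded valid entries), so both outputs
    total exactly 10^6 there and have identical per-diagonal non-excluded
    sums.  Excluded entries are scaled like any others and remain in the
    output; they are only left out of the factor computations.
    """
    if (a.region != b.region) or (a.bin_size != b.bin_size):
        raise ValueError("maps are on different region/bin grids")
    sa = diagonal_sums(a, exclude)
    sb = diagonal_sums(b, exclude)
    if sa.sum() == 0 and sb.sum() == 0:
        raise ValueError("both maps are empty")
    m_d = 0.5 * (sa + sb)

    n = a.n_bins
    d_of = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])

    outs = []
    for m, s_x in ((a, sa), (b, sb)):
        with np.errstate(divide="ignore", invalid="ignore"):
            per_diag = np.where(s_x > 0, m_d / np.where(s_x > 0, s_x, 1.0), 0.0)
        X = _finite(m) * per_diag[d_of]
        good = _good_bins(m, exclude)
        total = X[np.outer(good, good)].sum()
        if total > 0:
            X = X * (MAP_SCALE_TOTAL / total)
        meta = (f"{m.metadata}; joint distance scaling vs partner; "
                f"global factor={MAP_SCALE_TOTAL / total if total > 0 else 0:.6g}")
        outs.append(BinnedContactMap(m.region, m.bin_size, X, m.valid_mask,
                                     "scaled", meta))
    return outs[0], outs[1]


def subtract(minuend: BinnedContactMap, subtrahend: BinnedContactMap,
             orientation: str = "minuend - subtrahend",
             excluded=()) -> SubtractionMap:
    """Entrywise difference of two jointly scaled maps.

    Swapping the arguments negates every entry exactly.
    """
    if (minuend.region != subtrahend.region
            or minuend.bin_size != subtrahend.bin_size):
        raise ValueError("maps are on different region/bin grids")
    diff = _finite(minuend) - _finite(subtrahend)
    return SubtractionMap(minuend.region, minuend.bin_size, diff,
                          orientation, list(excluded))


def block_mean(sm: SubtractionMap, rows: GenomicInterval,
               cols: GenomicInterval) -> float:
    """Mean of the subtraction map over the block rows x cols (symmetrized)."""
    starts = sm.region.start + sm.bin_size * np.arange(sm.matrix.shape[0])
    ends = np.minimum(starts + sm.bin_size, sm.region.end)
    r = (starts < rows.end) & (rows.start < ends)
    c = (starts < cols.end) & (cols.start < ends)
    block = np.concatenate([sm.matrix[np.ix_(r, c)].ravel(),
                            sm.matrix[np.ix_(c, r)].ravel()])
    return float(block.mean())


def render_heatmap(m, path, clip_percentile: float = 99.0,
                   cmap: str | None = None) -> float:
    """Render a contact or subtraction map as a heatmap image.

    Linear color scale with values clipped at the given percentile;
    subtraction maps get a diverging scale centered at 0 with symmetric
    clipping.  Returns the clip value used.
    """
    if not (50 < clip_percentile <= 100):
        raise ValueError("clip_percentile must be in (50, 100]")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    signed = isinstance(m, SubtractionMap)
    M = np.nan_to_num(np.asarray(m.matrix, dtype=float), nan=0.0)
    if M.size == 0:
        raise ValueError("empty map")
    if signed:
        clip = float(np.percentile(np.abs(M), clip_percentile))
        vmin, vmax = -clip, clip
        cmap = cmap or "bwr"
    else:
        clip = float(np.percentile(M, clip_percentile))
        vmin, vmax = 0.0, clip
        cmap = cmap or "Reds"
    if vmax == vmin:
        vmax = vmin + 1.0
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(np.clip(M, vmin, vmax), cmap=cmap, vmin=vmin, vmax=vmax,
              interpolation="nearest")
    ax.set_xlabel(f"{m.region.chrom} bins ({m.bin_size} bp)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return clip


def write_subtraction(sm: SubtractionMap, path) -> None:
    """Dense TSV export of a subtraction map (signed values)."""
    as_map = BinnedContactMap(sm.region, sm.bin_size, sm.matrix,
                              norm_state="scaled",
                              metadata=f"subtraction {sm.orientation}")
    write_map(as_map, path, format="tsv")
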
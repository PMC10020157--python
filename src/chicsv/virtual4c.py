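"""Virtual 4C: one-dimensional viewpoint interaction profiles from Hi-C pairs.

The pipeline is count -> bin -> smooth -> scale.  Contacts of a viewpoint
interval are counted per restriction fragment (a pair qualifies when it
passes the MAPQ filter and exactly one end lies in the viewpoint), the
fragment counts are spread onto a 1 kb grid proportionally to overlap,
smoothed with a centered 5 kb sliding mean, and finally scaled by
10^3 / (sum of counts within the enriched region), where the viewpoint
itself plus a +/- 5 kb margin is excluded from the scaling sum.  The
integrated signal over a fixed window (e.g. the 125 kb enhancer region)
then compares contact intensity across genotypes on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hic_sim import ContactPairSet
from .locus_sv import GenomicInterval, RestrictionMap

__all__ = [
    "Viewpoint",
    "FragmentCountProfile",
    "BinnedProfile",
    "Virtual4CProfile",
    "count_by_fragment",
    "bin_1kb",
    "smooth",
    "scale_profile",
    "integrate",
    "merge_replicates",
    "viewpoint_profile",
    "write_profile_bedgraph",
    "PROFILE_SCALE_TOTAL",
]

#: fixed sum of a scaled profile over the eligible enriched region
PROFILE_SCALE_TOTAL = 1e3


@dataclass(frozen=True)
class Viewpoint:
    interval: GenomicInterval
    name: str = ""


@dataclass
class FragmentCountProfile:
    """Per-restriction-fragment contact counts of one viewpoint."""

    counts: np.ndarray
    viewpoint: Viewpoint
    total_qualifying: int


@dataclass
class BinnedProfile:
    region: GenomicInterval
    grid_size: int
    values: np.ndarray
    stage: str  # binned | smoothed | scaled

    @property
    def bin_starts(self) -> np.ndarray:
        return self.region.start + self.grid_size * np.arange(len(self.values))

    @property
    def bin_ends(self) -> np.ndarray:
        return np.minimum(self.bin_starts + self.grid_size, self.region.end)


@dataclass
class Virtual4CProfile:
    profile: BinnedProfile  # stage "scaled"
    enriched_region: GenomicInterval
    viewpoint: Viewpoint
    margin: int
    scale_factor: float

    @property
    def values(self) -> np.ndarray:
        return self.profile.values


def count_by_fragment(pairs: ContactPairSet, vp: Viewpoint,
                      rm: RestrictionMap, mapq_min: int = 30) -> FragmentCountProfile:
    """Count viewpoint contacts per restriction fragment.

    A pair qualifies iff min(mapq) >= mapq_min and exactly one end position
    lies within the viewpoint interval (the in-viewpoint test is on the base
    position, not the fragment); the distal end's fragment is incremented.
    Fragments overlapping the viewpoint itself carry no counts, so a distal
    end landing in a viewpoint-overlapping fragment is not counted.
    """
    region = rm.region
    if not (vp.interval.start >= region.start and vp.interval.end <= region.end):
        raise ValueError("viewpoint outside the restriction-map region")
    in1 = (pairs.end1_pos >= vp.interval.start) & (pairs.end1_pos < vp.interval.end)
    in2 = (pairs.end2_pos >= vp.interval.start) & (pairs.end2_pos < vp.interval.end)
    inside = ((pairs.end1_pos >= region.start) & (pairs.end1_pos < region.end)
              & (pairs.end2_pos >= region.start) & (pairs.end2_pos < region.end))
    qualify = (pairs.min_mapq >= mapq_min) & (in1 ^ in2) & inside
    distal = np.where(in1[qualify], pairs.end2_pos[qualify],
                      pairs.end1_pos[qualify])
    frag = rm.fragment_index(distal)
    vp_frags = np.array([f.overlaps(vp.interval) for f in rm.fragments])
    keep = ~vp_frags[frag]
    counts = np.bincount(frag[keep], minlength=rm.n_fragments).astype(float)
    return FragmentCountProfile(counts, vp, int(keep.sum()))


def bin_1kb(fc: FragmentCountProfile, rm: RestrictionMap,
            grid_size: int = 1000) -> BinnedProfile:
    """Spread fragment counts onto a regular grid proportionally to overlap.

    A fragment with count c overlapping several grid bins contributes
    c * overlap_k / fragment_length to bin k, conserving the total exactly.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    region = rm.region
    n = -(-len(region) // grid_size)
    values = np.zeros(n)
    for f_idx in np.nonzero(fc.counts)[0]:
        frag = rm.fragments[f_idx]
        c = fc.counts[f_idx]
        k0 = (frag.start - region.start) // grid_size
        k1 = (frag.end - 1 - region.start) // grid_size
        for k in range(k0, k1 + 1):
            bin_lo = region.start + k * grid_size
            bin_hi = min(bin_lo + grid_size, region.end)
            overlap = min(frag.end, bin_hi) - max(frag.start, bin_lo)
            values[k] += c * overlap / len(frag)
    return BinnedProfile(region, grid_size, values, "binned")


def smooth(bp: BinnedProfile, window: int = 5000) -> BinnedProfile:
    """Centered sliding-window mean; edge windows shrink to the bins present."""
    if window < bp.grid_size:
        raise ValueError("window must be at least one grid bin")
    half = window // bp.grid_size // 2
    w = 2 * half + 1
    kernel = np.ones(w)
    num = np.convolve(bp.values, kernel, mode="same")
    den = np.convolve(np.ones_like(bp.values), kernel, mode="same")
    return BinnedProfile(bp.region, bp.grid_size, num / den, "smoothed")


def _eligible_bins(bp: BinnedProfile, enriched: GenomicInterval,
                   vp: Viewpoint, margin: int) -> np.ndarray:
    """Bins in the scaling sum: overlapping the enriched region but not the
    viewpoint expanded by the margin (bin-level membership, not prorated)."""
    starts, ends = bp.bin_starts, bp.bin_ends
    in_enriched = (starts < enriched.end) & (enriched.start < ends)
    vp_lo = vp.interval.start - margin
    vp_hi = vp.interval.end + margin
    near_vp = (starts < vp_hi) & (vp_lo < ends)
    return in_enriched & ~near_vp


def scale_profile(bp: BinnedProfile, enriched: GenomicInterval,
                  vp: Viewpoint, margin: int = 5000) -> Virtual4CProfile:
    """Scale a smoothed profile by 10^3 / (sum over the enriched region).

    The viewpoint and a +/- margin around it are excluded from the scaling
    sum; every bin (the viewpoint bins included) is then multiplied by the
    factor, so the scaled profile sums to exactly 10^3 over the eligible set.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    if not (enriched.start >= bp.region.start and enriched.end <= bp.region.end):
        raise ValueError("enriched region outside profile region")
    eligible = _eligible_bins(bp, enriched, vp, margin)
    S = float(bp.values[eligible].sum())
    if S == 0:
        raise ValueError("no signal in enriched region")
    factor = PROFILE_SCALE_TOTAL / S
    scaled = BinnedProfile(bp.region, bp.grid_size, bp.values * factor, "scaled")
    return Virtual4CProfile(scaled, enriched, vp, margin, factor)


def integrate(p: Virtual4CProfile, window: GenomicInterval) -> float:
    """Integrated signal: sum of scaled bin values over a window, with bins
    partially overlapping the window weighted by their overlap fraction."""
    bp = p.profile
    starts, ends = bp.bin_starts, bp.bin_ends
    overlap = np.minimum(ends, window.end) - np.maximum(starts, window.start)
    overlap = np.clip(overlap, 0, None)
    frac = overlap / (ends - starts)
    return float((bp.values * frac).sum())


def merge_replicates(profiles: list[Virtual4CProfile]) -> Virtual4CProfile:
    """Per-bin arithmetic mean of scaled replicate profiles.

    Since each replicate sums to 10^3 over the common eligible set, so does
    the merge.
    """
    if not profiles:
        raise ValueError("no profiles to merge")
    first = profiles[0]
    for p in profiles[1:]:
        if (p.profile.grid_size != first.profile.grid_size
                or p.profile.region != first.profile.region
                or p.viewpoint != first.viewpoint
                or p.enriched_region != first.enriched_region
                or p.margin != first.margin):
            raise ValueError("profiles differ in grid, viewpoint or enriched region")
    mean_vals = np.mean([p.values for p in profiles], axis=0)
    merged = BinnedProfile(first.profile.region, first.profile.grid_size,
                           mean_vals, "scaled")
    return Virtual4CProfile(merged, first.enriched_region, first.viewpoint,
                            first.margin,
                            float(np.mean([p.scale_factor for p in profiles])))


def viewpoint_profile(pairs: ContactPairSet, vp: Viewpoint, rm: RestrictionMap,
                      enriched: GenomicInterval | None = None,
                      mapq_min: int = 30, grid_size: int = 1000,
                      window: int = 5000, margin: int = 5000) -> Virtual4CProfile:
    """Full count -> bin -> smooth -> scale pipeline for one viewpoint.

    The enriched region defaults to the whole capture region.
    """
    fc = count_by_fragment(pairs, vp, rm, mapq_min)
    bp = smooth(bin_1kb(fc, rm, grid_size), window)
    return scale_profile(bp, enriched or rm.region, vp, margin)


def write_profile_bedgraph(p: Virtual4CProfile, path) -> None:
    bp = p.profile
    with open(path, "w") as fh:
        fh.write(f"track type=bedGraph name=v4c_{p.viewpoint.name or 'vp'}\n")
        for s, e, v in zip(bp.bin_starts, bp.bin_ends, bp.values):
            fh.write(f"{bp.region.chrom}\t{s}\t{e}\t{v:.6g}\n")
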
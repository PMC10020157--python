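"""Synthetic capture-Hi-C contact generator for a structural-variant locus.

The generative model is the standard minimal one: expected contacts are a
power-law distance decay modulated by TAD structure (a within-TAD boost,
attenuated per boundary crossed by a "leakiness" factor) and by loop bumps
anchored on convergent CTCF pairs.  Pairs are sampled from this expectation
on whichever genome — reference or rearranged — is being simulated, and
rearranged-genome pairs are then projected back onto reference coordinates
through the segment map, emulating what a reference-only mapper does with
reads from a mutant allele (duplications pile up, inversions flip, knock-in
payload is lost).

The expectation is discretized on a sampling grid (default 2 kb) and end
positions are drawn uniformly within their grid cell; restriction-fragment
indices are then assigned from positions.  ``sample_pairs`` itself accepts
any tiling, including the restriction fragments themselves, which is the
fragment-level contract used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .locus_sv import (
    GenomicInterval,
    LocusAnnotation,
    RearrangementSpec,
    RestrictionMap,
    SegmentMap,
    build_segment_map,
    digest,
    project_annotation,
)

__all__ = [
    "ContactModelParams",
    "ContactPairSet",
    "expected_map",
    "convergent_loops",
    "sample_pairs",
    "project_pairs",
    "project_restriction_map",
    "simulate_dataset",
    "fit_decay_exponent",
    "write_pairs",
    "read_pairs",
]


@dataclass(frozen=True)
class ContactModelParams:
    """Parameters of the expected-contact model and the pair sampler.

    loops: explicit list of (anchor1, anchor2, strength, width-in-bp)
    tuples, or None to derive one loop per convergent CTCF pair from the
    annotation at (loop_strength, loop_width).
    """

    alpha: float = 1.0
    tad_boost: float = 3.0
    leakiness: float = 0.3
    loops: tuple | None = None
    loop_strength: float = 2.0
    loop_width: int = 20_000
    n_pairs: int = 500_000
    seed: int = 0
    p_highq: float = 0.9
    mapq_high: int = 60
    mapq_low: int = 3

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tad_boost < 1:
            raise ValueError("tad_boost must be >= 1")
        if not (0 < self.leakiness <= 1):
            raise ValueError("leakiness must be in (0, 1]")
        if not (0 <= self.p_highq <= 1):
            raise ValueError("p_highq must be a probability")
        if self.mapq_high < 30 or self.mapq_low >= 30:
            raise ValueError("mapq_high must be >= 30 and mapq_low < 30")


@dataclass
class ContactPairSet:
    """Column-oriented set of paired contacts with mapping qualities."""

    end1_pos: np.ndarray
    end2_pos: np.ndarray
    end1_frag: np.ndarray
    end2_frag: np.ndarray
    mapq1: np.ndarray
    mapq2: np.ndarray
    genome_tag: str = "reference"
    seed: int | None = None

    def __post_init__(self) -> None:
        arrays = [np.asarray(a) for a in
                  (self.end1_pos, self.end2_pos, self.end1_frag,
                   self.end2_frag, self.mapq1, self.mapq2)]
        n = len(arrays[0])
        if any(len(a) != n for a in arrays):
            raise ValueError("column lengths differ")
        (self.end1_pos, self.end2_pos, self.end1_frag, self.end2_frag,
         self.mapq1, self.mapq2) = (a.astype(np.int64) for a in arrays)

    def __len__(self) -> int:
        return len(self.end1_pos)

    @property
    def min_mapq(self) -> np.ndarray:
        return np.minimum(self.mapq1, self.mapq2)


def convergent_loops(ann: LocusAnnotation, strength: float,
                     width: int) -> list[tuple[int, int, float, int]]:
    """One loop per convergent CTCF pair (+ site upstream of a - site).

    Orientation is honored: after an inversion flips a site's strand, the
    set of convergent pairs — and with it the loop anchors — changes.
    """
    loops = []
    for p in ann.ctcf_sites:
        for q in ann.ctcf_sites:
            if p.strand == "+" and q.strand == "-" and p.start < q.start:
                loops.append((p.start, q.start, strength, width))
    return loops


def expected_map(ann: LocusAnnotation, params: ContactModelParams,
                 bin_size: int) -> np.ndarray:
    """Dense symmetric expected-count matrix over the annotation region.

    E[i,j] = lambda * (|i-j|+1)^(-alpha) * t(i,j) * (1 + sum of loop bumps)
    with t = tad_boost * (product of leakiness over boundaries crossed
    between the bin centers; per-boundary overrides from the annotation,
    reducing to tad_boost * leakiness^k when uniform), loop bumps Gaussian
    in the two anchor coordinates, and lambda fixed so the matrix total
    equals n_pairs.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    L = len(ann.region)
    if L == 0:
        raise ValueError("empty annotation region")
    n = -(-L // bin_size)
    lo = ann.region.start + bin_size * np.arange(n)
    hi = np.minimum(lo + bin_size, ann.region.end)
    centers = (lo + hi) / 2.0

    idx = np.arange(n)
    decay = (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** (-params.alpha)

    # attenuation across boundaries: product of the leakiness of every
    # boundary between the two bin centers (leakiness^k when uniform)
    leaks = ann.boundary_leak_values(params.leakiness)
    crossings = np.searchsorted(ann.boundary_points, centers)
    cum_neglog = np.concatenate([[0.0], np.cumsum(-np.log(leaks))])
    C = cum_neglog[crossings]
    tad = params.tad_boost * np.exp(-np.abs(C[:, None] - C[None, :]))

    loops = params.loops
    if loops is None:
        loops = convergent_loops(ann, params.loop_strength, params.loop_width)
    bumps = np.zeros((n, n))
    for a1, a2, strength, width in loops:
        d1 = (centers - a1) / width
        d2 = (centers - a2) / width
        g1 = np.exp(-0.5 * d1 ** 2)
        g2 = np.exp(-0.5 * d2 ** 2)
        bumps += strength * (np.outer(g1, g2) + np.outer(g2, g1))

    E = decay * tad * (1.0 + bumps)
    E = 0.5 * (E + E.T)  # exact symmetry against fp noise
    return E * (params.n_pairs / E.sum())


def _grid_tiles(region: GenomicInterval, bin_size: int) -> list[GenomicInterval]:
    edges = list(range(region.start, region.end, bin_size)) + [region.end]
    return [GenomicInterval(region.chrom, a, b) for a, b in zip(edges, edges[1:])]


def sample_pairs(weights: np.ndarray, rm: RestrictionMap,
                 params: ContactModelParams,
                 tiles: Sequence[GenomicInterval] | None = None,
                 genome_tag: str = "reference") -> ContactPairSet:
    """Draw n_pairs contacts with tile-pair probability proportional to weight.

    ``tiles`` defaults to the restriction fragments of ``rm`` (the
    fragment-level contract); end positions are uniform within their tile and
    fragment indices are assigned from positions under ``rm``.  Mapping
    qualities follow a two-point distribution (mapq_high with probability
    p_highq, else mapq_low) so the downstream MAPQ filter is exercised.
    """
    if tiles is None:
        tiles = rm.fragments
    W = np.asarray(weights, dtype=float)
    if W.shape != (len(tiles), len(tiles)):
        raise ValueError(f"weights shape {W.shape} does not match {len(tiles)} tiles")
    if np.any(W < 0):
        raise ValueError("weights must be nonnegative")
    total = W.sum()
    if total <= 0:
        raise ValueError("zero total weight")

    rng = np.random.default_rng(params.seed)
    counts = rng.multinomial(params.n_pairs, (W / total).ravel())
    flat = np.repeat(np.arange(W.size), counts)
    i, j = np.divmod(flat, W.shape[1])

    starts = np.asarray([t.start for t in tiles])
    lens = np.asarray([len(t) for t in tiles])
    p1 = starts[i] + rng.integers(0, lens[i])
    p2 = starts[j] + rng.integers(0, lens[j])
    n = len(p1)
    mq = np.where(rng.random((2, n)) < params.p_highq,
                  params.mapq_high, params.mapq_low)
    return ContactPairSet(p1, p2, rm.fragment_index(p1), rm.fragment_index(p2),
                          mq[0], mq[1], genome_tag=genome_tag, seed=params.seed)


def project_restriction_map(rm_ref: RestrictionMap,
                            sm: SegmentMap) -> RestrictionMap:
    """Carry reference cut sites through a segment map onto the rearranged genome.

    Segment junctions also become fragment ends (breakpoints interrupt the
    original fragments).  Payload segments carry no internal cuts.
    """
    region = GenomicInterval("rearranged", 0, sm.rearranged_length)
    cuts: set[int] = set()
    offset = 0
    for seg in sm.segments:
        if offset > 0:
            cuts.add(offset)
        if not seg.is_payload:
            inside = rm_ref.cut_positions[
                (rm_ref.cut_positions > seg.ref.start)
                & (rm_ref.cut_positions < seg.ref.end)]
            if seg.orientation == "forward":
                cuts.update(int(c) - seg.ref.start + offset for c in inside)
            else:
                cuts.update(seg.ref.end - int(c) + offset for c in inside)
        offset += len(seg)
    good = sorted(c for c in cuts if 0 < c < sm.rearranged_length)
    return digest(good, "GATC", region)


def project_pairs(sm: SegmentMap, pairs: ContactPairSet,
                  rm_ref: RestrictionMap) -> ContactPairSet:
    """Map rearranged-genome pairs onto the reference through the segment map.

    Pairs with either end inside knock-in payload are dropped (unmappable);
    fragment indices are re-assigned under the reference restriction map.
    Orientation flips change nothing beyond the position mapping itself.
    """
    if pairs.genome_tag == "reference":
        raise ValueError("pairs are already on reference coordinates")
    r1, _ = sm.map_positions(pairs.end1_pos)
    r2, _ = sm.map_positions(pairs.end2_pos)
    keep = (r1 >= 0) & (r2 >= 0)
    r1, r2 = r1[keep], r2[keep]
    return ContactPairSet(
        r1, r2, rm_ref.fragment_index(r1), rm_ref.fragment_index(r2),
        pairs.mapq1[keep], pairs.mapq2[keep],
        genome_tag="reference", seed=pairs.seed)


def simulate_dataset(ann: LocusAnnotation, rm: RestrictionMap,
                     params: ContactModelParams,
                     sv: RearrangementSpec | None = None,
                     sv_name: str = "wildtype",
                     sampling_bin: int = 2_000) -> dict:
    """End-to-end simulation of one genotype, projected to reference coordinates.

    For a structural variant, the annotation (boundaries, CTCF sites and so
    their loops), the restriction map and the contact model all live on the
    rearranged genome; only afterwards are the sampled pairs projected back.
    That ordering is what makes neo-TADs, bow-ties and enhancer repositioning
    emerge from the coordinate algebra rather than being painted on.

    Returns a dict with the reference-coordinate ``pairs``, the ``segment_map``,
    the rearranged-genome ``annotation`` and ``expected`` matrix, and the
    number of payload-dropped pairs.
    """
    if sv is None:
        sm = SegmentMap.identity(len(ann.region), ann.region.chrom,
                                 ann.region.start)
        ann_g, rm_g = ann, rm
    else:
        sm = build_segment_map(len(ann.region), sv, ann.region.chrom)
        ann_g = project_annotation(ann, sm, chrom=ann.region.chrom)
        rm_g = project_restriction_map(rm, sm)

    E = expected_map(ann_g, params, sampling_bin)
    tiles = _grid_tiles(ann_g.region, sampling_bin)
    raw = sample_pairs(E, rm_g, params, tiles=tiles,
                       genome_tag=f"rearranged:{sv_name}" if sv else "reference")
    if sv is None:
        pairs = raw
        n_dropped = 0
    else:
        pairs = project_pairs(sm, raw, rm)
        n_dropped = len(raw) - len(pairs)
    return {
        "pairs": pairs,
        "segment_map": sm,
        "annotation": ann_g,
        "expected": E,
        "n_dropped": n_dropped,
        "sv_name": sv_name,
    }


def fit_decay_exponent(matrix: np.ndarray, d_min: int = 5, d_max: int = 80,
                       pair_mask: np.ndarray | None = None) -> float:
    """Distance-decay exponent by log-log OLS on per-diagonal mean counts.

    ``pair_mask`` restricts the averaged entries (e.g. to same-TAD bin pairs,
    where the model's decay is a pure power law); the returned value is the
    positive exponent alpha.
    """
    n = matrix.shape[0]
    ds, means = [], []
    for d in range(d_min, min(d_max, n - 1) + 1):
        vals = np.diagonal(matrix, d)
        if pair_mask is not None:
            sel = np.diagonal(pair_mask, d)
            vals = vals[sel]
        if vals.size and vals.mean() > 0:
            ds.append(d + 1.0)
            means.append(vals.mean())
    if len(ds) < 3:
        raise ValueError("too few informative diagonals for a decay fit")
    slope = np.polyfit(np.log(ds), np.log(means), 1)[0]
    return float(-slope)


# ---------------------------------------------------------------------------
# pairs text format


def write_pairs(pairs: ContactPairSet, path) -> None:
    """Tab-separated pairs: end1, end2, frag1, frag2, mapq1, mapq2."""
    with open(path, "w") as fh:
        fh.write(f"# genome_tag={pairs.genome_tag} seed={pairs.seed}\n")
        for row in zip(pairs.end1_pos, pairs.end2_pos, pairs.end1_frag,
                       pairs.end2_frag, pairs.mapq1, pairs.mapq2):
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def read_pairs(path) -> ContactPairSet:
    tag, seed = "reference", None
    cols: list[list[int]] = [[], [], [], [], [], []]
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("genome_tag="):
                        tag = tok.split("=", 1)[1]
                    elif tok.startswith("seed="):
                        s = tok.split("=", 1)[1]
                        seed = None if s == "None" else int(s)
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{ln}: expected 6 columns")
            for c, v in zip(cols, parts):
                c.append(int(v))
    return ContactPairSet(*[np.asarray(c, dtype=np.int64) for c in cols],
                          genome_tag=tag, seed=seed)
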
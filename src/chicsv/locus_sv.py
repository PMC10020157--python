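"""Locus model and structural-variant coordinate algebra.

Coordinates are 0-based half-open throughout (BED convention); 1-based
inclusive strings such as ``chr19:44,440,001-46,400,000`` are converted at
the I/O boundary only.

A rearranged genome (tandem duplication, inversion, deletion, knock-in
insertion) is represented as a :class:`SegmentMap`: an ordered list of
oriented reference segments, optionally interleaved with non-reference
payload segments.  Mapping a rearranged-genome position back to reference
coordinates through the segment map is the in-silico analogue of aligning
reads from a mutant allele against the reference assembly — duplicated
sequence piles up on its single reference copy, inverted sequence flips
orientation, and knock-in payload is unmappable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "LocusAnnotation",
    "RestrictionMap",
    "Segment",
    "SegmentMap",
    "RearrangementSpec",
    "digest",
    "poisson_cut_sites",
    "build_segment_map",
    "map_to_reference",
    "copy_number_profile",
    "read_bed",
    "write_bed",
    "parse_region",
    "format_region",
]

PAYLOAD = "payload"  # sentinel chrom label for non-reference (knock-in) segments


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be '+', '-' or '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset,
                               self.strand, self.name)


@dataclass
class LocusAnnotation:
    """Features of the model locus.

    ``boundaries`` are TAD-boundary intervals; their midpoints act as the
    insulation points of the contact model.  CTCF sites are 1 bp stranded
    intervals; convergent (+ upstream, - downstream) pairs anchor loops.
    """

    region: GenomicInterval
    genes: list[GenomicInterval] = field(default_factory=list)
    ctcf_sites: list[GenomicInterval] = field(default_factory=list)
    boundaries: list[GenomicInterval] = field(default_factory=list)
    enhancers: list[GenomicInterval] = field(default_factory=list)
    #: per-boundary leakiness overrides by boundary name; boundaries not
    #: listed use the contact model's global leakiness (a boundary with fewer
    #: CTCF sites insulates less, i.e. has a larger leakiness value)
    boundary_leakiness: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for feat in (*self.genes, *self.ctcf_sites, *self.boundaries, *self.enhancers):
            if feat.start < self.region.start or feat.end > self.region.end:
                raise ValueError(f"feature {feat} outside region {self.region}")
        for site in self.ctcf_sites:
            if site.strand not in ("+", "-"):
                raise ValueError("CTCF sites must be stranded")

    @property
    def boundary_points(self) -> np.ndarray:
        """Boundary midpoints, sorted — the insulation points."""
        mids = sorted((b.start + b.end) // 2 for b in self.boundaries)
        return np.asarray(mids, dtype=np.int64)

    def boundary_leak_values(self, default: float) -> np.ndarray:
        """Leakiness per boundary, ordered like :attr:`boundary_points`."""
        ordered = sorted(self.boundaries, key=lambda b: (b.start + b.end) // 2)
        return np.asarray([self.boundary_leakiness.get(b.name, default)
                           for b in ordered])

    def feature(self, name: str) -> GenomicInterval:
        for feat in (*self.genes, *self.enhancers, *self.boundaries):
            if feat.name == name:
                return feat
        raise KeyError(name)


@dataclass
class RestrictionMap:
    """In-silico digestion of a region: cut positions and the fragment tiling."""

    region: GenomicInterval
    cut_positions: np.ndarray
    fragments: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.cut_positions = np.asarray(self.cut_positions, dtype=np.int64)
        if np.any(np.diff(self.cut_positions) <= 0):
            raise ValueError("cut positions must be strictly increasing")
        if self.cut_positions.size and (
            self.cut_positions[0] <= self.region.start
            or self.cut_positions[-1] >= self.region.end
        ):
            raise ValueError("cut positions must be interior to the region")
        prev = self.region.start
        for frag in self.fragments:
            if frag.start != prev:
                raise ValueError("fragments must tile the region without gaps")
            prev = frag.end
        if prev != self.region.end:
            raise ValueError("fragments must end at the region end")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def edges(self) -> np.ndarray:
        """Fragment boundary positions, length n_fragments + 1."""
        return np.concatenate(
            [[self.region.start], self.cut_positions, [self.region.end]]
        )

    def fragment_index(self, pos) -> np.ndarray:
        """Fragment index containing each base position (vectorized)."""
        pos = np.asarray(pos, dtype=np.int64)
        if np.any(pos < self.region.start) or np.any(pos >= self.region.end):
            raise ValueError("position outside region")
        return np.searchsorted(self.cut_positions, pos, side="right")


@dataclass(frozen=True)
class Segment:
    """One oriented piece of a rearranged genome."""

    ref: GenomicInterval
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def is_payload(self) -> bool:
        return self.ref.chrom == PAYLOAD

    def __len__(self) -> int:
        return len(self.ref)


@dataclass
class SegmentMap:
    """Piecewise-oriented mapping from a rearranged genome to the reference."""

    segments: list[Segment]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("segment list must be non-empty")
        self._starts = np.cumsum([0] + [len(s) for s in self.segments])

    @property
    def rearranged_length(self) -> int:
        return int(self._starts[-1])

    @property
    def payload_length(self) -> int:
        return sum(len(s) for s in self.segments if s.is_payload)

    @classmethod
    def identity(cls, length: int, chrom: str = "chrS", origin: int = 0) -> "SegmentMap":
        return cls([Segment(GenomicInterval(chrom, origin, origin + length))])

    def segment_at(self, pos: int) -> tuple[int, int]:
        """(segment index, offset within segment) for a rearranged position."""
        if not (0 <= pos < self.rearranged_length):
            raise ValueError(f"position {pos} outside rearranged genome "
                             f"[0, {self.rearranged_length})")
        idx = int(np.searchsorted(self._starts, pos, side="right")) - 1
        return idx, pos - int(self._starts[idx])

    def map_positions(self, pos) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized projection of rearranged positions onto the reference.

        Returns (reference positions, forward flags); payload positions get
        reference position -1.
        """
        pos = np.asarray(pos, dtype=np.int64)
        if np.any(pos < 0) or np.any(pos >= self.rearranged_length):
            raise ValueError("position outside rearranged genome")
        idx = np.searchsorted(self._starts, pos, side="right") - 1
        off = pos - self._starts[idx]
        ref = np.empty_like(pos)
        fwd = np.ones(pos.shape, dtype=bool)
        for i, seg in enumerate(self.segments):
            sel = idx == i
            if not np.any(sel):
                continue
            if seg.is_payload:
                ref[sel] = -1
            elif seg.orientation == "forward":
                ref[sel] = seg.ref.start + off[sel]
            else:
                ref[sel] = seg.ref.end - 1 - off[sel]
                fwd[sel] = False
        return ref, fwd

    def map_point_forward(self, ref_pos: int) -> list[int]:
        """All rearranged positions a reference base maps to (0, 1 or 2)."""
        hits = []
        for i, seg in enumerate(self.segments):
            if seg.is_payload or not seg.ref.contains(ref_pos):
                continue
            off = (ref_pos - seg.ref.start if seg.orientation == "forward"
                   else seg.ref.end - 1 - ref_pos)
            hits.append(int(self._starts[i]) + off)
        return hits


@dataclass(frozen=True)
class RearrangementSpec:
    """Declarative description of a single structural variant."""

    kind: str  # tandem_duplication | inversion | deletion | insertion
    breakpoints: tuple[int, ...]
    payload_length: int = 0

    KINDS = ("tandem_duplication", "inversion", "deletion", "insertion")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown SV kind {self.kind!r}")
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise ValueError("breakpoints must be sorted")
        if self.kind == "insertion":
            if len(self.breakpoints) != 1:
                raise ValueError("insertion takes exactly one breakpoint")
            if self.payload_length <= 0:
                raise ValueError("insertion requires payload_length > 0")
        else:
            if len(self.breakpoints) != 2:
                raise ValueError(f"{self.kind} takes exactly two breakpoints")
            if self.breakpoints[0] == self.breakpoints[1]:
                raise ValueError("zero-length structural variant")
            if self.payload_length:
                raise ValueError("payload_length only valid for insertions")


# ---------------------------------------------------------------------------
# operations


def digest(sequence_or_sites, motif: str, region: GenomicInterval) -> RestrictionMap:
    """In-silico restriction digest of ``region``.

    Accepts either the DNA sequence of the region (cuts placed at each motif
    start, non-overlapping left-to-right scan) or a precomputed list of cut
    positions in region coordinates.  For DpnII the motif is GATC and the
    blunt-cut convention (cut before the G) makes the motif start the cut
    site.
    """
    if not motif:
        raise ValueError("empty motif")
    if re.search("[^ACGT]", motif.upper()):
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    if isinstance(sequence_or_sites, str):
        seq = sequence_or_sites.upper()
        if len(seq) != len(region):
            raise ValueError("sequence length must equal region length")
        cuts = []
        i = seq.find(motif)
        while i != -1:
            cut = region.start + i
            if region.start < cut < region.end:
                cuts.append(cut)
            i = seq.find(motif, i + len(motif))  # non-overlapping scan
    else:
        cuts = sorted(int(c) for c in sequence_or_sites
                      if region.start < c < region.end)
    edges = [region.start, *cuts, region.end]
    frags = [GenomicInterval(region.chrom, a, b) for a, b in zip(edges, edges[1:])]
    return RestrictionMap(region, np.asarray(cuts, dtype=np.int64), frags)


def poisson_cut_sites(region: GenomicInterval, mean_spacing: float,
                      seed: int) -> np.ndarray:
    """Seed-deterministic cut sites as a Poisson process along the region.

    256 bp is the expected GATC spacing under uniform base composition, so
    ``mean_spacing=256`` emulates a DpnII digest of the model locus without
    materializing sequence.
    """
    rng = np.random.default_rng(seed)
    n_expected = int(len(region) / mean_spacing * 1.5) + 10
    gaps = rng.exponential(mean_spacing, size=n_expected)
    pos = region.start + np.cumsum(gaps)
    pos = np.unique(pos.astype(np.int64))
    return pos[(pos > region.start) & (pos < region.end - 1)]


def build_segment_map(reference_length: int, spec: RearrangementSpec,
                      chrom: str = "chrS") -> SegmentMap:
    """Segment map of the rearranged genome implied by a structural variant.

    Tandem duplications are direct (head-to-tail): the rearranged genome is
    ``[0,b2) + [b1,L)`` so the second copy immediately follows the first.
    Knock-in payload becomes a non-reference segment that projects nowhere.
    """
    L = reference_length
    for b in spec.breakpoints:
        if not (0 <= b <= L):
            raise ValueError(f"breakpoint {b} outside [0, {L}]")
    ivl = lambda a, b: GenomicInterval(chrom, a, b)
    if spec.kind == "tandem_duplication":
        b1, b2 = spec.breakpoints
        segs = [Segment(ivl(0, b2)), Segment(ivl(b1, L))]
    elif spec.kind == "inversion":
        b1, b2 = spec.breakpoints
        segs = []
        if b1 > 0:
            segs.append(Segment(ivl(0, b1)))
        segs.append(Segment(ivl(b1, b2), "reverse"))
        if b2 < L:
            segs.append(Segment(ivl(b2, L)))
    elif spec.kind == "deletion":
        b1, b2 = spec.breakpoints
        segs = []
        if b1 > 0:
            segs.append(Segment(ivl(0, b1)))
        if b2 < L:
            segs.append(Segment(ivl(b2, L)))
        if not segs:
            raise ValueError("deletion removes the whole genome")
    else:  # insertion
        (b,) = spec.breakpoints
        payload = Segment(GenomicInterval(PAYLOAD, 0, spec.payload_length))
        segs = []
        if b > 0:
            segs.append(Segment(ivl(0, b)))
        segs.append(payload)
        if b < L:
            segs.append(Segment(ivl(b, L)))
    return SegmentMap(segs)


def map_to_reference(sm: SegmentMap, pos: int):
    """Project one rearranged-genome position onto the reference.

    Returns ``(reference position, orientation)`` with orientation
    ``"forward"`` or ``"reverse"``, or the string ``"payload"`` for
    positions inside knock-in sequence (unmappable against the reference).
    """
    idx, off = sm.segment_at(pos)
    seg = sm.segments[idx]
    if seg.is_payload:
        return PAYLOAD
    if seg.orientation == "forward":
        return seg.ref.start + off, "forward"
    return seg.ref.end - 1 - off, "reverse"


def copy_number_profile(sm: SegmentMap, reference_length: int) -> np.ndarray:
    """Per-base reference copy number implied by a segment map."""
    cn = np.zeros(reference_length, dtype=np.int64)
    for seg in sm.segments:
        if not seg.is_payload:
            cn[seg.ref.start:seg.ref.end] += 1
    return cn


def project_annotation(ann: LocusAnnotation, sm: SegmentMap,
                       chrom: str = "chrS") -> LocusAnnotation:
    """Carry locus features through a segment map onto the rearranged genome.

    Point-like features (CTCF sites, boundary midpoints) move with their
    segment; a feature inside a duplicated interval appears twice, one
    inside a deletion disappears, and one inside an inverted segment flips
    strand.  This is what lets enhancer repositioning and boundary reshuffling
    emerge from the coordinate algebra instead of being re-annotated by hand.
    Interval features are carried by their midpoint and retain their length
    (clipped to the rearranged genome); features spanning a breakpoint are
    carried piecewise-by-midpoint, adequate for the model's point-like usage.
    """
    L_new = sm.rearranged_length
    region = GenomicInterval(chrom, 0, L_new)

    def carry(feats: Iterable[GenomicInterval]) -> list[GenomicInterval]:
        out = []
        for f in feats:
            mid = (f.start + f.end) // 2
            half = len(f) // 2
            for i, seg in enumerate(sm.segments):
                if seg.is_payload or not seg.ref.contains(mid):
                    continue
                if seg.orientation == "forward":
                    new_mid = int(sm._starts[i]) + (mid - seg.ref.start)
                    strand = f.strand
                else:
                    new_mid = int(sm._starts[i]) + (seg.ref.end - 1 - mid)
                    strand = {"+": "-", "-": "+", ".": "."}[f.strand]
                start = max(0, new_mid - half)
                end = min(L_new, max(start + 1, new_mid + max(1, len(f) - half)))
                out.append(GenomicInterval(chrom, start, end, strand, f.name))
        return sorted(out, key=lambda g: g.start)

    return LocusAnnotation(
        region=region,
        genes=carry(ann.genes),
        ctcf_sites=carry(ann.ctcf_sites),
        boundaries=carry(ann.boundaries),
        enhancers=carry(ann.enhancers),
        boundary_leakiness=dict(ann.boundary_leakiness),
    )


def model_locus(chrom: str = "chrS") -> LocusAnnotation:
    """Default two-TAD model locus on a 1.96 Mb capture region.

    Architecture mirrors the Lbx1/Fgf8 locus geometry: a ~350 kb centromeric
    TAD holding the Lbx1/Btrc model genes (Lbx1 ~90 kb inside its
    centromeric boundary) and a ~480 kb telomeric TAD holding Fbxw4/Fgf8,
    separated by a strong divergent-CTCF boundary; the 40 kb AER-enhancer
    cluster sits inside the Fbxw4 model gene ~390 kb from Lbx1 and ~120 kb
    from Fgf8, with one extra enhancer close to Fgf8.  Convergent CTCF
    pairs (+ then -) define the corner loop of each TAD and the larger loop
    joining the two TADs.  The centromeric boundary carries a single CTCF
    site and is leakier than the divergent mid boundary — when a tandem
    duplication copies it next to the neo-TAD, ectopic enhancer contacts
    cross a weak boundary, as they do at the real locus.  All coordinates
    are invented model coordinates on one synthetic chromosome.
    """
    iv = lambda a, b, s=".", n="": GenomicInterval(chrom, a, b, s, n)
    return LocusAnnotation(
        region=iv(0, 1_960_000),
        genes=[
            iv(680_000, 686_000, "+", "Lbx1"),
            iv(730_000, 790_000, "-", "Btrc"),
            iv(1_040_000, 1_100_000, "-", "Fbxw4"),
            iv(1_190_000, 1_196_000, "+", "Fgf8"),
        ],
        ctcf_sites=[
            iv(605_000, 605_001, "+", "ctcf_cen"),
            iv(945_000, 945_001, "-", "ctcf_mid_cen"),
            iv(955_000, 955_001, "+", "ctcf_mid_tel"),
            iv(1_425_000, 1_425_001, "-", "ctcf_tel"),
        ],
        boundaries=[
            iv(593_000, 607_000, ".", "boundary_cen"),
            iv(943_000, 957_000, ".", "boundary_mid"),
            iv(1_423_000, 1_437_000, ".", "boundary_tel"),
        ],
        enhancers=[
            iv(1_050_000, 1_090_000, ".", "aer_enhancers"),
            iv(1_160_000, 1_162_000, ".", "enh80"),
        ],
        boundary_leakiness={"boundary_cen": 0.5},
    )


#: Model structural variants at the default locus (invented breakpoints; the
#: true mouse coordinates are not printed and are configurable in any case).
#: dup copies from just centromeric of the Lbx1-TAD boundary to between the
#: AER enhancer cluster and Fgf8 (Fgf8 itself not duplicated) — the second
#: copy's Lbx1 then sits ~150 kb from the first copy's enhancers, behind the
#: weak copied boundary (the neo-TAD configuration).  inv1 inverts from
#: between Btrc and the mid boundary to the same telomeric breakpoint,
#: repositioning the enhancers next to Btrc/Lbx1 and stranding Fgf8; inv2
#: starts between Lbx1 and Btrc, taking Btrc into the Fgf8 TAD so only Lbx1
#: gains the enhancers; ki inserts a 2 kb non-reference payload next to Lbx1.
MODEL_SVS: dict[str, RearrangementSpec] = {
    "dup": RearrangementSpec("tandem_duplication", (590_000, 1_130_000)),
    "inv1": RearrangementSpec("inversion", (800_000, 1_130_000)),
    "inv2": RearrangementSpec("inversion", (700_000, 1_130_000)),
    "ki": RearrangementSpec("insertion", (690_000,), payload_length=2_000),
}


# ---------------------------------------------------------------------------
# I/O


def parse_region(text: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` printed 1-based inclusive into 0-based half-open."""
    m = re.fullmatch(r"([^:]+):([\d,]+)-([\d,]+)", text.strip())
    if not m:
        raise ValueError(f"cannot parse region {text!r}")
    start = int(m.group(2).replace(",", "")) - 1
    end = int(m.group(3).replace(",", ""))
    return GenomicInterval(m.group(1), start, end)


def format_region(iv: GenomicInterval) -> str:
    """Render an interval as the printed 1-based inclusive convention."""
    return f"{iv.chrom}:{iv.start + 1:,}-{iv.end:,}"


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file (0-based half-open; name col 4, strand col 6)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            name = cols[3] if len(cols) > 3 else ""
            strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
            out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2]),
                                       strand, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t"
                     f"{iv.strand if iv.strand != '.' else '.'}\n")
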
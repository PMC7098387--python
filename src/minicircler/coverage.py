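"""Coverage profiling and control-region boundary detection.

On a minicircle contig the conserved control region recruits reads from
every circle in the genome while coding sequence recruits only its own
circle's reads, so the per-base depth profile is a large step function
whose high/low ratio estimates the number of circles sharing the
conserved core.  Segmentation is deliberately simple: smooth, split at
the geometric mean of the two depth modes, merge sub-scale segments,
then sharpen each boundary against the unsmoothed profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Placement, best_per_read
from .containers import Contig


class BoundaryError(ValueError):
    pass


@dataclass
class CoverageProfile:
    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if np.any(self.depth < 0):
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class Segment:
    start: int
    end: int
    mean_depth: float
    label: str  # "high" | "low"


@dataclass
class SegmentedProfile:
    contig_id: str
    segments: list[Segment]
    boundaries: list[int] = field(default_factory=list)
    ratio: float = 1.0


def profile_coverage(placements: list[Placement], contig: Contig | int,
                     contig_id: str = "") -> CoverageProfile:
    """Per-base depth from the best placement of each mate (overhangs and
    soft-clipped tails excluded)."""
    if isinstance(contig, Contig):
        n, cid = len(contig), contig.id
    else:
        n, cid = int(contig), contig_id
    depth = np.zeros(n)
    for p in best_per_read(placements).values():
        depth[p.t_start : p.t_end] += 1
    return CoverageProfile(cid, depth)


def _moving_mean(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x.astype(float)
    kernel = np.ones(w)
    return np.convolve(x, kernel, "same") / np.convolve(np.ones_like(x), kernel, "same")


def _two_means(values: np.ndarray) -> tuple[float, float]:
    """Deterministic 1-D 2-means estimate of the two depth modes."""
    # the high mode can occupy well under 10% of the contig (a ~200 nt
    # conserved core on a multi-kb circle), so seed the high centre at the
    # maximum rather than an upper percentile
    lo, hi = float(np.percentile(values, 10.0)), float(values.max())
    if hi <= lo:
        return lo, hi
    for _ in range(100):
        split = (lo + hi) / 2.0
        low_vals, high_vals = values[values < split], values[values >= split]
        if len(low_vals) == 0 or len(high_vals) == 0:
            break
        new_lo, new_hi = float(low_vals.mean()), float(high_vals.mean())
        if (new_lo, new_hi) == (lo, hi):
            break
        lo, hi = new_lo, new_hi
    return lo, hi


def _labels_to_segments(labels: np.ndarray) -> list[tuple[int, int, bool]]:
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, bool(labels[start])))
            start = i
    return out


def segment_profile(profile: CoverageProfile, smooth_nt: int = 101,
                    min_seg_nt: int = 150) -> SegmentedProfile:
    depth = profile.depth
    n = len(depth)
    if n < 2 * min_seg_nt:
        raise ValueError(f"contig of length {n} too short to segment")
    smoothed = _moving_mean(depth, smooth_nt)
    lo, hi = _two_means(smoothed)
    if lo <= 0 or hi < 2.0 * lo:
        seg = Segment(0, n, float(depth.mean()), "low")
        return SegmentedProfile(profile.contig_id, [seg], [], 1.0)
    threshold = float(np.sqrt(lo * hi))
    labels = smoothed >= threshold

    # absorb sub-scale segments into their neighbours
    while True:
        segs = _labels_to_segments(labels)
        if len(segs) <= 1:
            break
        short = [s for s in segs if s[1] - s[0] < min_seg_nt]
        if not short:
            break
        s0, s1, lab = min(short, key=lambda s: (s[1] - s[0], s[0]))
        labels[s0:s1] = not lab

    segs = _labels_to_segments(labels)
    boundaries = [s for s, _e, _l in segs[1:]]
    refined = [_refine_boundary(depth, b, threshold, smooth_nt // 2)
               for b in boundaries]
    refined = _monotone(refined, n)
    if len(refined) != len(segs) - 1:     # degenerate clamp: keep coarse cuts
        refined = boundaries

    cuts = [0] + refined + [n]
    segments = []
    for (s, e), (_s0, _e0, lab) in zip(zip(cuts[:-1], cuts[1:]), segs):
        if e > s:
            segments.append(Segment(s, e, float(depth[s:e].mean()),
                                    "high" if lab else "low"))
    ratio = _high_low_ratio(segments)
    return SegmentedProfile(profile.contig_id, segments, refined, ratio)


def _refine_boundary(depth: np.ndarray, b: int, threshold: float,
                     radius: int) -> int:
    """Snap a smoothed-profile boundary to the raw threshold crossing."""
    local = _moving_mean(depth, 9)
    lo = max(1, b - radius)
    hi = min(len(depth) - 1, b + radius)
    crossings = [
        i for i in range(lo, hi + 1)
        if (local[i - 1] >= threshold) != (local[i] >= threshold)
    ]
    if not crossings:
        return b
    return min(crossings, key=lambda i: (abs(i - b), i))


def _monotone(bounds: list[int], n: int) -> list[int]:
    out: list[int] = []
    for b in bounds:
        b = min(max(b, (out[-1] + 1) if out else 1), n - 1)
        if not out or b > out[-1]:
            out.append(b)
    return out


def _high_low_ratio(segments: list[Segment]) -> float:
    highs = [s for s in segments if s.label == "high"]
    lows = [s for s in segments if s.label == "low"]
    if not highs or not lows:
        return 1.0
    hw = sum((s.end - s.start) for s in highs)
    lw = sum((s.end - s.start) for s in lows)
    h = sum(s.mean_depth * (s.end - s.start) for s in highs) / hw
    low = sum(s.mean_depth * (s.end - s.start) for s in lows) / lw
    return float(h / low) if low > 0 else float("inf")


def locate_cr_coding_boundary(sp: SegmentedProfile,
                              coding_spans: list[tuple[int, int]]) -> int:
    """The high->low transition immediately upstream of the first coding base."""
    if not coding_spans:
        raise BoundaryError("no coding annotation supplied")
    starts = sorted(s for s, _e in coding_spans)
    candidates = []
    # a smoothed/refined transition may land a few dozen nt past the
    # annotated coding start; treat starts within half a smoothing window
    # upstream as still downstream of the transition
    slack = 75
    for left, right in zip(sp.segments[:-1], sp.segments[1:]):
        if left.label != "high" or right.label != "low":
            continue
        downstream = [s for s in starts if s >= right.start - slack]
        if downstream:
            candidates.append((abs(downstream[0] - right.start), right.start))
    if not candidates:
        raise BoundaryError(
            "no high->low coverage transition upstream of a coding start"
        )
    return min(candidates)[1]


def segments_tsv(sp: SegmentedProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tmean_depth\tlabel\n")
        for s in sp.segments:
            fh.write(f"{sp.contig_id}\t{s.start}\t{s.end}\t"
                     f"{s.mean_depth:.2f}\t{s.label}\n")
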
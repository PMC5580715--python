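"""Posterior-based calling of extended-lineage-sorting candidate regions.

A candidate region is a stretch of sites with high posterior probability for
the ELS state (``P >= high``, default 0.7) that is uninterrupted by any site
with a low probability (``P <= low``, default 0.1).  Called regions are
filtered on genetic length (0.025 cM on autosomes, 0.035 cM on the X, which is
more strongly affected by drift), measured under one or more recombination
maps; regions passing under all maps form the *core* set, regions passing
under at least one map the *extended* set.  The two posterior cutoffs can be
re-calibrated against labeled simulations by an RMSE grid search.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .io import RecombinationMap
from .model import InterfaceError, PosteriorTrack, SiteSequence


@dataclass
class CutoffConfig:
    """Posterior cutoffs and minimum genetic lengths for candidate calling."""

    high: float = 0.7
    low: float = 0.1
    min_glen_autosome: float = 0.025
    min_glen_X: float = 0.035

    def __post_init__(self) -> None:
        if not 0.0 <= self.low < self.high <= 1.0:
            raise ValueError(f"need 0 <= low < high <= 1, got ({self.low}, {self.high})")

    def min_glen(self, chrom_is_X: bool) -> float:
        return self.min_glen_X if chrom_is_X else self.min_glen_autosome


@dataclass
class Segment:
    """A called ELS candidate region (physical coordinates are BED-style,
    0-based half-open; site positions are 1-based)."""

    chrom: str
    start: int
    end: int
    seed_sites: int
    max_posterior: float
    glen_per_map: dict[str, float] = field(default_factory=dict)
    archaic_support: tuple[str, ...] = ()
    set_label: str = "subthreshold"
    first_site: int = -1  # indices into the site sequence
    last_site: int = -1

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment start must precede end: [{self.start}, {self.end})")

    def overlaps(self, other: "Segment") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def overlap_interval(self, other: "Segment") -> tuple[int, int]:
        return max(self.start, other.start), min(self.end, other.end)

    def contains(self, pos: int) -> bool:
        """Whether a 1-based position falls inside the region."""
        return self.start < pos <= self.end


def call_segments(
    track: PosteriorTrack | np.ndarray,
    seq: SiteSequence,
    cfg: CutoffConfig | None = None,
) -> list[Segment]:
    """Call candidate regions from the per-site ELS posterior.

    The track is split at sites with posterior ``<= low``; within each block a
    segment spans from the first to the last seed site (posterior ``>= high``),
    so intermediate sites with posteriors in ``(low, high)`` neither interrupt
    nor extend a region.  Returned segments are disjoint and ordered.
    """
    cfg = cfg or CutoffConfig()
    p = track.p_els if isinstance(track, PosteriorTrack) else np.asarray(track, dtype=float)
    if len(p) != len(seq):
        raise InterfaceError(f"track length {len(p)} != sequence length {len(seq)}")
    segments: list[Segment] = []
    # block boundaries at interrupting sites (p <= low)
    interrupting = p <= cfg.low
    idx = np.arange(len(p))
    for _, block in itertools.groupby(idx, key=lambda i: interrupting[i]):
        block = list(block)
        if interrupting[block[0]]:
            continue
        seeds = [i for i in block if p[i] >= cfg.high]
        if not seeds:
            continue
        first, last = seeds[0], seeds[-1]
        segments.append(
            Segment(
                chrom=seq.chrom,
                start=int(seq.pos[first]) - 1,
                end=int(seq.pos[last]),
                seed_sites=len(seeds),
                max_posterior=float(p[first:last + 1].max()),
                first_site=first,
                last_site=last,
            )
        )
    return segments


def genetic_length(segment: Segment, rec_map: RecombinationMap) -> float | None:
    """Genetic length (cM) of a segment under one map, by linear interpolation.

    Returns ``None`` when the segment is not fully covered by the map (such
    segments carry no support under that map).
    """
    if not rec_map.covers(segment.start, segment.end):
        return None
    return rec_map.distance(segment.start, segment.end)


def annotate_genetic_lengths(
    segments: list[Segment], maps: list[RecombinationMap]
) -> list[Segment]:
    for seg in segments:
        for m in maps:
            g = genetic_length(seg, m)
            if g is not None:
                seg.glen_per_map[m.name] = g
    return segments


def filter_by_length(
    segments: list[Segment], min_glen: float, how: str = "any"
) -> list[Segment]:
    """Keep segments whose annotated genetic length passes ``min_glen`` under
    ``any`` (default) or ``all`` of their maps."""
    agg = any if how == "any" else all
    return [
        s for s in segments
        if s.glen_per_map and agg(g >= min_glen for g in s.glen_per_map.values())
    ]


def classify_sets(
    calls_per_map: dict[str, list[Segment]],
    maps: dict[str, RecombinationMap],
    cfg: CutoffConfig | None = None,
    chrom_is_X: bool = False,
) -> tuple[list[Segment], list[Segment]]:
    """Combine per-map calls into core and extended candidate sets.

    Segments called under different maps are matched when they physically
    overlap (>= 1 bp).  A matched group is *core* when, on the overlap
    interval shared by the group, the genetic length passes the threshold
    under every map; a segment is *extended* when its own genetic length under
    at least one map passes.  Every core region also appears in the extended
    set.  Returned core segments carry the overlap-interval coordinates;
    extended segments keep their own coordinates.
    """
    cfg = cfg or CutoffConfig()
    thr = cfg.min_glen(chrom_is_X)
    map_names = list(calls_per_map)
    for name in map_names:
        for seg in calls_per_map[name]:
            g = genetic_length(seg, maps[name])
            if g is not None:
                seg.glen_per_map[name] = g

    extended: list[Segment] = []
    for name in map_names:
        for seg in calls_per_map[name]:
            g = seg.glen_per_map.get(name)
            if g is not None and g >= thr:
                seg.set_label = "extended"
                extended.append(seg)
            else:
                seg.set_label = "subthreshold"

    core: list[Segment] = []
    if len(map_names) >= 2:
        base, *others = map_names
        for seg in calls_per_map[base]:
            group = [seg]
            for oname in others:
                match = [o for o in calls_per_map[oname] if o.overlaps(seg)]
                if not match:
                    group = None
                    break
                # longest-overlap partner under that map
                group.append(max(match, key=lambda o: min(o.end, seg.end) - max(o.start, seg.start)))
            if group is None:
                continue
            start = max(s.start for s in group)
            end = min(s.end for s in group)
            if start >= end:
                continue
            glens = {name: maps[name].distance(start, end) for name in map_names}
            if all(g >= thr for g in glens.values()):
                core_seg = Segment(
                    chrom=seg.chrom, start=start, end=end,
                    seed_sites=seg.seed_sites,
                    max_posterior=max(s.max_posterior for s in group),
                    glen_per_map=glens, set_label="core",
                )
                core.append(core_seg)
                for s in group:
                    s.set_label = "core"
    else:
        core = [s for s in extended]
        for s in core:
            s.set_label = "core"
    return core, extended


def combine_archaics(
    calls_per_archaic: dict[str, list[Segment]], require_all: bool = True
) -> list[Segment]:
    """Intersect candidate calls across archaic genomes.

    With ``require_all=True`` (default) a candidate must have overlapping
    calls for every archaic and the reported coordinates are the intersection;
    otherwise the union of all calls is returned annotated with the archaics
    supporting each.
    """
    names = list(calls_per_archaic)
    if len(names) == 1 or not require_all:
        out = []
        for name in names:
            for seg in calls_per_archaic[name]:
                support = tuple(
                    n for n in names
                    if any(o.overlaps(seg) for o in calls_per_archaic[n])
                )
                seg.archaic_support = support
                out.append(seg)
        return sorted(out, key=lambda s: (s.chrom, s.start))
    base, *others = names
    out = []
    for seg in calls_per_archaic[base]:
        start, end = seg.start, seg.end
        ok = True
        for oname in others:
            match = [o for o in calls_per_archaic[oname] if o.overlaps(seg)]
            if not match:
                ok = False
                break
            best = max(match, key=lambda o: min(o.end, end) - max(o.start, start))
            start, end = max(start, best.start), min(end, best.end)
        if ok and start < end:
            out.append(
                Segment(
                    chrom=seg.chrom, start=start, end=end,
                    seed_sites=seg.seed_sites, max_posterior=seg.max_posterior,
                    glen_per_map=dict(seg.glen_per_map),
                    archaic_support=tuple(names), set_label=seg.set_label,
                )
            )
    return out


def calibrate_cutoffs(
    labeled: list[tuple[np.ndarray, np.ndarray]],
    step: float = 0.05,
    min_glens: tuple[float, float] = (0.025, 0.035),
) -> CutoffConfig:
    """Grid-search posterior cutoffs minimizing the site-label RMSE.

    ``labeled`` pairs a per-site ELS posterior array with binary truth labels
    (1 = site inside a true extended-external region).  All ``(high, low)``
    pairs on a grid with the given step are scored by the root-mean-square
    error between truth and the binary called labels; ties break toward the
    more conservative (higher ``high``, then higher ``low``) pair.
    """
    if not labeled:
        raise ValueError("calibrate_cutoffs needs at least one labeled track")
    grid = np.round(np.arange(step, 1.0, step), 10)
    best = None
    for high in grid:
        for low in grid[grid < high]:
            se = 0.0
            n = 0
            for p, t in labeled:
                p = np.asarray(p, dtype=float)
                t = np.asarray(t, dtype=float)
                if len(p) != len(t):
                    raise InterfaceError("posterior/label length mismatch")
                called = np.zeros(len(p))
                # inline segment call on the posterior vector
                interrupting = p <= low
                idx = np.arange(len(p))
                for _, block in itertools.groupby(idx, key=lambda i: interrupting[i]):
                    block = list(block)
                    if interrupting[block[0]]:
                        continue
                    seeds = [i for i in block if p[i] >= high]
                    if seeds:
                        called[seeds[0]:seeds[-1] + 1] = 1.0
                se += float(((t - called) ** 2).sum())
                n += len(p)
            rmse = np.sqrt(se / n)
            key = (round(rmse, 12), -high, -low)
            if best is None or key < best[0]:
                best = (key, float(high), float(low))
    _, high, low = best
    return CutoffConfig(
        high=high, low=low,
        min_glen_autosome=min_glens[0], min_glen_X=min_glens[1],
    )


def write_bed(segments: list[Segment], path) -> None:
    """Write candidate regions as BED with name, max posterior, per-map genetic
    lengths and set label in extra columns."""
    with open(path, "w") as fh:
        for i, seg in enumerate(
            sorted(segments, key=lambda s: (s.chrom, s.start)), start=1
        ):
            glens = ",".join(f"{k}={v:.6f}" for k, v in sorted(seg.glen_per_map.items()))
            fh.write(
                f"{seg.chrom}\t{seg.start}\t{seg.end}\tELS_{i}\t"
                f"{seg.max_posterior:.4f}\t{glens or '.'}\t{seg.set_label}\n"
            )
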
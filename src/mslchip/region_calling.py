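"""Percentile-threshold calling of MSL-bound regions from a smoothed track.

Procedure: take the highest ``top_percent`` (default 1.5%) of the track's
defined values as the cutoff; steps at or above the cutoff are *data units*;
units spaced no more than ``max_gap_bp`` (200 bp) apart are chained into
candidate regions; candidates shorter than ``min_length_bp`` (200 bp) or with
fewer than ``min_units`` (5) units are discarded. Each surviving region is
scored with the mean of its best run of five consecutive step values
(sub-cutoff steps inside the region participate), and the peak centre is the
genomic centre of that run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from .core import BoundRegion, GeneAnnotation, GenomeTrack

__all__ = [
    "CallingParams",
    "threshold_top_percent",
    "call_bound_regions",
    "genes_overlapping_regions",
    "SCORE_RUN_STEPS",
]

#: length (in steps) of the consecutive run used for region score / peak centre
SCORE_RUN_STEPS = 5


@dataclass(frozen=True)
class CallingParams:
    top_percent: float = 1.5
    max_gap_bp: int = 200
    min_length_bp: int = 200
    min_units: int = 5
    scope: str = "genome-wide"  # or "per-chromosome"

    def __post_init__(self) -> None:
        if not 0 < self.top_percent < 100:
            raise ValueError(f"top_percent must be in (0, 100), got {self.top_percent}")
        if self.max_gap_bp < 0 or self.min_length_bp <= 0 or self.min_units < 1:
            raise ValueError("gap must be >= 0; length and unit filters must be positive")
        if self.scope not in ("genome-wide", "per-chromosome"):
            raise ValueError(f"unknown cutoff scope {self.scope!r}")


def _nearest_rank_cutoff(values: np.ndarray, top_percent: float) -> float:
    """k-th largest value with k = ceil(n * top_percent / 100) (nearest rank).

    Every value >= the cutoff "crosses"; ties at the cutoff all count.
    """
    n = values.size
    k = max(1, math.ceil(n * top_percent / 100.0))
    return float(np.partition(values, n - k)[n - k])


def threshold_top_percent(
    track: GenomeTrack, top_percent: float = 1.5, scope: str = "genome-wide"
):
    """Cutoff so that the highest ``top_percent`` of defined values cross it.

    Returns a float for genome-wide scope, or a {chromosome: float} dict for
    per-chromosome scope. An all-missing track (or chromosome) is an error.
    """
    if not 0 < top_percent < 100:
        raise ValueError(f"top_percent must be in (0, 100), got {top_percent}")
    if scope == "genome-wide":
        vals = track.pooled_values()
        if vals.size == 0:
            raise ValueError("track has no defined values")
        return _nearest_rank_cutoff(vals, top_percent)
    if scope == "per-chromosome":
        out = {}
        for chrom, v in track.values.items():
            defined = v[~np.isnan(v)]
            if defined.size == 0:
                raise ValueError(f"chromosome {chrom!r} has no defined values")
            out[chrom] = _nearest_rank_cutoff(defined, top_percent)
        return out
    raise ValueError(f"unknown cutoff scope {scope!r}")


def _best_run(v: np.ndarray, first: int, last: int, step: int) -> tuple[float, int]:
    """Best (max-mean) run of SCORE_RUN_STEPS consecutive steps in [first, last].

    Runs containing missing steps are skipped; if every run has a gap, run
    means fall back to the mean of the defined values in the run. Ties go to
    the leftmost run. Returns (score, genomic centre of the run).
    """
    seg = v[first : last + 1]
    k = SCORE_RUN_STEPS
    if seg.size < k:  # cannot happen when min_units >= k, kept for safety
        mean = float(np.nanmean(seg))
        centre = (first * step + (last + 1) * step) // 2
        return mean, centre
    windows = np.lib.stride_tricks.sliding_window_view(seg, k)
    full_means = windows.mean(axis=1)
    if np.isnan(full_means).all():
        with np.errstate(invalid="ignore"):
            means = np.nanmean(windows, axis=1)
    else:
        means = full_means
    w = int(np.nanargmax(means))
    score = float(means[w])
    start_bp = (first + w) * step
    centre = (start_bp + start_bp + k * step) // 2
    return score, centre


def call_bound_regions(
    track: GenomeTrack, params: CallingParams = CallingParams()
) -> list[BoundRegion]:
    """Call bound regions on a smoothed track. See module docstring."""
    step = track.assembly.step
    cutoff = threshold_top_percent(track, params.top_percent, params.scope)
    regions: list[BoundRegion] = []
    for chrom in track.chromosomes:
        v = track.values[chrom]
        c = cutoff[chrom] if isinstance(cutoff, dict) else cutoff
        with np.errstate(invalid="ignore"):
            units = np.flatnonzero(~np.isnan(v) & (v >= c))
        if units.size == 0:
            continue
        # genomic gap between consecutive units' step intervals
        gaps_bp = (np.diff(units) - 1) * step
        breaks = np.flatnonzero(gaps_bp > params.max_gap_bp)
        length = track.assembly.length(chrom)
        for chain in np.split(units, breaks + 1):
            first, last = int(chain[0]), int(chain[-1])
            start = first * step
            end = min((last + 1) * step, length)
            if end - start < params.min_length_bp:
                continue
            if chain.size < params.min_units:
                continue
            score, centre = _best_run(v, first, last, step)
            regions.append(
                BoundRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    score=score,
                    peak_center=centre,
                    n_units=int(chain.size),
                )
            )
    return regions


def genes_overlapping_regions(
    regions: list[BoundRegion],
    genes: list[GeneAnnotation],
    flank_bp: int = 0,
) -> list[GeneAnnotation]:
    """Label expressed genes bound/unbound by overlap with called regions.

    A gene is bound iff its span extended by ``flank_bp`` on both sides
    intersects any region (half-open intervals: a region ending exactly at the
    gene start does not overlap). Non-expressed genes stay unassigned.
    """
    by_chrom: dict[str, list[BoundRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for g in genes:
        if not g.expressed:
            out.append(replace(g, group="unassigned"))
            continue
        lo, hi = g.start - flank_bp, g.end + flank_bp
        hit = any(r.start < hi and r.end > lo for r in by_chrom.get(g.chrom, ()))
        out.append(replace(g, group="bound" if hit else "unbound"))
    return out
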
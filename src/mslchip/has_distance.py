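"""Nearest-distance statistics between called regions and high affinity sites.

Distance is the interval-to-interval gap in bp: 0 when a region overlaps or
abuts a HAS. Distances are summarized as fractions in contiguous bins (default
8 bins of 5 kb; the last bin is open-ended), and compared against the same
profile for uniformly random positions on the chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoundRegion, GenomeAssembly, IntervalSet

__all__ = [
    "DistanceProfile",
    "nearest_has_distance",
    "bin_fractions",
    "random_control",
]


@dataclass(frozen=True)
class DistanceProfile:
    """Fractions of query sites per distance bin (last bin open-ended)."""

    bin_edges: tuple[float, ...]  # finite left edges; last bin is [edges[-1], inf)
    fractions: tuple[float, ...]
    n: int
    label: str  # "observed" | "random"
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.bin_edges):
            raise ValueError("one fraction per bin required")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    @property
    def first_bin_fraction(self) -> float:
        return self.fractions[0]

    @property
    def last_bin_fraction(self) -> float:
        return self.fractions[-1]


def _min_gap_to_intervals(
    q_starts: np.ndarray, q_ends: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> np.ndarray:
    """Per query interval, min over reference intervals of the gap (0 on overlap/abutment)."""
    out = np.empty(q_starts.size, dtype=np.float64)
    chunk = max(1, 4_000_000 // max(1, starts.size))
    for i in range(0, q_starts.size, chunk):
        qs = q_starts[i : i + chunk, None]
        qe = q_ends[i : i + chunk, None]
        gap = np.maximum(starts[None, :] - qe, qs - ends[None, :])
        np.maximum(gap, 0, out=gap)
        out[i : i + chunk] = gap.min(axis=1)
    return out


def nearest_has_distance(regions: list[BoundRegion], has: IntervalSet) -> list[int]:
    """Closest distance (bp) from each region to any HAS on its chromosome."""
    if not regions:
        raise ValueError("no regions to measure")
    if len(has) == 0:
        raise ValueError("empty HAS set")
    dists: list[int] = []
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for r in regions:
        if r.chrom not in by_chrom:
            by_chrom[r.chrom] = has.chrom_arrays(r.chrom)
        starts, ends = by_chrom[r.chrom]
        if starts.size == 0:
            raise ValueError(f"no HAS on chromosome {r.chrom!r}")
    for chrom in by_chrom:
        idx = [i for i, r in enumerate(regions) if r.chrom == chrom]
        qs = np.array([regions[i].start for i in idx], dtype=np.int64)
        qe = np.array([regions[i].end for i in idx], dtype=np.int64)
        starts, ends = by_chrom[chrom]
        d = _min_gap_to_intervals(qs, qe, starts, ends)
        for i, dist in zip(idx, d):
            dists.append((i, int(dist)))
    dists.sort()
    return [d for _, d in dists]


def bin_fractions(
    distances,
    bin_width_bp: int = 5_000,
    n_bins: int = 8,
    label: str = "observed",
    seed: int | None = None,
) -> DistanceProfile:
    """Bin distances into ``n_bins`` contiguous bins of ``bin_width_bp``.

    Bins are [0, w), [w, 2w), ..., [(n-1)w, inf); fractions are counts / n.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    if bin_width_bp <= 0:
        raise ValueError("bin width must be positive")
    d = np.asarray(list(distances), dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty distance list")
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    edges = np.concatenate([np.arange(n_bins) * bin_width_bp, [np.inf]])
    counts, _ = np.histogram(d, bins=edges)
    return DistanceProfile(
        bin_edges=tuple(float(e) for e in edges[:-1]),
        fractions=tuple((counts / d.size).tolist()),
        n=int(d.size),
        label=label,
        seed=seed,
    )


def random_control(
    n: int,
    chromosome: str,
    assembly: GenomeAssembly,
    has: IntervalSet,
    seed: int = 0,
    bin_width_bp: int = 5_000,
    n_bins: int = 8,
) -> DistanceProfile:
    """Distance profile of ``n`` uniform random positions (zero-length sites)."""
    if n < 1:
        raise ValueError("need at least one random position")
    length = assembly.length(chromosome)
    starts, ends = has.chrom_arrays(chromosome)
    if starts.size == 0:
        raise ValueError(f"no HAS on chromosome {chromosome!r}")
    rng = np.random.default_rng(seed)
    pos = rng.integers(0, length, size=n)
    d = _min_gap_to_intervals(pos, pos, starts, ends)
    return bin_fractions(
        d, bin_width_bp=bin_width_bp, n_bins=n_bins, label="random", seed=seed
    )
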
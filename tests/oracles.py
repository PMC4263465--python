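"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as plain scalar Python (sort, loop,
enumerate) so it shares no code path with the vectorized package internals.
"""

from __future__ import annotations

import math


def _isnan(x: float) -> bool:
    return x != x


def nearest_rank_cutoff(values, top_percent: float) -> float:
    """k-th largest defined value, k = ceil(n * p / 100)."""
    vals = sorted(v for v in values if not _isnan(v))
    n = len(vals)
    k = max(1, math.ceil(n * top_percent / 100.0))
    return vals[n - k]


def lower_median(values) -> float:
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def median_smooth_brute(values, step: int, window_bp: int, min_points: int) -> list[float]:
    """Per-window lower median with minimum-data-point discarding."""
    n = len(values)
    n_win = window_bp // step
    left = n_win // 2
    right = n_win - 1 - left
    out = []
    for i in range(n):
        window = [
            values[j]
            for j in range(max(0, i - left), min(n, i + right + 1))
            if not _isnan(values[j])
        ]
        out.append(lower_median(window) if len(window) >= min_points else float("nan"))
    return out


def call_regions_brute(
    values_by_chrom: dict[str, list[float]],
    chrom_lengths: dict[str, int],
    step: int,
    top_percent: float = 1.5,
    max_gap_bp: int = 200,
    min_length_bp: int = 200,
    min_units: int = 5,
    run_len: int = 5,
):
    """Enumerate unit chains, apply filters, score by exhaustive window search.

    Returns tuples (chrom, start, end, score, peak_center, n_units).
    """
    pooled = [v for vals in values_by_chrom.values() for v in vals if not _isnan(v)]
    cutoff = nearest_rank_cutoff(pooled, top_percent)
    regions = []
    for chrom, values in values_by_chrom.items():
        units = [i for i, v in enumerate(values) if not _isnan(v) and v >= cutoff]
        chains: list[list[int]] = []
        for i in units:
            if chains and (i - chains[-1][-1] - 1) * step <= max_gap_bp:
                chains[-1].append(i)
            else:
                chains.append([i])
        for chain in chains:
            start = chain[0] * step
            end = min((chain[-1] + 1) * step, chrom_lengths[chrom])
            if end - start < min_length_bp or len(chain) < min_units:
                continue
            # exhaustive search over all run_len-step windows inside the region
            best = None
            for w in range(chain[0], chain[-1] - run_len + 2):
                window = values[w : w + run_len]
                if any(_isnan(x) for x in window):
                    continue
                mean = sum(window) / run_len
                if best is None or mean > best[0]:
                    best = (mean, w)
            if best is None:  # all windows gapped: fall back to defined-value means
                for w in range(chain[0], chain[-1] - run_len + 2):
                    window = [x for x in values[w : w + run_len] if not _isnan(x)]
                    if not window:
                        continue
                    mean = sum(window) / len(window)
                    if best is None or mean > best[0]:
                        best = (mean, w)
            score, w = best
            centre = (w * step + (w + run_len) * step) // 2
            regions.append((chrom, start, end, score, centre, len(chain)))
    return regions


def min_gap_brute(q_start: int, q_end: int, intervals) -> int:
    """Exhaustive min interval-to-interval gap (0 on overlap/abutment)."""
    best = None
    for s, e in intervals:
        gap = max(s - q_end, q_start - e, 0)
        best = gap if best is None else min(best, gap)
    return best
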
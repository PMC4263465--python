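"""Enrichment-ratio tracks and running-median smoothing.

The ratio track is ``log2((chip + p) / (input + p))`` per 10 bp step after the
two coverage tracks are scaled to a common library total (the mean of the two
genome-wide sums); ``p`` is an additive pseudocount, default 0.5.

Smoothing is a running median over a genomic window (500 bp or 2000 bp in the
standard presets) centred on each step; windows holding fewer than a minimum
number of defined values (25 and 100 for the two presets) are discarded, i.e.
set to missing.
"""

from __future__ import annotations

import numpy as np

from .core import GenomeAssembly, GenomeTrack

__all__ = ["compute_enrichment_ratio", "median_smooth", "SMOOTHING_PRESETS"]

#: window size (bp) -> minimum defined values required per window
SMOOTHING_PRESETS: dict[int, int] = {500: 25, 2000: 100}


def compute_enrichment_ratio(
    chip: GenomeTrack,
    input_: GenomeTrack,
    pseudocount: float = 0.5,
    equalize_totals: bool = True,
) -> GenomeTrack:
    """log2 ChIP/input ratio per step.

    Both tracks are first scaled to the mean of their genome-wide totals
    (library-size normalization) unless ``equalize_totals`` is False; the
    pseudocount is added after scaling. Steps missing in either track are
    missing in the output.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    if not chip.same_grid(input_):
        raise ValueError("chip and input tracks are on different assemblies/grids")
    if equalize_totals:
        t_chip = float(np.nansum(chip.pooled_values()))
        t_input = float(np.nansum(input_.pooled_values()))
        if t_chip <= 0 or t_input <= 0:
            raise ValueError("cannot normalize: a track has zero total coverage")
        target = 0.5 * (t_chip + t_input)
        s_chip, s_input = target / t_chip, target / t_input
    else:
        s_chip = s_input = 1.0
    out = {}
    for chrom in chip.chromosomes:
        c = chip.values[chrom] * s_chip
        i = input_.values[chrom] * s_input
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.log2((c + pseudocount) / (i + pseudocount))
        r[np.isnan(c) | np.isnan(i)] = np.nan
        out[chrom] = r
    return GenomeTrack(chip.assembly, out, semantics="log2 ChIP/input", smoothing="raw")


def _window_offsets(n_window: int) -> tuple[int, int]:
    """Steps before/after the centre step covered by an n-step window.

    Derived from the window's genomic span centred on the step midpoint: a
    step j belongs to the window of step i iff its midpoint lies in
    ``[mid_i - W/2, mid_i + W/2)``, giving ``j in [i - n//2, i + n - 1 - n//2]``.
    """
    left = n_window // 2
    right = n_window - 1 - left
    return left, right


def _rolling_lower_median(
    v: np.ndarray, n_window: int, min_points: int, chunk: int = 65536
) -> np.ndarray:
    left, right = _window_offsets(n_window)
    pad = np.concatenate([np.full(left, np.nan), v, np.full(right, np.nan)])
    windows = np.lib.stride_tricks.sliding_window_view(pad, n_window)
    out = np.full(v.size, np.nan)
    for s in range(0, v.size, chunk):
        block = windows[s : s + chunk]
        cnt = np.sum(~np.isnan(block), axis=1)
        ok = cnt >= min_points
        if not ok.any():
            continue
        srt = np.sort(block[ok], axis=1)  # NaN sorts to the end
        med_idx = (cnt[ok] - 1) // 2  # lower median on even counts
        out[s : s + chunk][ok] = np.take_along_axis(srt, med_idx[:, None], axis=1).ravel()
    return out


def median_smooth(
    track: GenomeTrack, window_bp: int, min_points: int | None = None
) -> GenomeTrack:
    """Running-median smooth with minimum-data-point discarding.

    The output value at step i is the lower median of the defined raw values
    in the ``window_bp`` window centred on step i, or missing where fewer than
    ``min_points`` values are defined. ``min_points`` defaults to the preset
    pairing (500 -> 25, 2000 -> 100); for other window sizes it must be given.
    Windows are truncated at chromosome ends (the minimum still applies).
    """
    step = track.assembly.step
    if window_bp % step != 0 or window_bp < step:
        raise ValueError(f"window ({window_bp} bp) must be a positive multiple of step ({step} bp)")
    n_window = window_bp // step
    if min_points is None:
        if window_bp not in SMOOTHING_PRESETS:
            raise ValueError(
                f"no min_points preset for window {window_bp} bp; pass min_points explicitly"
            )
        min_points = SMOOTHING_PRESETS[window_bp]
    if not 1 <= min_points <= n_window:
        raise ValueError(
            f"min_points ({min_points}) must be in [1, window capacity {n_window}]"
        )
    out = {
        chrom: _rolling_lower_median(vals, n_window, min_points)
        for chrom, vals in track.values.items()
    }
    return GenomeTrack(
        track.assembly, out, semantics=track.semantics, smoothing=f"median {window_bp} bp"
    )
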
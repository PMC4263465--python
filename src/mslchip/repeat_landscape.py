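"""Repeat-masked content around transcription start sites.

Two stages: (1) a genome-wide track of the fraction of repeat-masked
nucleotides in a 200 bp window at every 10 bp step; (2) per gene group, the
mean repeat percentage in 20 bins of 1 kb of absolute distance from the TSS,
with a 95% confidence interval across genes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomeAssembly, GenomeTrack, IntervalSet
from .region_calling import threshold_top_percent

__all__ = [
    "repeat_fraction_track",
    "tss_repeat_profile",
    "select_wildtype_bound_genes",
]


def _masked_cumulative(starts: np.ndarray, ends: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Masked bp in [0, x) given merged, sorted intervals (vectorized in x)."""
    lengths = ends - starts
    cum = np.concatenate([[0], np.cumsum(lengths)])
    i = np.searchsorted(starts, x, side="right") - 1
    ii = np.clip(i, 0, None)
    partial = np.clip(x - starts[ii], 0, lengths[ii]) if starts.size else np.zeros_like(x)
    return np.where(i >= 0, cum[ii] + partial, 0.0)


def repeat_fraction_track(
    repeats: IntervalSet, assembly: GenomeAssembly, window_bp: int = 200
) -> GenomeTrack:
    """Fraction of repeat-masked bp in a window centred on each grid step.

    Windows truncated at chromosome ends use the truncated width as the
    denominator, so values stay in [0, 1].
    """
    if window_bp <= 0:
        raise ValueError("window must be positive")
    merged = repeats.merged() if len(repeats) else repeats
    out = {}
    for chrom in assembly.chromosomes:
        length = assembly.length(chrom)
        mids = assembly.step_midpoints(chrom)
        lo = np.clip(mids - window_bp / 2.0, 0, length)
        hi = np.clip(mids + window_bp / 2.0, 0, length)
        if len(merged) and chrom in merged.chromosomes:
            starts, ends = merged.chrom_arrays(chrom)
            masked = _masked_cumulative(starts, ends, hi) - _masked_cumulative(
                starts, ends, lo
            )
        else:
            masked = np.zeros(mids.size)
        out[chrom] = masked / (hi - lo)
    return GenomeTrack(assembly, out, semantics="repeat fraction")


def _gene_bin_means(
    gene: GeneAnnotation,
    track: GenomeTrack,
    n_bins: int,
    bin_bp: int,
    signed: bool,
) -> np.ndarray:
    """Mean fraction-track value per distance bin for one gene.

    Unsigned mode pools upstream and downstream (absolute distance, bins
    0..n_bins-1). Signed mode orients by strand and returns 2*n_bins values
    (upstream bins first). Bins truncated at chromosome ends simply average
    the steps that exist.
    """
    v = track.chrom_values(gene.chrom)
    step = track.assembly.step
    half_steps = (n_bins * bin_bp) // step
    centre = gene.tss // step
    lo = max(0, centre - half_steps)
    hi = min(v.size, centre + half_steps + 1)
    idx = np.arange(lo, hi)
    mids = idx * step + step / 2.0
    offset = mids - gene.tss
    if signed and gene.strand == "-":
        offset = -offset
    dist = np.abs(offset)
    inside = dist < n_bins * bin_bp
    idx, offset, dist = idx[inside], offset[inside], dist[inside]
    bins = (dist // bin_bp).astype(int)
    if signed:
        bins = np.where(offset < 0, n_bins - 1 - bins, n_bins + bins)
        total = 2 * n_bins
    else:
        total = n_bins
    vals = v[idx]
    ok = ~np.isnan(vals)
    sums = np.bincount(bins[ok], weights=vals[ok], minlength=total)
    counts = np.bincount(bins[ok], minlength=total)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def tss_repeat_profile(
    genes: list[GeneAnnotation],
    fraction_track: GenomeTrack,
    n_bins: int = 20,
    bin_bp: int = 1_000,
    signed: bool = False,
    groups: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Mean repeat percentage per distance bin and gene group.

    Gene-level bin means are averaged across the genes of each group (genes
    are the independent units); the 95% CI is the normal approximation
    ``mean +/- 1.96 * SE`` over genes. Returns a tidy frame with columns
    group, bin, dist_lo_bp, dist_hi_bp, mean_pct, ci95_half_pct, n_genes.
    """
    if n_bins < 1 or bin_bp <= 0:
        raise ValueError("n_bins and bin_bp must be positive")
    if groups is None:
        groups = tuple(dict.fromkeys(g.group for g in genes if g.group != "unassigned"))
        if not groups:
            groups = ("all",)
    rows = []
    total = 2 * n_bins if signed else n_bins
    for group in groups:
        members = [
            g
            for g in genes
            if (group == "all" and g.expressed) or (g.expressed and g.group == group)
        ]
        if not members:
            raise ValueError(f"gene group {group!r} is empty")
        mat = np.vstack(
            [_gene_bin_means(g, fraction_track, n_bins, bin_bp, signed) for g in members]
        )
        for b in range(total):
            col = mat[:, b]
            col = col[~np.isnan(col)]
            n = col.size
            mean = float(col.mean() * 100) if n else float("nan")
            se = float(col.std(ddof=1) / np.sqrt(n) * 100) if n > 1 else float("nan")
            if signed:
                lo = (b - n_bins) * bin_bp
                hi = lo + bin_bp
            else:
                lo, hi = b * bin_bp, (b + 1) * bin_bp
            rows.append(
                {
                    "group": group,
                    "bin": b,
                    "dist_lo_bp": lo,
                    "dist_hi_bp": hi,
                    "mean_pct": mean,
                    "ci95_half_pct": 1.96 * se if n > 1 else float("nan"),
                    "n_genes": n,
                }
            )
    return pd.DataFrame(rows)


def select_wildtype_bound_genes(
    genes: list[GeneAnnotation],
    ratio_track: GenomeTrack,
    top_percent: float = 5.0,
) -> list[GeneAnnotation]:
    """Label expressed genes bound/unbound by a top-percentile ratio cutoff.

    A gene is bound iff any step within its span reaches the
    ``(100 - top_percent)`` cutoff of the track's defined values (ties at the
    cutoff cross, so a constant track labels every gene bound).
    """
    from dataclasses import replace

    cutoff = threshold_top_percent(ratio_track, top_percent)
    step = ratio_track.assembly.step
    out = []
    for g in genes:
        if not g.expressed:
            out.append(replace(g, group="unassigned"))
            continue
        v = ratio_track.chrom_values(g.chrom)
        i0 = g.start // step
        i1 = min(v.size, -(-g.end // step))
        with np.errstate(invalid="ignore"):
            hit = bool(np.any(v[i0:i1] >= cutoff))
        out.append(replace(g, group="bound" if hit else "unbound"))
    return out
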
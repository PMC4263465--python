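"""Synthetic genomes, tracks, annotations and count tables with ground truth.

The generator emulates the statistical structure the analysis assumes:

* localized high-enrichment sites (HAS analogs) as boxcar fold enrichments of
  configurable width on a background coverage baseline;
* a pericentromeric gradient — the enrichment fold decays exponentially with
  distance from the centromere-proximal (right) chromosome end:
  ``fold(d) = 1 + (max_fold - 1) * exp(-d / decay_bp)``;
* per-step log2-ratio noise, Gaussian with configurable sd, split evenly (in
  variance) between the ChIP and input coverage tracks;
* repeat-masked intervals denser (by a configured factor) within a window
  around the TSSs of "bound"-labelled genes than "unbound" ones;
* per-repeat-class Poisson read counts with planted ChIP/input folds.

Everything is driven by one seeded RNG; a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import GeneAnnotation, GenomeAssembly, GenomeTrack, IntervalSet
from .io_formats import (
    write_bedgraph,
    write_gene_annotation,
    write_intervals,
)
from .repeat_class_enrichment import RepeatClassCounts

__all__ = [
    "RepeatClassSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "simulate_ratio_tracks",
    "simulate_repeat_class_counts",
    "pericentromeric_fold",
    "write_simulation",
    "DEFAULT_REPEAT_CLASSES",
]


@dataclass(frozen=True)
class RepeatClassSpec:
    """One repeat class: consensus length and planted ChIP/input fold."""

    name: str
    length_bp: int
    fold: float = 1.0

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"repeat class {self.name!r}: length must be positive")
        if self.fold <= 0:
            raise ValueError(f"repeat class {self.name!r}: fold must be positive")


# Planted folds follow the three classes reported as strongly enriched
# (Hoppel-derived PROTOP_B/PROTOP_A and the rDNA non-transcribed spacer);
# the remaining common Drosophila classes are null. Lengths are round
# consensus-scale values.
DEFAULT_REPEAT_CLASSES: tuple[RepeatClassSpec, ...] = (
    RepeatClassSpec("PROTOP_B", 1500, 5.0),
    RepeatClassSpec("PROTOP_A", 3000, 3.0),
    RepeatClassSpec("NTS_DM", 4000, 2.0),
    RepeatClassSpec("DNAREP1_DM", 600, 1.0),
    RepeatClassSpec("ROO_I", 9000, 1.0),
    RepeatClassSpec("COPIA_DM", 5100, 1.0),
    RepeatClassSpec("GYPSY_DM", 7400, 1.0),
    RepeatClassSpec("JOCKEY_DM", 5000, 1.0),
    RepeatClassSpec("BLOOD_I", 7400, 1.0),
    RepeatClassSpec("MDG1_I", 7500, 1.0),
    RepeatClassSpec("DOC_DM", 4700, 1.0),
    RepeatClassSpec("F_DM", 4700, 1.0),
    RepeatClassSpec("HOBO", 3000, 1.0),
    RepeatClassSpec("POGO_DM", 2100, 1.0),
    RepeatClassSpec("I_DM", 5400, 1.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults: a 1 Mb X-chromosome analog carrying 50 HAS of 500 bp at 4-fold
    enrichment over a log2-noise sd of 0.3, with a 2-fold pericentromeric
    gradient decaying over 100 kb; an autosome analog carrying 400 expressed
    genes (half bound, half unbound) spaced 50 kb apart, with repeat-masked
    intervals three times denser within 20 kb of bound TSSs; and 15 repeat
    classes, three with planted folds 5, 3 and 2, at an expected 1e5
    repeat-mapped reads per library.
    """

    chromosomes: Mapping[str, int] = field(
        default_factory=lambda: {"chrX": 1_000_000, "chr2L": 20_050_000}
    )
    step: int = 10
    # HAS analogs
    has_per_chromosome: Mapping[str, int] = field(default_factory=lambda: {"chrX": 50})
    has_width_bp: int = 500
    has_fold: float = 4.0
    # ratio tracks
    noise_sd: float = 0.3
    baseline_coverage: float = 100.0
    gradient_max_fold: float = 2.0
    gradient_decay_bp: float = 100_000.0
    # genes and repeat intervals
    genes_per_chromosome: Mapping[str, int] = field(default_factory=lambda: {"chr2L": 400})
    gene_spacing_bp: int = 50_000
    gene_length_bp: int = 2_000
    bound_fraction: float = 0.5
    repeat_window_bp: int = 20_000  # half-width of the TSS-centred enriched window
    repeat_density_bound: float = 0.30  # masked fraction inside bound-gene windows
    repeat_density_ratio: float = 3.0  # bound : unbound density
    background_repeat_density: float = 0.02
    repeat_length_bp: int = 200
    # repeat-class read counts
    repeat_classes: tuple[RepeatClassSpec, ...] = DEFAULT_REPEAT_CLASSES
    repeat_reads_expected: int = 100_000
    mapped_reads_total: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.has_fold <= 0 or self.gradient_max_fold <= 0:
            raise ValueError("folds must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.has_width_bp <= 0 or self.gene_length_bp <= 0 or self.repeat_length_bp <= 0:
            raise ValueError("feature widths must be positive")
        if not 0 < self.repeat_density_bound <= 1 or self.repeat_density_ratio < 1:
            raise ValueError("repeat densities must be in (0, 1] with ratio >= 1")
        if not 0 <= self.background_repeat_density < 1:
            raise ValueError("background repeat density must be in [0, 1)")
        if self.repeat_reads_expected <= 0 or self.mapped_reads_total <= 0:
            raise ValueError("read totals must be positive")
        if not 0 <= self.bound_fraction <= 1:
            raise ValueError("bound fraction must be in [0, 1]")
        for c in self.repeat_classes:
            if not isinstance(c, RepeatClassSpec):
                raise TypeError("repeat_classes must hold RepeatClassSpec entries")


@dataclass
class GroundTruth:
    """What was planted: HAS intervals, gene group labels, class folds."""

    has: IntervalSet
    gene_groups: dict[str, str]
    class_folds: dict[str, float]

    def to_json(self, path) -> None:
        payload = {
            "has": [
                {"chrom": r.chrom, "start": int(r.start), "end": int(r.end)}
                for r in self.has
            ],
            "gene_groups": self.gene_groups,
            "class_folds": self.class_folds,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def pericentromeric_fold(dist_bp: np.ndarray, max_fold: float, decay_bp: float) -> np.ndarray:
    """Enrichment fold at a distance from the centromere-proximal chromosome end."""
    return 1.0 + (max_fold - 1.0) * np.exp(-np.asarray(dist_bp, dtype=float) / decay_bp)


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeAssembly, IntervalSet, list[GeneAnnotation], IntervalSet, GroundTruth]:
    """Generate assembly, HAS, genes, repeat intervals and the ground truth.

    HAS are placed one per equal chromosome segment (jittered within the
    segment), so they never overlap. Gene TSSs sit on a jittered regular grid
    with spacing ``gene_spacing_bp``; repeat intervals of ``repeat_length_bp``
    are laid down slot-wise inside each TSS window at the group's target
    density, plus a uniform background elsewhere.
    """
    rng = _rng(config, 0)
    assembly = GenomeAssembly(dict(config.chromosomes), step=config.step)

    # --- HAS ---------------------------------------------------------------
    has_rows: list[tuple[str, int, int, str]] = []
    for chrom, n in config.has_per_chromosome.items():
        if n == 0:
            continue
        length = assembly.length(chrom)
        seg = length // n
        if seg < config.has_width_bp:
            raise ValueError(
                f"{n} HAS of {config.has_width_bp} bp do not fit on {chrom} ({length} bp)"
            )
        for k in range(n):
            start = k * seg + int(rng.integers(0, seg - config.has_width_bp + 1))
            has_rows.append((chrom, start, start + config.has_width_bp, f"HAS_{chrom}_{k + 1}"))
    has = IntervalSet(
        pd.DataFrame(has_rows, columns=["chrom", "start", "end", "name"]),
        assembly=assembly,
    ) if has_rows else IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))

    # --- genes -------------------------------------------------------------
    genes: list[GeneAnnotation] = []
    window = config.repeat_window_bp
    spacing = config.gene_spacing_bp
    jitter = max(1, spacing // 10)
    gene_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in assembly.chromosomes}
    for chrom, n in config.genes_per_chromosome.items():
        if n == 0:
            continue
        length = assembly.length(chrom)
        needed = 2 * window + (n - 1) * spacing + jitter + config.gene_length_bp
        if needed > length:
            raise ValueError(
                f"{n} genes at {spacing} bp spacing (+/-{window} bp windows) "
                f"do not fit on {chrom} ({length} bp)"
            )
        n_bound = int(round(n * config.bound_fraction))
        labels = np.array(["bound"] * n_bound + ["unbound"] * (n - n_bound))
        labels = labels[rng.permutation(n)]
        for k in range(n):
            tss = window + k * spacing + int(rng.integers(0, jitter))
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            if strand == "+":
                start, end = tss, tss + config.gene_length_bp
            else:
                start, end = tss + 1 - config.gene_length_bp, tss + 1
                if start < 0:
                    start, end, strand = tss, tss + config.gene_length_bp, "+"
            genes.append(
                GeneAnnotation(
                    gene_id=f"gene_{chrom}_{k + 1:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    expressed=True,
                    group=str(labels[k]),
                )
            )
            gene_windows[chrom].append((max(0, tss - window), min(length, tss + window)))

    # --- repeat intervals ---------------------------------------------------
    rep_len = config.repeat_length_bp
    rep_rows: list[tuple[str, int, int]] = []
    for g in genes:
        density = (
            config.repeat_density_bound
            if g.group == "bound"
            else config.repeat_density_bound / config.repeat_density_ratio
        )
        w0 = max(0, g.tss - window)
        w1 = min(assembly.length(g.chrom), g.tss + window)
        n_rep = int(round(density * (w1 - w0) / rep_len))
        if n_rep == 0:
            continue
        slot = (w1 - w0) / n_rep
        for j in range(n_rep):
            lo = w0 + int(j * slot)
            play = max(1, int(slot) - rep_len + 1)
            s = lo + int(rng.integers(0, play))
            rep_rows.append((g.chrom, s, min(s + rep_len, w1)))
    if config.background_repeat_density > 0:
        stride = int(rep_len / config.background_repeat_density)
        for chrom in assembly.chromosomes:
            length = assembly.length(chrom)
            windows = sorted(gene_windows.get(chrom, []))
            w_starts = np.array([w[0] for w in windows], dtype=np.int64)
            w_ends = np.array([w[1] for w in windows], dtype=np.int64)
            for pos in range(0, length - stride, stride):
                s = pos + int(rng.integers(0, stride - rep_len + 1))
                e = s + rep_len
                if w_starts.size:
                    k = int(np.searchsorted(w_starts, e, side="left")) - 1
                    if k >= 0 and w_ends[k] > s:
                        continue  # inside a gene window: density set by the gene group
                rep_rows.append((chrom, s, e))
    repeats = (
        IntervalSet(pd.DataFrame(rep_rows, columns=["chrom", "start", "end"]), assembly=assembly)
        if rep_rows
        else IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
    )

    truth = GroundTruth(
        has=has,
        gene_groups={g.gene_id: g.group for g in genes},
        class_folds={c.name: c.fold for c in config.repeat_classes},
    )
    return assembly, has, genes, repeats, truth


def simulate_ratio_tracks(
    assembly: GenomeAssembly,
    has: IntervalSet,
    config: SimulationConfig,
) -> tuple[GenomeTrack, GenomeTrack]:
    """Simulate (chip, input) coverage tracks on the assembly grid.

    The input track is the baseline with multiplicative exp-noise; the ChIP
    track multiplies the baseline by the HAS fold (a boxcar over each HAS) and
    the pericentromeric gradient factor, with its own independent noise. The
    per-track log2 noise sd is ``noise_sd / sqrt(2)`` so the log2 *ratio*
    noise sd equals ``noise_sd``.
    """
    rng = _rng(config, 1)
    sd_track = config.noise_sd / np.sqrt(2.0)
    step = assembly.step
    chip_vals: dict[str, np.ndarray] = {}
    input_vals: dict[str, np.ndarray] = {}
    for chrom in assembly.chromosomes:
        n = assembly.n_steps(chrom)
        length = assembly.length(chrom)
        mids = assembly.step_midpoints(chrom)
        fold = np.ones(n)
        if chrom in has.chromosomes:
            starts, ends = has.chrom_arrays(chrom)
            if starts.size and (starts.min() < 0 or ends.max() > length):
                raise ValueError(f"HAS outside {chrom} bounds")
            for s, e in zip(starts, ends):
                i0 = max(0, -(-int(s - step / 2) // step))
                i1 = min(n, -(-int(e - step / 2) // step))
                fold[i0:i1] = config.has_fold
        if config.gradient_max_fold != 1.0:
            fold = fold * pericentromeric_fold(
                length - mids, config.gradient_max_fold, config.gradient_decay_bp
            )
        noise_in = rng.normal(0.0, sd_track, n) if config.noise_sd > 0 else np.zeros(n)
        noise_ch = rng.normal(0.0, sd_track, n) if config.noise_sd > 0 else np.zeros(n)
        input_vals[chrom] = config.baseline_coverage * np.exp2(noise_in)
        chip_vals[chrom] = config.baseline_coverage * fold * np.exp2(noise_ch)
    chip = GenomeTrack(assembly, chip_vals, semantics="coverage")
    inp = GenomeTrack(assembly, input_vals, semantics="coverage")
    return chip, inp


def simulate_repeat_class_counts(
    config: SimulationConfig,
) -> tuple[RepeatClassCounts, RepeatClassCounts]:
    """Poisson read counts per repeat class for (chip, input) libraries.

    Input expectations are proportional to class consensus length and sum to
    ``repeat_reads_expected``; ChIP expectations are scaled by each class's
    planted fold. Both libraries report ``mapped_reads_total`` genome-mapped
    reads (the RPKM denominator).
    """
    if not config.repeat_classes:
        raise ValueError("repeat class list is empty")
    rng = _rng(config, 2)
    lengths = np.array([c.length_bp for c in config.repeat_classes], dtype=float)
    folds = np.array([c.fold for c in config.repeat_classes], dtype=float)
    lam = config.repeat_reads_expected * lengths / lengths.sum()
    input_counts = rng.poisson(lam)
    chip_counts = rng.poisson(lam * folds)
    names = [c.name for c in config.repeat_classes]
    chip = RepeatClassCounts(
        pd.DataFrame({"name": names, "length_bp": lengths.astype(int), "count": chip_counts}),
        mapped_total=config.mapped_reads_total,
    )
    inp = RepeatClassCounts(
        pd.DataFrame({"name": names, "length_bp": lengths.astype(int), "count": input_counts}),
        mapped_total=config.mapped_reads_total,
    )
    return chip, inp


def write_simulation(config: SimulationConfig, outdir) -> dict[str, str]:
    """Run the full generator and write every emitted file under *outdir*.

    Emits chrom.sizes, has.bed, repeats.bed, genes.gff3, gene_groups.tsv,
    chip.bedGraph, input.bedGraph, chip_repeat_counts.tsv,
    input_repeat_counts.tsv and ground_truth.json. Returns name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, has, genes, repeats, truth = simulate_genome(config)
    chip_track, input_track = simulate_ratio_tracks(assembly, has, config)
    chip_counts, input_counts = simulate_repeat_class_counts(config)
    header = {"generator": "mslchip simulate", "seed": config.seed}

    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = str(outdir / name)
        return paths[name]

    with open(_p("chrom.sizes"), "wt") as fh:
        for chrom, length in assembly.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
    write_intervals(has, _p("has.bed"), header=header)
    write_intervals(repeats, _p("repeats.bed"), header=header)
    write_gene_annotation(genes, _p("genes.gff3"), header=header)
    with open(_p("gene_groups.tsv"), "wt") as fh:
        fh.write("gene_id\tgroup\texpressed\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.group}\t{int(g.expressed)}\n")
    write_bedgraph(chip_track, _p("chip.bedGraph"), header=header)
    write_bedgraph(input_track, _p("input.bedGraph"), header=header)
    chip_counts.to_tsv(_p("chip_repeat_counts.tsv"), header=header)
    input_counts.to_tsv(_p("input_repeat_counts.tsv"), header=header)
    truth.to_json(_p("ground_truth.json"))
    return paths
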
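# mslchip

ChIP-seq enrichment-track construction, bound-region calling and repeat
analysis for studies of MSL-complex targeting in *Drosophila* — in particular
the question of where the male-specific lethal (MSL) dosage-compensation
complex binds when its *roX1*/*roX2* RNAs are absent: the X-chromosomal high
affinity sites (HAS), pericentromeric heterochromatin, and repeat-rich
neighbourhoods of active genes.

The package is for computational biologists who have stepped coverage tracks
(bedGraph/wiggle) for ChIP and input libraries, interval annotation (BED),
gene models (GFF/GTF) and per-repeat-class read-count tables, and want a
tested, scriptable reimplementation of this analysis style rather than a
one-off notebook. A seeded synthetic-data generator emits ground-truthed
inputs for every stage, so the whole pipeline is testable without any
sequencing data.

## What it computes

1. **Enrichment ratio tracks** — per 10 bp step,
   `log2((chip + p) / (input + p))` after scaling both coverage tracks to a
   common library total (pseudocount `p = 0.5` by default), then a running
   **median smooth** over 500 bp or 2000 bp windows, discarding windows with
   fewer than 25 or 100 defined values respectively.
2. **Bound-region calling** — the cutoff is the value crossed by the highest
   1.5% of the smoothed values (nearest-rank); steps ≥ cutoff ("data units")
   spaced ≤ 200 bp apart are chained into regions; regions shorter than
   200 bp or with fewer than 5 units are discarded. Each region is scored
   with the mean of its best run of five consecutive step values, whose
   genomic centre is the peak centre.
3. **HAS distance statistics** — the closest interval-to-interval distance of
   each called region to the HAS set, binned into 8 contiguous bins (last bin
   open-ended), versus the same profile for uniform random positions.
4. **TSS repeat landscape** — fraction of repeat-masked bp in 200 bp windows
   at 10 bp steps, averaged in 20 bins of 1 kb of distance from the TSS per
   gene group (bound vs unbound expressed genes), with 95% CIs across genes.
5. **Repeat-class enrichment** — per Repbase-style repeat class,
   `RPKM = count / ((length/10^3) · (genome-mapped reads/10^6))` and the
   ChIP/input RPKM ratio with a seeded bootstrap CI, plus ranking of classes
   by mutant-over-wild-type relative enrichment.

## Worked example

Simulate an X-chromosome analog (1 Mb, 50 planted HAS of 500 bp at 4-fold
enrichment over log2-ratio noise of sd 0.3, plus a pericentromeric gradient),
run the full calling chain and compare the HAS-distance profile of the called
regions with a random control:

```python
from mslchip import (SimulationConfig, simulate_genome, simulate_ratio_tracks,
                     compute_enrichment_ratio, median_smooth, call_bound_regions,
                     CallingParams, nearest_has_distance, bin_fractions, random_control)

cfg = SimulationConfig(chromosomes={"chrX": 1_000_000},
                       has_per_chromosome={"chrX": 50},
                       genes_per_chromosome={}, seed=1)
assembly, has, genes, repeats, truth = simulate_genome(cfg)
chip, inp = simulate_ratio_tracks(assembly, has, cfg)

ratio = compute_enrichment_ratio(chip, inp, pseudocount=0.5)
smoothed = median_smooth(ratio, window_bp=500)          # preset: >=25 points
regions = call_bound_regions(smoothed, CallingParams(top_percent=1.5))
print(f"{len(regions)} bound regions; first: "
      f"{regions[0].chrom}:{regions[0].start}-{regions[0].end} "
      f"score={regions[0].score:.2f} peak={regions[0].peak_center}")

dist = nearest_has_distance(regions, has)
observed = bin_fractions(dist, bin_width_bp=1_000, n_bins=8)
control = random_control(10_000, "chrX", assembly, has, seed=1, bin_width_bp=1_000)
print("observed:", [round(f, 3) for f in observed.fractions])
print("control: ", [round(f, 3) for f in control.fractions])
```

Output:

```
42 bound regions; first: chrX:9360-9560 score=1.73 peak=9465
observed: [1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
control:  [0.118, 0.088, 0.098, 0.088, 0.087, 0.081, 0.074, 0.366]
```

Every called region overlaps or abuts a planted HAS (observed first-bin
fraction 1.0), while only ~12% of random positions fall within 1 kb of one
and the largest random fraction sits in the open-ended far bin — the
signature of HAS-directed binding.

The same chain is available from the shell:

```bash
mslchip simulate --outdir data/ --seed 1
mslchip ratio --chip data/chip.bedGraph --input data/input.bedGraph \
        --chrom-sizes data/chrom.sizes --window 500 --out smoothed.bedGraph
mslchip callregions --track smoothed.bedGraph --chrom-sizes data/chrom.sizes \
        --out regions.bed
mslchip hasdist --regions regions.bed --has data/has.bed \
        --chrom-sizes data/chrom.sizes --chromosome chrX --out profile.tsv
```

plus `tssrepeat`, `repeatclass`, and the YAML-driven end-to-end commands
`run-has` and `run-repeat` (see `mslchip run-has --help`).

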
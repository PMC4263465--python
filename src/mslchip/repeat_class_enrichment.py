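"""Per-repeat-class RPKM and ChIP/input enrichment from read-count tables.

Each table holds, per repeat class, the consensus length and the number of
reads aligned to that class (multi-mapped reads retained, counted once per
class they hit), plus the library's genome-mapped read total, which is the
RPKM denominator. Enrichment is the ratio of ChIP to input RPKM; its 95% CI
comes from a seeded multinomial bootstrap over reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RepeatClassCounts",
    "rpkm",
    "class_enrichment",
    "per_nucleotide_coverage",
    "rank_enriched_classes",
    "sam_to_class_counts",
]


@dataclass
class RepeatClassCounts:
    """Read counts per repeat class plus the library genome-mapped total."""

    table: pd.DataFrame  # columns: name, length_bp, count
    mapped_total: int

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"name", "length_bp", "count"}
        if not required.issubset(t.columns):
            raise ValueError(f"count table needs columns {sorted(required)}")
        t["length_bp"] = t["length_bp"].astype(np.int64)
        t["count"] = t["count"].astype(np.int64)
        if (t["length_bp"] <= 0).any():
            bad = t.loc[t["length_bp"] <= 0, "name"].iloc[0]
            raise ValueError(f"repeat class {bad!r} has non-positive length")
        if (t["count"] < 0).any():
            raise ValueError("negative read count")
        if t["name"].duplicated().any():
            dup = t.loc[t["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate repeat class {dup!r}")
        if self.mapped_total <= 0:
            raise ValueError("genome-mapped read total must be positive")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "RepeatClassCounts":
        """Read a TSV with columns name, length_bp, count, library_total."""
        df = pd.read_csv(path, sep="\t", comment="#")
        if "library_total" not in df.columns:
            raise ValueError(f"{path}: missing library_total column")
        total = int(df["library_total"].iloc[0])
        return cls(df[["name", "length_bp", "count"]], mapped_total=total)

    def to_tsv(self, path, header: dict | None = None) -> None:
        df = self.table.copy()
        df["library_total"] = self.mapped_total
        with open(path, "wt") as fh:
            if header:
                fh.write("".join(f"# {k}: {v}\n" for k, v in header.items()))
            df.to_csv(fh, sep="\t", index=False)


def rpkm(read_count: float, class_length_bp: float, mapped_reads_total: float) -> float:
    """Reads per kilobase of class consensus per million genome-mapped reads."""
    if class_length_bp <= 0:
        raise ValueError("class length must be positive")
    if mapped_reads_total <= 0:
        raise ValueError("mapped read total must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return read_count / ((class_length_bp / 1e3) * (mapped_reads_total / 1e6))


def per_nucleotide_coverage(depth_per_position, mapped_reads_total: float) -> np.ndarray:
    """Positional depths normalized per million genome-mapped reads."""
    if mapped_reads_total <= 0:
        raise ValueError("mapped read total must be positive")
    return np.asarray(depth_per_position, dtype=np.float64) / (mapped_reads_total / 1e6)


def _bootstrap_ratios(
    chip_counts: np.ndarray,
    input_counts: np.ndarray,
    scale: float,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_boot, n_classes) bootstrap ratio replicates by resampling reads over classes."""
    n_chip, n_input = int(chip_counts.sum()), int(input_counts.sum())
    if n_chip == 0 or n_input == 0:
        return np.full((n_boot, chip_counts.size), np.nan)
    bc = rng.multinomial(n_chip, chip_counts / n_chip, size=n_boot).astype(float)
    bi = rng.multinomial(n_input, input_counts / n_input, size=n_boot).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (bc / bi) * scale
    r[~np.isfinite(r)] = np.nan
    return r


def class_enrichment(
    chip: RepeatClassCounts,
    input_: RepeatClassCounts,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-class RPKM, ChIP/input ratio and bootstrap 95% CI.

    Classes must match between the two tables. Classes with zero input RPKM
    get an undefined (NaN) ratio. Returns columns: name, length_bp,
    chip_count, input_count, chip_rpkm, input_rpkm, chip_per_nt, input_per_nt,
    ratio, ci95_lo, ci95_hi.
    """
    c = chip.table.set_index("name")
    i = input_.table.set_index("name")
    only_chip = set(c.index) - set(i.index)
    only_input = set(i.index) - set(c.index)
    if only_chip or only_input:
        missing = sorted(only_chip | only_input)[0]
        raise ValueError(f"repeat class {missing!r} present in only one table")
    i = i.loc[c.index]
    if not (c["length_bp"] == i["length_bp"]).all():
        raise ValueError("class consensus lengths differ between tables")
    lengths = c["length_bp"].to_numpy(dtype=float)
    cc = c["count"].to_numpy(dtype=float)
    ic = i["count"].to_numpy(dtype=float)
    chip_rpkm = cc / ((lengths / 1e3) * (chip.mapped_total / 1e6))
    input_rpkm = ic / ((lengths / 1e3) * (input_.mapped_total / 1e6))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(input_rpkm > 0, chip_rpkm / input_rpkm, np.nan)
    scale = input_.mapped_total / chip.mapped_total
    rng = np.random.default_rng(seed)
    boot = _bootstrap_ratios(cc, ic, scale, n_boot, rng)
    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(boot, 2.5, axis=0)
        hi = np.nanpercentile(boot, 97.5, axis=0)
    lo = np.where(np.isnan(ratio), np.nan, lo)
    hi = np.where(np.isnan(ratio), np.nan, hi)
    return pd.DataFrame(
        {
            "name": c.index,
            "length_bp": lengths.astype(int),
            "chip_count": cc.astype(int),
            "input_count": ic.astype(int),
            "chip_rpkm": chip_rpkm,
            "input_rpkm": input_rpkm,
            "chip_per_nt": (cc / lengths) / (chip.mapped_total / 1e6),
            "input_per_nt": (ic / lengths) / (input_.mapped_total / 1e6),
            "ratio": ratio,
            "ci95_lo": lo,
            "ci95_hi": hi,
        }
    ).reset_index(drop=True)


def rank_enriched_classes(
    wildtype: pd.DataFrame,
    mutant: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Order classes by mutant enrichment relative to wild type.

    Takes two :func:`class_enrichment` outputs; adds
    ``relative_enrichment = mutant ratio / wild-type ratio`` and a boolean
    ``above_threshold`` flag, sorted by relative enrichment (descending, NaN
    last). Both samples' RPKMs and ratios are retained for scatter plotting.
    """
    merged = wildtype.merge(mutant, on=["name", "length_bp"], suffixes=("_wt", "_mut"))
    if len(merged) != len(wildtype) or len(merged) != len(mutant):
        raise ValueError("wild-type and mutant tables cover different class sets")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = merged["ratio_mut"] / merged["ratio_wt"]
    merged["relative_enrichment"] = rel
    merged["above_threshold"] = rel >= fold_threshold
    return merged.sort_values(
        "relative_enrichment", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)


def sam_to_class_counts(sam_path, mapped_total: int) -> RepeatClassCounts:
    """Helper: count alignments per reference from a SAM of reads vs consensi.

    All aligned records are counted (secondary alignments included, matching
    map-all alignment policies); ``mapped_total`` must be the library's
    genome-mapped read count, which is external to this file.
    """
    import pysam

    counts: dict[str, int] = {}
    lengths: dict[str, int] = {}
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        for name, length in zip(sam.references, sam.lengths):
            lengths[name] = int(length)
            counts[name] = 0
        for rec in sam:
            if rec.is_unmapped:
                continue
            counts[rec.reference_name] += 1
    df = pd.DataFrame(
        {
            "name": list(lengths),
            "length_bp": [lengths[n] for n in lengths],
            "count": [counts[n] for n in lengths],
        }
    )
    return RepeatClassCounts(df, mapped_total=mapped_total)
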
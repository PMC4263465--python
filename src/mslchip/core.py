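"""Core genomic containers shared across the pipeline.

All coordinates are 0-based half-open (BED convention). Signal tracks live on a
fixed step grid defined by a :class:`GenomeAssembly`; missing values are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "GenomeTrack",
    "IntervalSet",
    "GeneAnnotation",
    "BoundRegion",
]


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome lengths plus the step grid (default 10 bp) tracks live on."""

    chrom_lengths: Mapping[str, int]
    step: int = 10

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step size must be positive, got {self.step}")
        lengths = dict(self.chrom_lengths)
        if not lengths:
            raise ValueError("assembly needs at least one chromosome")
        for name, length in lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chrom_lengths", {k: int(v) for k, v in lengths.items()})

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.chrom_lengths)

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def n_steps(self, chrom: str) -> int:
        """Number of grid steps on *chrom*; the last step may be partial."""
        return -(-self.length(chrom) // self.step)

    def step_midpoints(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_steps(chrom)) * self.step + self.step / 2.0


class GenomeTrack:
    """Stepped numeric signal: one float per grid step per chromosome.

    Parameters
    ----------
    assembly:
        The grid the values live on.
    values:
        Mapping chromosome -> float array of length ``assembly.n_steps(chrom)``.
        NaN marks missing steps.
    semantics:
        What the values mean (e.g. ``"coverage"``, ``"log2 ChIP/input"``,
        ``"repeat fraction"``).
    smoothing:
        ``"raw"`` or a description such as ``"median 500 bp"``.
    """

    def __init__(
        self,
        assembly: GenomeAssembly,
        values: Mapping[str, np.ndarray],
        semantics: str = "coverage",
        smoothing: str = "raw",
    ) -> None:
        self.assembly = assembly
        self.semantics = semantics
        self.smoothing = smoothing
        coerced: dict[str, np.ndarray] = {}
        for chrom, arr in values.items():
            n = assembly.n_steps(chrom)  # raises on unknown chromosome
            a = np.asarray(arr, dtype=np.float64)
            if a.shape != (n,):
                raise ValueError(
                    f"track on {chrom!r} has {a.shape[0] if a.ndim == 1 else a.shape} "
                    f"values, expected {n}"
                )
            if np.isinf(a).any():
                raise ValueError(f"track on {chrom!r} contains non-finite (inf) values")
            coerced[chrom] = a
        self.values = coerced

    @classmethod
    def empty(cls, assembly: GenomeAssembly, semantics: str = "coverage") -> "GenomeTrack":
        vals = {c: np.full(assembly.n_steps(c), np.nan) for c in assembly.chromosomes}
        return cls(assembly, vals, semantics=semantics)

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.values)

    def chrom_values(self, chrom: str) -> np.ndarray:
        try:
            return self.values[chrom]
        except KeyError:
            raise KeyError(f"track has no values for chromosome {chrom!r}") from None

    def pooled_values(self) -> np.ndarray:
        """All non-missing values across chromosomes, concatenated."""
        parts = [v[~np.isnan(v)] for v in self.values.values()]
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)

    def n_defined(self) -> int:
        return int(sum((~np.isnan(v)).sum() for v in self.values.values()))

    def same_grid(self, other: "GenomeTrack") -> bool:
        return (
            self.assembly.step == other.assembly.step
            and self.assembly.chrom_lengths == other.assembly.chrom_lengths
            and set(self.values) == set(other.values)
        )


_BED_COLUMNS = ["chrom", "start", "end", "name", "score"]


class IntervalSet:
    """Sorted genomic intervals (0-based half-open) on named chromosomes."""

    def __init__(self, df: pd.DataFrame, assembly: GenomeAssembly | None = None) -> None:
        df = df.copy()
        for col in ("name", "score"):
            if col not in df.columns:
                df[col] = None
        df = df[_BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']} (start >= end)"
            )
        if (df["start"] < 0).any():
            raise ValueError("negative interval start")
        if assembly is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                length = assembly.length(str(chrom))  # raises on unknown chromosome
                if int(sub["end"].max()) > length:
                    raise ValueError(
                        f"interval on {chrom} extends past chromosome end ({length} bp)"
                    )
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(
            drop=True
        )

    @classmethod
    def from_arrays(
        cls,
        chroms,
        starts,
        ends,
        names=None,
        scores=None,
        assembly: GenomeAssembly | None = None,
    ) -> "IntervalSet":
        df = pd.DataFrame(
            {
                "chrom": list(chroms),
                "start": np.asarray(starts, dtype=np.int64),
                "end": np.asarray(ends, dtype=np.int64),
                "name": list(names) if names is not None else None,
                "score": list(scores) if scores is not None else None,
            }
        )
        return cls(df, assembly=assembly)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[tuple]:
        return self.df.itertuples(index=False, name="Interval")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["chrom"]))

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome, sorted by start."""
        sub = self.df[self.df["chrom"] == chrom]
        return sub["start"].to_numpy(), sub["end"].to_numpy()

    def merged(self) -> "IntervalSet":
        """Union of intervals per chromosome (overlaps and abutments fused)."""
        rows: list[tuple[str, int, int]] = []
        for chrom in self.chromosomes:
            starts, ends = self.chrom_arrays(chrom)
            cur_s, cur_e = int(starts[0]), int(ends[0])
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:
                    cur_e = max(cur_e, int(e))
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            rows.append((chrom, cur_s, cur_e))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return IntervalSet(df)

    def total_bp(self) -> int:
        return int((self.df["end"] - self.df["start"]).sum())


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its span, strand, expression flag and analysis group.

    The TSS is the 0-based position of the first transcribed base: ``start``
    for + genes, ``end - 1`` for - genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    expressed: bool = True
    group: str = "unassigned"  # bound | unbound | unassigned

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.group not in ("bound", "unbound", "unassigned"):
            raise ValueError(f"gene {self.gene_id}: invalid group {self.group!r}")
        if self.group != "unassigned" and not self.expressed:
            raise ValueError(
                f"gene {self.gene_id}: group labels are assigned to expressed genes only"
            )

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class BoundRegion:
    """A called enriched interval.

    ``score`` is the mean of the best run of five consecutive step values inside
    the region; ``peak_center`` the genomic centre of that run.
    """

    chrom: str
    start: int
    end: int
    score: float
    peak_center: int
    n_units: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("region start must be < end")
        if not (self.start <= self.peak_center < self.end):
            raise ValueError(
                f"peak centre {self.peak_center} outside region "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.n_units < 1:
            raise ValueError("region must contain at least one data unit")
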
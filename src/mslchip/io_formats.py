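"""Readers and writers for the genomic text formats the pipeline consumes.

Coordinate conventions: everything is 0-based half-open internally. BED input
is used as-is; GFF/GTF (1-based closed) and wiggle (1-based) are converted on
read. All readers are gzip-transparent (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
from typing import Sequence

import numpy as np
import pandas as pd

from .core import BoundRegion, GeneAnnotation, GenomeAssembly, GenomeTrack, IntervalSet

__all__ = [
    "read_chrom_sizes",
    "read_coverage_track",
    "read_intervals",
    "read_gene_annotation",
    "read_regions",
    "write_regions",
    "write_intervals",
    "write_bedgraph",
    "write_gene_annotation",
    "repeatmasker_out_to_bed",
]


def _open_text(path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _header_lines(header: dict | None) -> str:
    if not header:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in header.items())


def read_chrom_sizes(path, step: int = 10) -> GenomeAssembly:
    """Read a UCSC-style ``.chrom.sizes`` file (name <tab> length)."""
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+", header=None, comment="#", usecols=[0, 1])
    return GenomeAssembly(dict(zip(df[0].astype(str), df[1].astype(int))), step=step)


# ---------------------------------------------------------------------------
# coverage tracks (bedGraph / wiggle)
# ---------------------------------------------------------------------------

def _sniff_wiggle(path) -> bool:
    with _open_text(path) as fh:
        for _ in range(20):
            line = fh.readline()
            if not line:
                break
            s = line.strip()
            if not s or s.startswith("#") or s.startswith(("track", "browser")):
                continue
            return s.startswith(("fixedStep", "variableStep"))
    return False


def _wiggle_to_bedgraph_df(path) -> pd.DataFrame:
    """Expand fixedStep/variableStep wiggle into (chrom, start, end, value) rows."""
    rows: list[tuple[str, int, int, float]] = []
    mode = None
    chrom = ""
    start = 0
    step = 1
    span = 1
    with _open_text(path) as fh:
        for raw in fh:
            s = raw.strip()
            if not s or s.startswith("#") or s.startswith(("track", "browser")):
                continue
            if s.startswith(("fixedStep", "variableStep")):
                fields = dict(kv.split("=", 1) for kv in s.split()[1:])
                mode = s.split()[0]
                chrom = fields["chrom"]
                span = int(fields.get("span", 1))
                if mode == "fixedStep":
                    start = int(fields["start"]) - 1  # wiggle is 1-based
                    step = int(fields.get("step", 1))
                continue
            if mode is None:
                raise ValueError(f"{path}: wiggle data before any declaration line")
            if mode == "fixedStep":
                rows.append((chrom, start, start + span, float(s)))
                start += step
            else:
                pos_s, val_s = s.split()
                pos = int(pos_s) - 1
                rows.append((chrom, pos, pos + span, float(val_s)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def read_coverage_track(path, assembly: GenomeAssembly, semantics: str = "coverage") -> GenomeTrack:
    """Read a bedGraph or wiggle file onto the assembly step grid.

    Each grid step takes the value of the input interval covering the step
    midpoint; steps covered by no interval are missing. Overlapping input
    intervals or unknown chromosomes are hard errors.
    """
    if _sniff_wiggle(path):
        df = _wiggle_to_bedgraph_df(path)
    else:
        with _open_text(path) as fh:
            try:
                df = pd.read_csv(
                    fh,
                    sep=r"\s+",
                    header=None,
                    comment="#",
                    names=["chrom", "start", "end", "value"],
                    dtype={0: str},
                    skiprows=0,
                )
            except pd.errors.EmptyDataError:
                df = pd.DataFrame(columns=["chrom", "start", "end", "value"])
        df = df[~df["chrom"].astype(str).str.startswith(("track", "browser"))]
    track = GenomeTrack.empty(assembly, semantics=semantics)
    if df.empty:
        return track
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(np.float64)
    for chrom, sub in df.groupby("chrom", sort=False):
        chrom = str(chrom)
        length = assembly.length(chrom)  # unknown chromosome -> KeyError naming it
        sub = sub.sort_values("start", kind="mergesort")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts < 0).any() or (ends > length).any():
            raise ValueError(f"{path}: interval outside {chrom} bounds (length {length})")
        if (starts >= ends).any():
            raise ValueError(f"{path}: empty or inverted interval on {chrom}")
        if (ends[:-1] > starts[1:]).any():
            i = int(np.flatnonzero(ends[:-1] > starts[1:])[0])
            raise ValueError(
                f"{path}: overlapping intervals on {chrom} near position {starts[i + 1]}"
            )
        mids = assembly.step_midpoints(chrom)
        idx = np.searchsorted(starts, mids, side="right") - 1
        covered = (idx >= 0) & (mids < ends[np.clip(idx, 0, None)])
        vals = track.values[chrom]
        vals[covered] = sub["value"].to_numpy()[idx[covered]]
    return track


def write_bedgraph(track: GenomeTrack, path, header: dict | None = None) -> None:
    """Write a track as bedGraph, run-length merging equal adjacent steps."""
    with _open_text(path, "wt") as fh:
        fh.write(_header_lines(header))
        step = track.assembly.step
        for chrom in track.chromosomes:
            v = track.values[chrom]
            length = track.assembly.length(chrom)
            defined = ~np.isnan(v)
            if not defined.any():
                continue
            # boundaries where value changes or definedness changes
            change = np.flatnonzero(
                (defined[1:] != defined[:-1])
                | (defined[1:] & defined[:-1] & (v[1:] != v[:-1]))
            )
            run_starts = np.concatenate([[0], change + 1])
            run_ends = np.concatenate([change + 1, [v.size]])
            for a, b in zip(run_starts, run_ends):
                if not defined[a]:
                    continue
                fh.write(
                    f"{chrom}\t{a * step}\t{min(b * step, length)}\t{v[a]:.6g}\n"
                )


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path, assembly: GenomeAssembly | None = None) -> IntervalSet:
    """Read a BED3+ file into a sorted :class:`IntervalSet`."""
    rows = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#") or s.startswith(("track", "browser")):
                continue
            f = s.split("\t") if "\t" in s else s.split()
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            start, end = int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            rows.append((f[0], start, end, name, score))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    return IntervalSet(df, assembly=assembly)


def write_intervals(intervals: IntervalSet, path, header: dict | None = None) -> None:
    with _open_text(path, "wt") as fh:
        fh.write(_header_lines(header))
        for rec in intervals:
            fields = [rec.chrom, str(rec.start), str(rec.end)]
            if rec.name is not None or rec.score is not None:
                fields.append(str(rec.name) if rec.name is not None else ".")
            if rec.score is not None:
                fields.append(f"{rec.score:.6g}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene annotation (GFF3 / GTF / BED6)
# ---------------------------------------------------------------------------

def _read_genes_bed(path) -> list[tuple[str, str, int, int, str]]:
    out = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#") or s.startswith(("track", "browser")):
                continue
            f = s.split("\t") if "\t" in s else s.split()
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: BED gene records need 6 columns (strand)")
            if f[5] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: missing strand")
            out.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return out


def read_gene_annotation(
    path,
    assembly: GenomeAssembly | None = None,
    expressed_ids: set[str] | None = None,
    feature_type: str = "gene",
) -> list[GeneAnnotation]:
    """Read genes from GFF3/GTF (1-based, converted) or BED6 (strand required).

    ``expressed_ids``: if given, only those gene ids are flagged expressed; a
    GFF attribute ``expressed=0|1`` takes precedence when present; otherwise
    every gene is considered expressed.
    """
    name = str(path)
    stripped = name[:-3] if name.endswith(".gz") else name
    if stripped.endswith((".bed",)):
        raw = _read_genes_bed(path)
        attr_expressed: dict[str, bool] = {}
    else:
        import gffutils

        try:
            db = gffutils.create_db(str(path), ":memory:", merge_strategy="error", keep_order=True)
        except ValueError as exc:
            raise ValueError(f"{path}: duplicate gene ids in annotation ({exc})") from exc
        raw = []
        attr_expressed = {}
        for feat in db.features_of_type(feature_type):
            if feat.strand not in ("+", "-"):
                raise ValueError(f"{path}: gene {feat.id} has no strand")
            raw.append((feat.id, feat.seqid, feat.start - 1, feat.end, feat.strand))
            if "expressed" in feat.attributes:
                attr_expressed[feat.id] = feat.attributes["expressed"][0] not in ("0", "false")
        if not raw:
            raise ValueError(f"{path}: no {feature_type!r} features found")
    seen: set[str] = set()
    genes: list[GeneAnnotation] = []
    for gid, chrom, start, end, strand in raw:
        if gid in seen:
            raise ValueError(f"{path}: duplicate gene id {gid!r}")
        seen.add(gid)
        if assembly is not None:
            length = assembly.length(chrom)
            if not (0 <= start < end <= length):
                raise ValueError(f"{path}: gene {gid} outside {chrom} bounds")
        if gid in attr_expressed:
            expressed = attr_expressed[gid]
        elif expressed_ids is not None:
            expressed = gid in expressed_ids
        else:
            expressed = True
        genes.append(GeneAnnotation(gid, chrom, start, end, strand, expressed=expressed))
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path, header: dict | None = None) -> None:
    """Write genes as GFF3 with ``expressed`` and ``group`` attributes."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        fh.write(_header_lines(header))
        for g in genes:
            attrs = f"ID={g.gene_id};expressed={int(g.expressed)};group={g.group}"
            fh.write(
                f"{g.chrom}\tmslchip\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# bound regions (BED6+2: true score and peak centre as extra columns)
# ---------------------------------------------------------------------------

def write_regions(regions: Sequence[BoundRegion], path, header: dict | None = None) -> None:
    """Write called regions as BED6+2.

    Columns: chrom, start, end, name, BED score (true score x1000, truncated
    and clipped to [0, 1000]), strand ".", true score, peak centre.
    """
    with _open_text(path, "wt") as fh:
        fh.write(_header_lines(header))
        for i, r in enumerate(regions, start=1):
            bed_score = int(min(max(r.score * 1000, 0), 1000))
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t{bed_score}\t.\t"
                f"{r.score:.6g}\t{r.peak_center}\t{r.n_units}\n"
            )


def read_regions(path) -> list[BoundRegion]:
    regions = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            s = raw.strip()
            if not s or s.startswith("#") or s.startswith(("track", "browser")):
                continue
            f = s.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected BED6+3 region record")
            regions.append(
                BoundRegion(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    score=float(f[6]),
                    peak_center=int(f[7]),
                    n_units=int(f[8]),
                )
            )
    return regions


# ---------------------------------------------------------------------------
# RepeatMasker .out converter (not part of the analysis path)
# ---------------------------------------------------------------------------

def repeatmasker_out_to_bed(path_in, path_out) -> int:
    """Convert RepeatMasker ``.out`` to BED6 (name=repeat, score=SW). Returns n rows."""
    n = 0
    with _open_text(path_in) as fh, _open_text(path_out, "wt") as out:
        for line in fh:
            f = line.split()
            if not f or not f[0].isdigit():
                continue  # header / blank lines
            sw, chrom, begin, end, name = f[0], f[4], int(f[5]), int(f[6]), f[9]
            strand = "+" if f[8] == "+" else "-"
            out.write(f"{chrom}\t{begin - 1}\t{end}\t{name}\t{sw}\t{strand}\n")
            n += 1
    return n
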
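"""Readers for per-sample WGBS count files and writers for segment outputs.

Input is one count file per sample over a shared CpG universe, either in
Bismark coverage format (chrom, start, end, methylation %, methylated
count, unmethylated count; start 1-based) or the equivalent 0-based
6-column bedGraph dialect.  Samples are outer-joined on (chrom, position);
a CpG missing from one sample becomes a zero-coverage cell.  Gzipped files
are read transparently.

Outputs: a BED6 of segment intervals (0-based half-open), a segment-level
summary TSV (1-based inclusive coordinates, documented in its header), and
a segment-by-sample matrix of pooled methylation rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import MethylationCountSet
from .clustering import Segmentation

__all__ = [
    "SampleFileSpec",
    "read_counts",
    "write_bismark_cov",
    "write_segments_bed",
    "write_segment_summary",
    "write_segment_matrix",
]

_COLUMNS = ["chrom", "start", "end", "meth_pct", "meth", "unmeth"]


@dataclass
class SampleFileSpec:
    """One sample's count file: id, path, and coordinate dialect."""

    sample_id: str
    path: str | Path
    format: str = "bismark_cov"  # "bismark_cov" (1-based) | "bedgraph6" (0-based)


def _load_sample(spec: SampleFileSpec) -> pd.DataFrame:
    if spec.format not in ("bismark_cov", "bedgraph6"):
        raise ValueError(f"unknown format {spec.format!r} for {spec.path}")
    try:
        df = pd.read_csv(
            spec.path,
            sep="\t",
            header=None,
            names=_COLUMNS,
            comment="#",
            dtype={
                "chrom": str,
                "start": np.int64,
                "end": np.int64,
                "meth_pct": float,
                "meth": np.int64,
                "unmeth": np.int64,
            },
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed count file {spec.path}: {exc}") from exc
    if df.shape[0] == 0:
        raise ValueError(f"empty count file {spec.path}")
    bad = df.index[(df["meth"] < 0) | (df["unmeth"] < 0)]
    if len(bad):
        raise ValueError(
            f"negative count in {spec.path} at line {int(bad[0]) + 1}"
        )
    # internal convention: 1-based position of the CpG cytosine
    df["pos"] = df["start"] if spec.format == "bismark_cov" else df["start"] + 1
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        line = int(df.index[dup][0]) + 1
        raise ValueError(
            f"duplicate position in {spec.path} at line {line}"
        )
    return df[["chrom", "pos", "meth", "unmeth"]]


def _chrom_style(chroms) -> str:
    flags = {str(c).startswith("chr") for c in chroms}
    if flags == {True}:
        return "chr-prefixed"
    if flags == {False}:
        return "plain"
    return "mixed"


def read_counts(
    specs: list[SampleFileSpec],
    min_coverage: int = 0,
    chrom_filter: list[str] | None = None,
) -> MethylationCountSet:
    """Outer-join per-sample count files into one count set.

    Sites present in some samples only get zero-coverage cells elsewhere.
    ``min_coverage`` (total reads summed over samples; default 0 = keep
    all) drops shallow sites.  Inconsistent chromosome naming styles across
    files (``chr1`` vs ``1``) raise with the offending files listed.
    """
    if not specs:
        raise ValueError("no input files")
    specs = [
        s if isinstance(s, SampleFileSpec) else SampleFileSpec(*s) for s in specs
    ]
    ids = [s.sample_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")

    frames: dict[str, pd.DataFrame] = {}
    styles: dict[str, str] = {}
    for spec in specs:
        df = _load_sample(spec)
        if chrom_filter is not None:
            df = df[df["chrom"].isin(chrom_filter)]
        frames[spec.sample_id] = df.set_index(["chrom", "pos"])
        styles[spec.sample_id] = _chrom_style(df["chrom"].unique())
    if len(set(styles.values())) > 1:
        offenders = ", ".join(f"{sid} ({st})" for sid, st in sorted(styles.items()))
        raise ValueError(f"inconsistent chromosome naming across files: {offenders}")

    index = frames[ids[0]].index
    for sid in ids[1:]:
        index = index.union(frames[sid].index)
    index = index.sortlevel([0, 1])[0]
    m, n = len(index), len(ids)
    meth = np.zeros((m, n), dtype=np.int64)
    unmeth = np.zeros((m, n), dtype=np.int64)
    for j, sid in enumerate(ids):
        sub = frames[sid].reindex(index)
        meth[:, j] = sub["meth"].fillna(0).to_numpy(dtype=np.int64)
        unmeth[:, j] = sub["unmeth"].fillna(0).to_numpy(dtype=np.int64)

    chroms = np.asarray(index.get_level_values(0), dtype=object)
    positions = index.get_level_values(1).to_numpy(dtype=np.int64)
    if min_coverage > 0:
        keep = (meth + unmeth).sum(axis=1) >= min_coverage
        if not keep.any():
            raise ValueError("min_coverage filter removed every site")
        meth, unmeth = meth[keep], unmeth[keep]
        chroms, positions = chroms[keep], positions[keep]
    return MethylationCountSet(meth, unmeth, positions, chroms, list(ids))


def write_bismark_cov(
    data: MethylationCountSet, sample: int | str, path: str | Path
) -> None:
    """Write one sample as a Bismark coverage file (covered sites only)."""
    j = data.sample_ids.index(sample) if isinstance(sample, str) else sample
    c = data.meth_counts[:, j]
    t = data.unmeth_counts[:, j]
    covered = (c + t) > 0
    with open(path, "w") as fh:
        for i in np.flatnonzero(covered):
            pct = 100.0 * c[i] / (c[i] + t[i])
            fh.write(
                f"{data.chroms[i]}\t{data.positions[i]}\t{data.positions[i]}"
                f"\t{pct:.6g}\t{c[i]}\t{t[i]}\n"
            )


def _segment_ids(segmentation: Segmentation) -> list[str]:
    width = max(5, len(str(len(segmentation.segments))))
    return [f"seg_{i + 1:0{width}d}" for i in range(len(segmentation.segments))]


def write_segments_bed(segmentation: Segmentation, path: str | Path) -> None:
    """BED6 of segment spans: 0-based half-open, score = 1000 * mean rate."""
    with open(path, "w") as fh:
        for seg, sid in zip(segmentation.segments, _segment_ids(segmentation)):
            score = 0 if np.isnan(seg.mean_rate) else int(round(1000 * seg.mean_rate))
            fh.write(
                f"{seg.chrom}\t{seg.start_pos - 1}\t{seg.end_pos}\t{sid}\t{score}\t.\n"
            )


def write_segment_summary(segmentation: Segmentation, path: str | Path) -> None:
    """Segment-level summary TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("# coordinates are 1-based inclusive CpG positions\n")
        fh.write(
            "segment_id\tchrom\tstart\tend\tlength_bp\tn_cpgs\t"
            "mean_methylation\tcoherent\tcoherence_pvalue\n"
        )
        for seg, sid in zip(segmentation.segments, _segment_ids(segmentation)):
            coh = "NA" if seg.coherent is None else ("TRUE" if seg.coherent else "FALSE")
            pv = "NA" if seg.coherence_pvalue is None else repr(seg.coherence_pvalue)
            mean = "NA" if np.isnan(seg.mean_rate) else repr(seg.mean_rate)
            fh.write(
                f"{sid}\t{seg.chrom}\t{seg.start_pos}\t{seg.end_pos}"
                f"\t{seg.end_pos - seg.start_pos + 1}\t{seg.n_cpgs}"
                f"\t{mean}\t{coh}\t{pv}\n"
            )


def write_segment_matrix(
    segmentation: Segmentation, data: MethylationCountSet, path: str | Path
) -> None:
    """Segment-by-sample matrix of pooled methylation rates ("NA" if no coverage)."""
    with open(path, "w") as fh:
        fh.write("segment_id\t" + "\t".join(data.sample_ids) + "\n")
        for seg, sid in zip(segmentation.segments, _segment_ids(segmentation)):
            cells = [
                "NA" if np.isnan(r) else repr(float(r)) for r in seg.per_sample_rate
            ]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")
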
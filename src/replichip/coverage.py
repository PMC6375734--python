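"""Fixed-width binned coverage tracks and their file formats.

All downstream analysis runs on per-chromosome vectors of counts in
fixed-width bins (default 100 bp, the resolution at which S/G1 copy-number
ratios are computed).  Fragments are assigned to the single bin containing
their midpoint, which keeps counts integral and conserved; the trailing
partial bin at each chromosome end is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import GenomeIndex
from .errors import ValidationError


@dataclass
class BinnedTrack:
    """Per-chromosome fixed-width bin counts for one sample.

    ``data[chrom]`` is a float vector of length ``ceil(chrom_length /
    bin_width)``; values are non-negative (counts, or count-rate expectations
    for simulated tracks).
    """

    sample_id: str
    bin_width: int
    data: dict[str, np.ndarray]
    genome: GenomeIndex

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError(f"bin_width must be positive, got {self.bin_width}")
        for chrom in self.genome.names:
            if chrom not in self.data:
                raise ValidationError(f"track {self.sample_id!r} missing chromosome {chrom!r}")
            n = self.genome.n_bins(chrom, self.bin_width)
            if len(self.data[chrom]) != n:
                raise ValidationError(
                    f"track {self.sample_id!r}: {chrom} has {len(self.data[chrom])} bins, "
                    f"expected {n}"
                )

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))

    def scaled(self, k: float) -> "BinnedTrack":
        return BinnedTrack(
            self.sample_id, self.bin_width,
            {c: v * float(k) for c, v in self.data.items()}, self.genome,
        )

    def same_grid(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.genome.names == other.genome.names
            and self.genome.lengths == other.genome.lengths
        )

    def concat(self) -> np.ndarray:
        """All bins in genome order as one vector (convenience for stats)."""
        return np.concatenate([self.data[c] for c in self.genome.names])


def empty_track(genome: GenomeIndex, bin_width: int, sample_id: str = "") -> BinnedTrack:
    data = {c: np.zeros(genome.n_bins(c, bin_width)) for c in genome.names}
    return BinnedTrack(sample_id, bin_width, data, genome)


def _fragments_frame(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        df = fragments.iloc[:, :3].copy()
        df.columns = ["chrom", "start", "end"]
    else:
        df = pd.read_csv(fragments, sep="\t", header=None, comment="#",
                         usecols=[0, 1, 2], names=["chrom", "start", "end"],
                         dtype={0: str})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def bin_fragments(
    fragments,
    genome: GenomeIndex,
    bin_width: int,
    sample_id: str = "fragments",
) -> BinnedTrack:
    """Count BED fragments into fixed-width bins by fragment midpoint.

    Each fragment ``[start, end)`` goes to the single bin containing
    ``floor((start + end) / 2)``; the total bin count equals the number of
    fragments.  Fragments on unknown chromosomes, with ``start >= end`` or
    out of chromosome bounds are hard errors.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    df = _fragments_frame(fragments)
    unknown = set(df["chrom"]) - set(genome.names)
    if unknown:
        raise ValidationError(f"fragments on unknown chromosome(s): {sorted(unknown)}")
    bad = df[df["start"] >= df["end"]]
    if len(bad):
        first = bad.iloc[0]
        raise ValidationError(
            f"fragment with start >= end: {first['chrom']}:{first['start']}-{first['end']}"
        )
    track = empty_track(genome, bin_width, sample_id)
    for chrom, sub in df.groupby("chrom", sort=False):
        length = genome.length(chrom)
        if (sub["start"] < 0).any() or (sub["end"] > length).any():
            raise ValidationError(f"fragment outside [0, {length}) on {chrom}")
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        bins = mids // bin_width
        track.data[chrom] = np.bincount(
            bins, minlength=genome.n_bins(chrom, bin_width)
        ).astype(float)
    return track


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path,
    genome: GenomeIndex,
    bin_width: int,
    sample_id: str | None = None,
) -> BinnedTrack:
    """Read a bedGraph onto the fixed bin grid.

    Intervals that tile bins exactly reproduce the writer's values
    bit-exactly; other intervals are re-binned by length-weighted averaging
    (each bin receives ``value * overlap / bin_width``).  Overlapping
    intervals are an error — a bedGraph is a function, not a pileup.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "value"],
                     dtype={0: str})
    track = empty_track(genome, bin_width, sample_id or str(path))
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in genome:
            raise ValidationError(f"bedGraph interval on unknown chromosome {chrom!r}")
        length = genome.length(chrom)
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        values = sub["value"].to_numpy(float)
        if (starts < 0).any() or (ends > length).any() or (starts >= ends).any():
            raise ValidationError(f"malformed bedGraph interval on {chrom}")
        if (starts[1:] < ends[:-1]).any():
            i = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValidationError(
                f"overlapping bedGraph intervals on {chrom} near position {ends[i]}"
            )
        arr = track.data[chrom]
        for s, e, v in zip(starts, ends, values):
            b0 = s // bin_width
            b1 = (e - 1) // bin_width
            if b0 == b1:
                arr[b0] += v * (e - s) / bin_width
            else:
                arr[b0] += v * ((b0 + 1) * bin_width - s) / bin_width
                arr[b1] += v * (e - b1 * bin_width) / bin_width
                if b1 > b0 + 1:
                    arr[b0 + 1:b1] += v
    return track


def write_bedgraph(values: dict[str, np.ndarray], genome: GenomeIndex,
                   bin_width: int, path, *, skip_nan: bool = True) -> None:
    """Write per-bin values as bedGraph, merging runs of equal value.

    NaN bins (masked) are omitted when *skip_nan* is set, which is how
    masked copy-number profiles are exported.
    """
    with open(path, "w") as fh:
        for chrom in genome.names:
            arr = np.asarray(values[chrom], dtype=float)
            length = genome.length(chrom)
            run_start = 0
            i = 1
            n = len(arr)
            while run_start < n:
                while i < n and (arr[i] == arr[run_start]
                                 or (np.isnan(arr[i]) and np.isnan(arr[run_start]))):
                    i += 1
                v = arr[run_start]
                if not (skip_nan and np.isnan(v)):
                    s = run_start * bin_width
                    e = min(i * bin_width, length)
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.17g}\n")
                run_start = i
                i += 1


def track_to_bedgraph(track: BinnedTrack, path) -> None:
    write_bedgraph(track.data, track.genome, track.bin_width, path)


def write_bigwig(values: dict[str, np.ndarray], genome: GenomeIndex,
                 bin_width: int, path) -> None:
    """Optional bigWig export (requires pyBigWig); NaN bins are omitted."""
    import pyBigWig  # deferred: optional dependency

    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(c, genome.length(c)) for c in genome.names])
    for chrom in genome.names:
        arr = np.asarray(values[chrom], dtype=float)
        keep = ~np.isnan(arr)
        idx = np.nonzero(keep)[0]
        if len(idx) == 0:
            continue
        starts = (idx * bin_width).astype(np.int64)
        ends = np.minimum(starts + bin_width, genome.length(chrom)).astype(np.int64)
        bw.addEntries([chrom] * len(idx), starts.tolist(),
                      ends=ends.tolist(), values=arr[idx].tolist())
    bw.close()
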
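"""Replication copy-number profiles calibrated on dormant regions.

The methodology, at 100-bp resolution:

1. ratio of the S-phase (HU) sample to the G1 sample per bin;
2. the mean raw ratio over the dormant-region set is taken as 1N;
3. every bin is expressed relative to that 1N value;
4. relative values bigger than 2.2N are masked out (alignment/copy
   artefacts — rDNA, transposons — produce ratios no true 1→2N transition
   can reach in a single HU arrest).

The ratio is oriented S/G1 so that replication *increases* the value:
the 1N baseline and 2.2N ceiling are only meaningful for a copy-number-like
quantity.  The transposed orientation (G1/S) is available behind
``literal_orientation`` for auditing.

Masked bins are NaN; they stay masked through every later step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import DormantRegion, GenomeIndex, Origin
from .coverage import BinnedTrack, write_bedgraph
from .errors import ValidationError

DEFAULT_MAX_N = 2.2
DEFAULT_MIN_G1_COUNT = 1.0


@dataclass
class CopyNumberProfile:
    """Per-bin relative copy number in N units (NaN = masked).

    ``one_n_value`` is the raw S/G1 ratio that maps to 1N; it is ``None``
    for an uncalibrated raw ratio track and 1.0 for a profile calibrated
    from an already-calibrated input (calibration is idempotent).
    """

    values: dict[str, np.ndarray]
    bin_width: int
    genome: GenomeIndex
    one_n_value: float | None = None
    sample_id: str = ""

    @property
    def calibrated(self) -> bool:
        return self.one_n_value is not None

    def mask(self) -> dict[str, np.ndarray]:
        return {c: np.isnan(v) for c, v in self.values.items()}

    def n_masked(self) -> int:
        return int(sum(np.isnan(v).sum() for v in self.values.values()))

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.names])

    def same_grid(self, other) -> bool:
        return (
            self.bin_width == other.bin_width
            and self.genome.names == other.genome.names
            and self.genome.lengths == other.genome.lengths
        )


def ratio_track(
    s_track: BinnedTrack,
    g1_track: BinnedTrack,
    min_g1_count: float = DEFAULT_MIN_G1_COUNT,
    literal_orientation: bool = False,
) -> CopyNumberProfile:
    """Step 1: per-bin S/G1 raw ratio, masking bins without denominator support.

    Bins whose G1 count falls below *min_g1_count* (default 1: unmappable or
    empty bins) are masked rather than padded with pseudocounts — no signal
    is fabricated where the G1 library saw nothing.
    """
    if not s_track.same_grid(g1_track):
        raise ValidationError(
            f"bin-grid mismatch between {s_track.sample_id!r} and {g1_track.sample_id!r}"
        )
    values: dict[str, np.ndarray] = {}
    for chrom in s_track.genome.names:
        s = s_track.data[chrom].astype(float)
        g1 = g1_track.data[chrom].astype(float)
        if literal_orientation:
            num, den = g1, s
        else:
            num, den = s, g1
        out = np.full(len(s), np.nan)
        ok = (g1 >= min_g1_count) & (den > 0)
        out[ok] = num[ok] / den[ok]
        values[chrom] = out
    return CopyNumberProfile(values, s_track.bin_width, s_track.genome,
                             sample_id=s_track.sample_id)


def dormant_bin_mask(
    regions: list[DormantRegion], genome: GenomeIndex, bin_width: int
) -> dict[str, np.ndarray]:
    """Boolean per-bin mask of bins overlapping any dormant region."""
    masks = {c: np.zeros(genome.n_bins(c, bin_width), dtype=bool) for c in genome.names}
    for r in regions:
        b0 = r.start // bin_width
        b1 = (r.end - 1) // bin_width
        masks[r.chrom][b0:b1 + 1] = True
    return masks


def calibrate_to_1n(
    raw: CopyNumberProfile, dormant: list[DormantRegion]
) -> CopyNumberProfile:
    """Steps 2–3: set the dormant-region mean ratio to 1N and rescale.

    ``one_n_value`` is the mean of the unmasked raw ratios over all bins of
    the dormant-region set; the profile is the raw track divided by it, so
    the dormant-region mean of the output is 1 by construction.
    """
    if not dormant:
        raise ValidationError("no dormant regions supplied for 1N calibration")
    dmask = dormant_bin_mask(dormant, raw.genome, raw.bin_width)
    pooled = np.concatenate(
        [raw.values[c][dmask[c]] for c in raw.genome.names]
    )
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValidationError("no unmasked dormant-region bins; cannot define 1N")
    one_n = float(pooled.mean())
    if one_n <= 0:
        raise ValidationError(f"non-positive 1N value {one_n}")
    values = {c: raw.values[c] / one_n for c in raw.genome.names}
    return CopyNumberProfile(values, raw.bin_width, raw.genome,
                             one_n_value=one_n, sample_id=raw.sample_id)


def apply_mask(profile: CopyNumberProfile, max_n: float = DEFAULT_MAX_N) -> CopyNumberProfile:
    """Step 4: mask bins strictly greater than *max_n* (default 2.2N).

    A value exactly at the ceiling is retained ("bigger than" is strict);
    previously masked bins stay masked.
    """
    values = {}
    for chrom, v in profile.values.items():
        out = v.copy()
        with np.errstate(invalid="ignore"):
            out[out > max_n] = np.nan
        values[chrom] = out
    return CopyNumberProfile(values, profile.bin_width, profile.genome,
                             one_n_value=profile.one_n_value,
                             sample_id=profile.sample_id)


@dataclass(frozen=True)
class ForkExtent:
    """Result of :func:`estimate_fork_extent`; distances in bp from the origin."""

    extent: int
    extent_left: int
    extent_right: int
    low_confidence: bool


def estimate_fork_extent(
    profile: CopyNumberProfile, origin: Origin, threshold_n: float = 1.5
) -> ForkExtent:
    """How far the replicated (≥ *threshold_n*) zone extends from an origin.

    Scans outward from the origin's bin on each side through the contiguous
    run of qualifying bins and reports the distance from the origin to the
    outer edge of the farthest one; the overall extent is the max of the two
    sides (forks move symmetrically, so the longer side is the better
    estimate when one side is truncated by noise or a chromosome end).

    Masked bins qualify: within a replicated zone a bin is masked either by
    the 2.2N ceiling (too HIGH — certainly above *threshold_n*) or for a
    missing G1 denominator, and breaking the run there would systematically
    truncate extents.  If the origin's own bin is masked the result is
    flagged low-confidence.
    """
    vals = profile.values[origin.chrom]
    bw = profile.bin_width
    length = profile.genome.length(origin.chrom)
    b = origin.pos // bw
    with np.errstate(invalid="ignore"):
        qual = np.isnan(vals) | (vals >= threshold_n)
    low_confidence = bool(np.isnan(vals[b]))
    if not qual[b]:
        return ForkExtent(0, 0, 0, low_confidence)
    j = b
    while j + 1 < len(vals) and qual[j + 1]:
        j += 1
    i = b
    while i - 1 >= 0 and qual[i - 1]:
        i -= 1
    extent_right = min((j + 1) * bw, length) - origin.pos
    extent_left = origin.pos - i * bw
    return ForkExtent(max(extent_left, extent_right), extent_left, extent_right,
                      low_confidence)


def orientation_looks_inverted(profile: CopyNumberProfile) -> bool:
    """Heuristic sanity check that the S/G1 ratio was not computed upside down.

    After a correct calibration the dormant regions sit at the *bottom* of
    the distribution: excursions run upward (towards 2N).  If the G1 and S
    inputs were swapped, replicated loci instead dip to ~0.5 and the lower
    tail is heavier than the upper one.  Compares the 1st/99th percentile
    distances from 1N.
    """
    vals = profile.concat()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return False
    q01, q99 = np.percentile(vals, [1, 99])
    return (1.0 - q01) > (q99 - 1.0)


def profile_to_bedgraph(profile: CopyNumberProfile, path) -> None:
    """Export the profile as bedGraph; masked bins are omitted."""
    write_bedgraph(profile.values, profile.genome, profile.bin_width, path, skip_nan=True)


def mask_to_bed(profile: CopyNumberProfile) -> pd.DataFrame:
    """Masked bins as merged BED3 intervals."""
    rows = []
    bw = profile.bin_width
    for chrom in profile.genome.names:
        nan = np.isnan(profile.values[chrom])
        if not nan.any():
            continue
        idx = np.nonzero(nan)[0]
        run_start = idx[0]
        prev = idx[0]
        length = profile.genome.length(chrom)
        for k in list(idx[1:]) + [None]:
            if k is not None and k == prev + 1:
                prev = k
                continue
            rows.append((chrom, int(run_start * bw), int(min((prev + 1) * bw, length))))
            if k is not None:
                run_start = prev = k
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])
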
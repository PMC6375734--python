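"""Centromeric internal-standard and background normalization of ChIP tracks.

Every anti-HA ChIP sample in the experiment carries the centromeric histone
Cse4 tagged with the same epitope as the kinase of interest.  Its
centromeric signal is constant across strains, so the mean read count per
bin within ±500 bp of the centromere midpoints acts as an internal standard
— a built-in spike-in — that removes library-size and IP-efficiency
differences and makes tracks directly comparable across strains.

After centromere scaling, a tagged sample can additionally be normalized to
the track of the internal-standard-only strain (per-bin ratio by default,
subtraction as an option), or — as a cross-check — to the mean signal at an
unreplicated background locus.  Centromeric windows are masked in exported
visualization tracks: the internal standard itself is not signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .annotations import CentromereSet, GenomeIndex
from .coverage import BinnedTrack, write_bedgraph
from .errors import ValidationError

DEFAULT_CEN_HALFWIDTH = 500

BACKGROUND_MODES = ("cse4_track", "unreplicated_locus", "none")


@dataclass
class NormalizedChIPTrack:
    """A ChIP track after internal-standard scaling (NaN = masked).

    ``cen_scale_factor`` is the scalar the raw counts were divided by: the
    joint mean raw count per bin over all centromeric windows (or, for
    locus normalization, the mean over the background locus).
    ``cen_mask[chrom]`` marks the centromeric windows, masked in exports
    and in background-normalized output.
    """

    values: dict[str, np.ndarray]
    bin_width: int
    genome: GenomeIndex
    cen_scale_factor: float
    background_mode: str
    cen_mask: dict[str, np.ndarray]
    sample_id: str = ""
    epsilon: float | None = None

    def __post_init__(self) -> None:
        if self.background_mode not in BACKGROUND_MODES:
            raise ValidationError(f"unknown background_mode {self.background_mode!r}")
        if not self.cen_scale_factor > 0:
            raise ValidationError("cen_scale_factor must be positive")

    def same_grid(self, other) -> bool:
        return (
            self.bin_width == other.bin_width
            and self.genome.names == other.genome.names
            and self.genome.lengths == other.genome.lengths
        )

    def concat(self) -> np.ndarray:
        return np.concatenate([self.values[c] for c in self.genome.names])


def cen_window_mask(
    genome: GenomeIndex,
    cens: CentromereSet,
    bin_width: int,
    halfwidth: int = DEFAULT_CEN_HALFWIDTH,
) -> dict[str, np.ndarray]:
    """Bins whose centre lies within ±halfwidth of a centromere midpoint."""
    masks = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom, bin_width)
        centers = np.arange(n) * bin_width + bin_width / 2
        masks[chrom] = np.abs(centers - cens.midpoint(chrom)) <= halfwidth
    return masks


def cen_scale(
    track: BinnedTrack,
    cens: CentromereSet,
    halfwidth: int = DEFAULT_CEN_HALFWIDTH,
) -> NormalizedChIPTrack:
    """Divide a track by its joint centromeric-window mean.

    One scalar across all centromeres (a single internal standard, not a
    per-chromosome one); after scaling, the mean over the centromeric
    windows is exactly 1.  A track with no centromeric counts has no
    internal standard and is an error.
    """
    masks = cen_window_mask(track.genome, cens, track.bin_width, halfwidth)
    pooled = np.concatenate([track.data[c][masks[c]] for c in track.genome.names])
    if pooled.size == 0 or pooled.sum() <= 0:
        raise ValidationError(
            f"track {track.sample_id!r}: zero counts in centromeric windows "
            "(internal standard absent)"
        )
    factor = float(pooled.mean())
    values = {c: track.data[c] / factor for c in track.genome.names}
    return NormalizedChIPTrack(values, track.bin_width, track.genome, factor,
                               "none", masks, sample_id=track.sample_id)


def background_normalize(
    signal: NormalizedChIPTrack,
    background: NormalizedChIPTrack,
    mode: str = "ratio",
    epsilon: float | None = None,
) -> NormalizedChIPTrack:
    """Normalize a cen-scaled signal track to a cen-scaled background track.

    ``ratio`` mode divides bin-wise by ``background + epsilon`` (epsilon
    defaults to half the genome-wide median of the background, guarding
    against division blow-ups in empty bins); ``subtract`` mode subtracts
    and floors at zero.  Centromeric windows are masked in the output — the
    internal standard is removed from the comparison it enabled.
    """
    if mode not in ("ratio", "subtract"):
        raise ValidationError(f"unknown background mode {mode!r}")
    if not signal.same_grid(background):
        raise ValidationError("signal/background bin-grid mismatch")
    if epsilon is None:
        med = float(np.nanmedian(background.concat()))
        epsilon = 0.5 * med
    if mode == "ratio" and epsilon <= 0:
        raise ValidationError("epsilon must be positive in ratio mode")
    values = {}
    for chrom in signal.genome.names:
        s = signal.values[chrom]
        b = background.values[chrom]
        if mode == "ratio":
            out = s / (b + epsilon)
        else:
            out = np.maximum(s - b, 0.0)
        out = out.copy()
        out[signal.cen_mask[chrom]] = np.nan
        values[chrom] = out
    return NormalizedChIPTrack(values, signal.bin_width, signal.genome,
                               signal.cen_scale_factor, "cse4_track",
                               signal.cen_mask, sample_id=signal.sample_id,
                               epsilon=epsilon if mode == "ratio" else None)


def locus_normalize(
    track: BinnedTrack, locus: tuple[str, int, int]
) -> NormalizedChIPTrack:
    """Normalize to the mean count over a background locus.

    The alternative to the internal standard: divide every bin by the mean
    count over an unreplicated locus.  Agrees with :func:`cen_scale` up to
    one global constant on any fixed track.
    """
    chrom, start, end = locus
    if chrom not in track.genome:
        raise ValidationError(f"locus on unknown chromosome {chrom!r}")
    if not (0 <= start < end <= track.genome.length(chrom)):
        raise ValidationError(f"locus {chrom}:{start}-{end} outside chromosome bounds")
    bw = track.bin_width
    b0, b1 = start // bw, (end - 1) // bw
    window = track.data[chrom][b0:b1 + 1]
    if window.sum() <= 0:
        raise ValidationError(f"zero counts at background locus {chrom}:{start}-{end}")
    factor = float(window.mean())
    values = {c: track.data[c] / factor for c in track.genome.names}
    empty = {c: np.zeros(len(v), dtype=bool) for c, v in values.items()}
    return NormalizedChIPTrack(values, bw, track.genome, factor,
                               "unreplicated_locus", empty, sample_id=track.sample_id)


def fork_window_mean(
    track: NormalizedChIPTrack,
    fork_positions: dict[str, list[int]],
    halfwidth: int = 500,
) -> float:
    """Mean normalized signal over bins within ±halfwidth of fork positions.

    The summary statistic for fork-associated enrichment: with stalled
    forks at known (or simulated) positions, compare this to the
    genome-wide background, or between strains to quantify attenuation.
    NaN (masked) bins are excluded.
    """
    pooled = []
    for chrom, forks in fork_positions.items():
        if chrom not in track.values or not forks:
            continue
        n = len(track.values[chrom])
        centers = np.arange(n) * track.bin_width + track.bin_width / 2
        sel = np.zeros(n, dtype=bool)
        for f in forks:
            sel |= np.abs(centers - f) <= halfwidth
        pooled.append(track.values[chrom][sel])
    if not pooled:
        raise ValidationError("no fork windows on the track's chromosomes")
    vals = np.concatenate(pooled)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError("all fork-window bins are masked")
    return float(vals.mean())


def attenuation_estimate(
    wt: NormalizedChIPTrack,
    mutant: NormalizedChIPTrack,
    background: NormalizedChIPTrack,
    fork_positions: dict[str, list[int]],
    halfwidth: int = 500,
) -> float:
    """Fraction of wild-type fork enrichment retained by a mutant.

    Computed from cen-scaled tracks as the ratio of background-subtracted
    fork-window means, ``(mut − bg) / (wt − bg)``.  Subtracting the
    background's fork-window *mean* (rather than per-bin values floored at
    zero) keeps the estimator unbiased when the mutant signal is close to
    background.
    """
    fw_wt = fork_window_mean(wt, fork_positions, halfwidth)
    fw_mut = fork_window_mean(mutant, fork_positions, halfwidth)
    fw_bg = fork_window_mean(background, fork_positions, halfwidth)
    denom = fw_wt - fw_bg
    if denom <= 0:
        raise ValidationError(
            "wild-type fork-window signal does not exceed background; "
            "attenuation is undefined"
        )
    return (fw_mut - fw_bg) / denom


def normalized_to_bedgraph(track: NormalizedChIPTrack, path,
                           mask_centromeres: bool = True) -> None:
    """Export as bedGraph; centromeric windows masked for visualization."""
    if mask_centromeres:
        values = {}
        for chrom, v in track.values.items():
            out = v.copy()
            out[track.cen_mask[chrom]] = np.nan
            values[chrom] = out
    else:
        values = track.values
    write_bedgraph(values, track.genome, track.bin_width, path, skip_nan=True)


def write_normalization_json(track: NormalizedChIPTrack, path) -> None:
    """Provenance sidecar: the scale factor and normalization mode used."""
    with open(path, "w") as fh:
        json.dump(
            {
                "sample_id": track.sample_id,
                "cen_scale_factor": track.cen_scale_factor,
                "background_mode": track.background_mode,
                "epsilon": track.epsilon,
                "bin_width": track.bin_width,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
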
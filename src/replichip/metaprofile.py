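"""Origin-centred heatmaps ordered by replication timing, and averages.

The central visualization of the fork-ChIP comparison: one row per origin,
rows sorted by ascending t_rep (early origins on top), columns spanning a
fixed window around the origin midpoint.  Column means over unmasked cells
give the origin-averaged profile; tracking its peak offset across an HU
time course follows the fork position as it moves away from origins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import Origin, OriginSet
from .errors import ValidationError

DEFAULT_WINDOW = 5000


@dataclass
class HeatmapMatrix:
    """Origins × offsets matrix of signal around origin midpoints.

    ``matrix[i, j]`` is the track value at ``origins[i].pos`` offset by
    ``offsets[j]`` bp (NaN where the window leaves the chromosome or the
    track is masked).  Rows are strictly sorted by (t_rep, chromosome
    order, position); the centre column is the origin's own bin.
    """

    matrix: np.ndarray
    offsets: np.ndarray
    origins: tuple[Origin, ...]
    window: int
    bin_width: int

    @property
    def n_origins(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=[o.label for o in self.origins],
                            columns=self.offsets)

    def row_order_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "origin": [o.label for o in self.origins],
                "chrom": [o.chrom for o in self.origins],
                "pos": [o.pos for o in self.origins],
                "t_rep": [o.t_rep for o in self.origins],
            }
        )


@dataclass
class AverageProfile:
    """Mean signal per offset across origins, with per-offset support counts."""

    offsets: np.ndarray
    mean: np.ndarray
    n_contributing: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n": self.n_contributing}
        )


def _track_values(track) -> tuple[dict[str, np.ndarray], int, "GenomeIndex"]:
    data = getattr(track, "values", None)
    if data is None:
        data = track.data
    return data, track.bin_width, track.genome


def build_heatmap(track, origins: OriginSet, window: int = DEFAULT_WINDOW) -> HeatmapMatrix:
    """Extract a ±window view around every origin, rows sorted by t_rep.

    Accepts any binned track (raw counts, copy-number profile or normalized
    ChIP).  Cells outside the chromosome are masked; masked track bins stay
    masked.  Rows are never rescaled — cross-strain comparability of the
    internal-standard units is the point.
    """
    data, bw, genome = _track_values(track)
    if window <= 0 or window % bw != 0:
        raise ValidationError(f"window must be a positive multiple of bin_width {bw}")
    n_flank = window // bw
    offsets = np.arange(-n_flank, n_flank + 1) * bw
    ordered = tuple(sorted(origins, key=lambda o: (o.t_rep, genome.rank(o.chrom), o.pos)))
    mat = np.full((len(ordered), 2 * n_flank + 1), np.nan)
    for i, o in enumerate(ordered):
        if o.chrom not in data:
            raise ValidationError(f"origin chromosome {o.chrom!r} missing from track")
        vals = data[o.chrom]
        b = o.pos // bw
        lo = b - n_flank
        hi = b + n_flank + 1
        src_lo = max(lo, 0)
        src_hi = min(hi, len(vals))
        mat[i, src_lo - lo: src_hi - lo] = vals[src_lo:src_hi]
    return HeatmapMatrix(mat, offsets, ordered, window, bw)


def average_profile(hm: HeatmapMatrix) -> AverageProfile:
    """NaN-aware column means; an all-masked offset stays NaN (not zero).

    Each column mean is computed over exactly the unmasked cells, so the
    profile equals the heatmap's column means bit-for-bit.
    """
    ncol = hm.matrix.shape[1]
    mean = np.full(ncol, np.nan)
    contributing = np.zeros(ncol, dtype=int)
    for j in range(ncol):
        col = hm.matrix[:, j]
        col = col[~np.isnan(col)]
        contributing[j] = col.size
        if col.size:
            mean[j] = np.mean(col)
    return AverageProfile(hm.offsets.copy(), mean, contributing)


def symmetrized(profile: AverageProfile) -> tuple[np.ndarray, np.ndarray]:
    """Fold the profile about the origin: mean of the +o and −o values."""
    n_flank = (len(profile.offsets) - 1) // 2
    center = n_flank
    pos_offsets = profile.offsets[center:]
    left = profile.mean[center::-1]
    right = profile.mean[center:]
    with np.errstate(invalid="ignore"):
        folded = np.nanmean(np.vstack([left, right]), axis=0)
    return pos_offsets, folded


def track_signal_position(profiles: Sequence[AverageProfile]) -> np.ndarray:
    """Peak offset (bp from origin) of each time point's symmetrized profile.

    In a lengthening HU time course the forks — and with them the
    fork-associated ChIP signal — move away from origins, so the peak
    offset increases with time.  A flat (or all-masked) profile has no
    defined peak and yields NaN.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two time points to track signal position")
    grid = profiles[0].offsets
    for p in profiles[1:]:
        if len(p.offsets) != len(grid) or not np.array_equal(p.offsets, grid):
            raise ValidationError("time points are on different offset grids")
    peaks = np.full(len(profiles), np.nan)
    for t, p in enumerate(profiles):
        pos_offsets, folded = symmetrized(p)
        finite = folded[~np.isnan(folded)]
        if finite.size == 0 or np.all(finite == finite[0]):
            continue  # flat: peak undefined, stays NaN
        peaks[t] = pos_offsets[int(np.nanargmax(folded))]
    return peaks


# ---------------------------------------------------------------------------
# exports


def heatmap_to_tsv(hm: HeatmapMatrix, path) -> None:
    hm.to_frame().to_csv(path, sep="\t", index_label="origin")


def row_order_to_tsv(hm: HeatmapMatrix, path) -> None:
    hm.row_order_frame().to_csv(path, sep="\t", index=False)


def profile_to_tsv(profile: AverageProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def save_heatmap_png(hm: HeatmapMatrix, path, title: str = "",
                     vmax_quantile: float = 0.98) -> None:
    """Render the heatmap (rows top-to-bottom = early-to-late origins)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    finite = hm.matrix[~np.isnan(hm.matrix)]
    vmax = np.quantile(finite, vmax_quantile) if finite.size else 1.0
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(hm.matrix, aspect="auto", interpolation="nearest",
                   vmin=0, vmax=vmax, cmap="viridis",
                   extent=[hm.offsets[0], hm.offsets[-1], hm.n_origins, 0])
    ax.set_xlabel("offset from origin (bp)")
    ax.set_ylabel("origins (increasing $t_{rep}$)")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="normalized signal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_profile_png(profiles: dict[str, AverageProfile], path,
                     ylabel: str = "normalized signal") -> None:
    """Overlay one or more origin-averaged profiles (e.g. strains to compare)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, p in profiles.items():
        ax.plot(p.offsets, p.mean, label=label)
    ax.set_xlabel("offset from origin (bp)")
    ax.set_ylabel(ylabel)
    ax.axvline(0, color="0.8", lw=0.8, zorder=0)
    if len(profiles) > 1:
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
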
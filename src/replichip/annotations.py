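"""Genome, origin and centromere annotations; dormant-region selection.

The copy-number calibration in :mod:`replichip.repprofile` needs a set of
*dormant regions*: stretches of the genome that are confidently unreplicated
after release into hydroxyurea (HU), because they lie as far as possible from
any origin that could have fired.  A dormant region is defined here as a
fixed-width window (default 10 kb) centred on the midpoint of the gap between
two adjacent late/dormant origins, taking the ``n_pairs`` largest such gaps
genome-wide.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

EARLY = "early"
LATE_DORMANT = "late_dormant"
FIRE_CLASSES = (EARLY, LATE_DORMANT)

#: Default late/dormant cutoff: percentile of the input t_rep distribution.
DEFAULT_LATE_PERCENTILE = 75.0


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome names and lengths; the coordinate authority.

    Every interval handled by the package must lie within
    ``[0, chrom_length)`` of a chromosome listed here, and every binned
    track is laid out in this chromosome order.
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValidationError("duplicate chromosome names in genome index")
        if len(self.names) != len(self.lengths):
            raise ValidationError("genome index names/lengths length mismatch")
        for name, length in zip(self.names, self.lengths):
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def sizes(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def rank(self, chrom: str) -> int:
        """Position of *chrom* in the genome ordering (for deterministic sorts)."""
        try:
            return self.names.index(chrom)
        except ValueError:
            raise ValidationError(f"unknown chromosome {chrom!r}") from None

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return math.ceil(self.length(chrom) / bin_width)

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


@dataclass(frozen=True)
class Origin:
    """A replication origin: midpoint position and normal replication time.

    ``t_rep`` is the time (minutes into S phase) at which the locus is
    normally replicated; small values mark early origins.  ``fire_class``
    is ``None`` until classified (or provided explicitly in the input).
    """

    chrom: str
    pos: int
    t_rep: float
    fire_class: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.t_rep):
            raise ValidationError(f"origin {self.chrom}:{self.pos} has non-finite t_rep")
        if self.fire_class is not None and self.fire_class not in FIRE_CLASSES:
            raise ValidationError(
                f"origin {self.chrom}:{self.pos} has unknown fire_class {self.fire_class!r}"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def label(self) -> str:
        return self.name or f"{self.chrom}:{self.pos}"


@dataclass(frozen=True)
class OriginSet:
    """Origins sorted by (genome chromosome order, position), unique by locus."""

    origins: tuple[Origin, ...]
    genome: GenomeIndex

    def __post_init__(self) -> None:
        for o in self.origins:
            if o.chrom not in self.genome:
                raise ValidationError(f"origin on unknown chromosome {o.chrom!r}")
            if not (0 <= o.pos < self.genome.length(o.chrom)):
                raise ValidationError(
                    f"origin {o.chrom}:{o.pos} outside [0, {self.genome.length(o.chrom)})"
                )
        ordered = tuple(sorted(self.origins, key=lambda o: (self.genome.rank(o.chrom), o.pos)))
        keys = [o.key for o in ordered]
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        if dupes:
            listing = ", ".join(f"{c}:{p}" for c, p in dupes)
            raise ValidationError(f"duplicate origin positions: {listing}")
        object.__setattr__(self, "origins", ordered)

    def __len__(self) -> int:
        return len(self.origins)

    def __iter__(self) -> Iterator[Origin]:
        return iter(self.origins)

    def __getitem__(self, i: int) -> Origin:
        return self.origins[i]

    def on(self, chrom: str) -> tuple[Origin, ...]:
        return tuple(o for o in self.origins if o.chrom == chrom)

    @property
    def t_reps(self) -> np.ndarray:
        return np.array([o.t_rep for o in self.origins], dtype=float)

    def with_origins(self, origins: Iterable[Origin]) -> "OriginSet":
        return OriginSet(tuple(origins), self.genome)


@dataclass(frozen=True)
class CentromereSet:
    """Exactly one centromere interval per chromosome of the genome."""

    intervals: dict[str, tuple[int, int]]
    genome: GenomeIndex

    def __post_init__(self) -> None:
        for chrom in self.genome.names:
            if chrom not in self.intervals:
                raise ValidationError(f"no centromere for chromosome {chrom!r}")
        for chrom, (start, end) in self.intervals.items():
            if chrom not in self.genome:
                raise ValidationError(f"centromere on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.genome.length(chrom)):
                raise ValidationError(
                    f"centromere {chrom}:{start}-{end} outside chromosome bounds"
                )
        if len(self.intervals) != len(self.genome.names):
            extra = set(self.intervals) - set(self.genome.names)
            raise ValidationError(f"centromeres on chromosomes absent from genome: {sorted(extra)}")

    def midpoint(self, chrom: str) -> int:
        start, end = self.intervals[chrom]
        return (start + end) // 2

    def midpoints(self) -> dict[str, int]:
        return {c: self.midpoint(c) for c in self.genome.names}


@dataclass(frozen=True)
class DormantRegion:
    """Fixed-width window centred on the gap midpoint between two late origins."""

    chrom: str
    start: int
    end: int
    flanking: tuple[Origin, Origin]

    @property
    def gap(self) -> int:
        return self.flanking[1].pos - self.flanking[0].pos

    @property
    def width(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# file loading


def read_chrom_sizes(path) -> GenomeIndex:
    """Read a two-column (name, length) TSV into a :class:`GenomeIndex`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["chrom", "length"], dtype={0: str})
    lengths = pd.to_numeric(df["length"], errors="coerce")
    if lengths.isna().any():
        bad = df.loc[lengths.isna(), "chrom"].tolist()
        raise ValidationError(f"non-numeric chromosome length for {bad}")
    return GenomeIndex(tuple(df["chrom"]), tuple(int(x) for x in lengths))


def read_origins_bed(path, genome: GenomeIndex) -> OriginSet:
    """Read origins from BED3 + t_rep column (+ optional class column).

    Column layout: chrom, start, end, t_rep[, class] where class is
    ``early`` or ``late`` (mapped to :data:`LATE_DORMANT`).  The origin
    position is the interval midpoint.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "t_rep", "cls", "extra"],
                     dtype={"chrom": str, "t_rep": object, "cls": object})
    if df["t_rep"].isna().all() and len(df):
        raise ValidationError(f"origin file {path} needs >= 4 columns (chrom,start,end,t_rep)")
    origins = []
    for row in df.itertuples(index=False):
        chrom = str(row.chrom)
        if chrom not in genome:
            raise ValidationError(f"origin record on unknown chromosome {chrom!r}: {tuple(row)}")
        start, end = int(row.start), int(row.end)
        try:
            t_rep = float(row.t_rep)
        except (TypeError, ValueError):
            raise ValidationError(f"non-numeric t_rep in origin record {tuple(row)}") from None
        fire_class = None
        if isinstance(row.cls, str) and row.cls.strip():
            raw = row.cls.strip().lower()
            if raw in ("early",):
                fire_class = EARLY
            elif raw in ("late", "dormant", "late_dormant", "late/dormant"):
                fire_class = LATE_DORMANT
            else:
                raise ValidationError(f"unknown origin class {row.cls!r} in record {tuple(row)}")
        origins.append(Origin(chrom, (start + end) // 2, t_rep, fire_class))
    return OriginSet(tuple(origins), genome)


def read_centromeres_bed(path, genome: GenomeIndex) -> CentromereSet:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    intervals: dict[str, tuple[int, int]] = {}
    for row in df.itertuples(index=False):
        chrom = str(row[0])
        if chrom in intervals:
            raise ValidationError(f"multiple centromere records for chromosome {chrom!r}")
        intervals[chrom] = (int(row[1]), int(row[2]))
    return CentromereSet(intervals, genome)


def load_annotations(genome_table, origins, centromeres):
    """Load and validate the three annotation files.

    Returns ``(GenomeIndex, OriginSet, CentromereSet)``; any record that
    violates the coordinate authority (unknown chromosome, out-of-bounds
    position, duplicate origin locus) raises :class:`ValidationError`.
    """
    genome = read_chrom_sizes(genome_table)
    oset = read_origins_bed(origins, genome)
    cens = read_centromeres_bed(centromeres, genome)
    return genome, oset, cens


# ---------------------------------------------------------------------------
# classification and dormant-region selection


def classify_origins(oset: OriginSet, late_threshold: float | None = None) -> OriginSet:
    """Assign ``fire_class`` by t_rep threshold: late/dormant iff t_rep >= threshold.

    Origins carrying an explicit class from the input file keep it.  When
    *late_threshold* is ``None`` it defaults to the 75th percentile of the
    full t_rep distribution — a conventional cut for "late" origins when
    the annotation provides no class of its own.
    """
    if late_threshold is None:
        late_threshold = float(np.percentile(oset.t_reps, DEFAULT_LATE_PERCENTILE))
    out = []
    for o in oset:
        if o.fire_class is not None:
            out.append(o)
        else:
            cls = LATE_DORMANT if o.t_rep >= late_threshold else EARLY
            out.append(replace(o, fire_class=cls))
    return oset.with_origins(out)


def select_dormant_regions(
    oset: OriginSet,
    genome: GenomeIndex,
    n_pairs: int = 10,
    width: int = 10_000,
) -> list[DormantRegion]:
    """Pick the ``n_pairs`` widest gaps between adjacent late/dormant origins.

    A candidate pair is two origins adjacent in the chromosome's origin
    ordering that are *both* late/dormant — no origin of any class lies
    between them, which is what licenses the assumption that the region is
    unreplicated in HU.  Pairs with gap >= *width* are ranked genome-wide
    by gap size (descending; ties broken by genome chromosome order then
    start) and the top *n_pairs* become dormant regions: the *width*-bp
    window centred on the gap midpoint, the point least likely to have been
    reached by a fork from either side.
    """
    candidates: list[tuple[Origin, Origin]] = []
    for chrom in genome.names:
        chrom_origins = oset.on(chrom)
        candidates.extend(
            (a, b)
            for a, b in zip(chrom_origins, chrom_origins[1:])
            if a.fire_class == LATE_DORMANT and b.fire_class == LATE_DORMANT
        )
    eligible = [(a, b) for a, b in candidates if b.pos - a.pos >= width]
    if len(eligible) < n_pairs:
        raise ValidationError(
            f"{len(eligible)} eligible pairs (need {n_pairs}) of adjacent "
            f"late/dormant origins with gap >= {width} bp"
        )
    eligible.sort(key=lambda ab: (-(ab[1].pos - ab[0].pos), genome.rank(ab[0].chrom), ab[0].pos))
    regions = []
    for a, b in eligible[:n_pairs]:
        mid = (a.pos + b.pos) // 2
        start = mid - width // 2
        end = start + width
        regions.append(DormantRegion(a.chrom, start, end, (a, b)))
    return regions


def dormant_regions_to_bed(regions: Sequence[DormantRegion]) -> pd.DataFrame:
    """Export as BED6; the score column carries the flanking-origin gap in bp."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "name": [f"dormant_{i + 1}" for i in range(len(regions))],
            "score": [r.gap for r in regions],
            "strand": ["." for _ in regions],
        }
    )
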
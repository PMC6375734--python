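"""Synthetic HU-arrest sequencing data with known ground truth.

The generator emulates the statistical structure of the real experiment:
cells released from G1 into hydroxyurea (HU) stall replication forks about
2 kb from each fired origin, so

* a G1 (unreplicated) whole-genome sample is flat ~1N coverage,
* an S-phase HU sample shows 2N plateaus spanning ``pos ± fork_distance``
  around every fired origin,
* a checkpoint-kinase (Rad53) ChIP sample shows a peak at each of the two
  stalled-fork positions per fired origin, on top of a flat background,
* every anti-HA ChIP sample additionally carries strong centromeric peaks
  from the Cse4-HA internal standard, present whether or not the kinase
  itself is tagged.

Counts are drawn per 100-bp bin from a Poisson with the appropriate rate;
the analysis operates entirely on binned counts, so fragment-level
simulation is unnecessary (a BED-fragment writer is still provided to
exercise the fragment-binning reader).  Firing regimes: ``wildtype`` fires
only origins with t_rep <= ``firing_cutoff`` (late origins stay dormant
under the checkpoint); ``sld3A_dbf4A`` emulates the checkpoint-blind
*sld3-A dbf4-A* alleles and fires every origin.  The *cdc45-2A* mutant,
which retains only background ChIP signal at forks, is emulated as a
multiplicative attenuation of the fork-peak enrichment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .annotations import CentromereSet, GenomeIndex, Origin, OriginSet
from .coverage import BinnedTrack
from .errors import ValidationError

WILDTYPE = "wildtype"
SLD3A_DBF4A = "sld3A_dbf4A"
FIRING_REGIMES = (WILDTYPE, SLD3A_DBF4A)

SAMPLE_KINDS = ("G1", "S", "chip_tagged", "chip_untagged")
_KIND_CODE = {k: i for i, k in enumerate(SAMPLE_KINDS)}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with the study's conditions as defaults.

    ``depth_lambda`` is the expected fragment count per 1N bin;
    ``fork_distance`` (bp) is how far forks travel before stalling (2 kb,
    matching how far the fork-associated ChIP signal reaches from origins);
    ``peak_sigma`` is the Gaussian width of each fork ChIP peak;
    ``cen_amplitude``/``cen_halfwidth`` shape the centromeric
    internal-standard peaks; ``enrichment_attenuation`` in [0, 1] scales
    the fork enrichment (1 = wild type, ~0.1 emulates *cdc45-2A*).
    """

    seed: int = 0
    bin_width: int = 100
    depth_lambda: float = 100.0
    firing_regime: str = SLD3A_DBF4A
    firing_cutoff: float = 30.0
    fork_distance: int = 2000
    chip_background: float = 5.0
    fork_enrichment: float = 30.0
    enrichment_attenuation: float = 1.0
    peak_sigma: float = 200.0
    cen_amplitude: float = 50.0
    cen_halfwidth: int = 500

    def __post_init__(self) -> None:
        if self.firing_regime not in FIRING_REGIMES:
            raise ValidationError(f"unknown firing_regime {self.firing_regime!r}")
        for name in ("depth_lambda", "chip_background", "fork_enrichment",
                     "cen_amplitude", "peak_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.enrichment_attenuation <= 1.0):
            raise ValidationError("enrichment_attenuation must be in [0, 1]")
        if self.bin_width <= 0 or self.fork_distance < 0 or self.cen_halfwidth < 0:
            raise ValidationError("bin_width must be > 0; distances must be >= 0")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class GroundTruth:
    """What the simulator actually did, for parameter-recovery tests.

    ``replicated`` holds merged (union) replicated intervals per chromosome;
    ``true_copy_number[chrom]`` is 2 on bins overlapping a replicated
    interval and 1 elsewhere — overlapping forks never stack beyond 2N,
    since each locus is replicated at most once.
    """

    fired: tuple[Origin, ...]
    replicated: dict[str, list[tuple[int, int]]]
    fork_positions: dict[str, list[int]]
    true_copy_number: dict[str, np.ndarray]
    genome: GenomeIndex
    bin_width: int
    fork_distance: int

    def copy_mask(self, n: int) -> dict[str, np.ndarray]:
        """Boolean per-bin mask of bins with true copy number *n*."""
        return {c: v == n for c, v in self.true_copy_number.items()}


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def simulate_copy_number(
    origins: OriginSet, genome: GenomeIndex, cfg: SimulationConfig
) -> GroundTruth:
    """Decide which origins fire and lay down the 1N/2N ground truth.

    Each fired origin replicates ``[pos - fork_distance, pos + fork_distance)``
    (clipped to the chromosome); the two interval ends are the stalled-fork
    positions targeted by the ChIP peaks.
    """
    if cfg.firing_regime == SLD3A_DBF4A:
        fired = tuple(origins)
    else:
        fired = tuple(o for o in origins if o.t_rep <= cfg.firing_cutoff)

    replicated: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    fork_positions: dict[str, list[int]] = {c: [] for c in genome.names}
    for o in fired:
        length = genome.length(o.chrom)
        s = max(0, o.pos - cfg.fork_distance)
        e = min(length, o.pos + cfg.fork_distance)
        replicated[o.chrom].append((s, e))
        fork_positions[o.chrom].extend(
            int(np.clip(p, 0, length - 1))
            for p in (o.pos - cfg.fork_distance, o.pos + cfg.fork_distance)
        )

    true_cn: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        merged = _merge_intervals(replicated[chrom])
        replicated[chrom] = merged
        cn = np.ones(genome.n_bins(chrom, cfg.bin_width), dtype=np.int64)
        for s, e in merged:
            b0 = s // cfg.bin_width
            b1 = (e - 1) // cfg.bin_width
            cn[b0:b1 + 1] = 2
        true_cn[chrom] = cn
        fork_positions[chrom].sort()
    return GroundTruth(fired, replicated, fork_positions, true_cn, genome,
                       cfg.bin_width, cfg.fork_distance)


def _cen_term(genome: GenomeIndex, cens: CentromereSet, cfg: SimulationConfig,
              chrom: str) -> np.ndarray:
    """cen_amplitude on bins whose centre lies within ±cen_halfwidth of the
    centromere midpoint (the same window the normalizer uses)."""
    n = genome.n_bins(chrom, cfg.bin_width)
    centers = np.arange(n) * cfg.bin_width + cfg.bin_width / 2
    out = np.zeros(n)
    out[np.abs(centers - cens.midpoint(chrom)) <= cfg.cen_halfwidth] = cfg.cen_amplitude
    return out


def expected_rate(
    truth: GroundTruth,
    cfg: SimulationConfig,
    sample_kind: str,
    cens: CentromereSet | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free per-bin Poisson rates for one sample kind.

    Exposed separately from :func:`sample_reads` so invariants about the
    signal model (e.g. tagged minus untagged is zero away from forks) can be
    checked on expectations rather than on noisy draws.
    """
    if sample_kind not in SAMPLE_KINDS:
        raise ValidationError(f"unknown sample_kind {sample_kind!r}; expected one of {SAMPLE_KINDS}")
    if sample_kind.startswith("chip") and cens is None:
        raise ValidationError(f"sample_kind {sample_kind!r} requires a CentromereSet")
    genome = truth.genome
    rates: dict[str, np.ndarray] = {}
    for chrom in genome.names:
        n = genome.n_bins(chrom, cfg.bin_width)
        if sample_kind == "G1":
            rate = np.full(n, cfg.depth_lambda)
        elif sample_kind == "S":
            rate = cfg.depth_lambda * truth.true_copy_number[chrom].astype(float)
        else:
            rate = np.full(n, cfg.chip_background) + _cen_term(genome, cens, cfg, chrom)
            if sample_kind == "chip_tagged":
                centers = np.arange(n) * cfg.bin_width + cfg.bin_width / 2
                amp = cfg.fork_enrichment * cfg.enrichment_attenuation
                if amp > 0 and cfg.peak_sigma > 0:
                    span = 5.0 * cfg.peak_sigma
                    for f in truth.fork_positions[chrom]:
                        lo = max(0, int((f - span) // cfg.bin_width))
                        hi = min(n, int((f + span) // cfg.bin_width) + 1)
                        d = (centers[lo:hi] - f) / cfg.peak_sigma
                        rate[lo:hi] += amp * np.exp(-0.5 * d * d)
        rates[chrom] = rate
    return rates


def sample_reads(
    truth: GroundTruth,
    cfg: SimulationConfig,
    sample_kind: str,
    cens: CentromereSet | None = None,
    stream: int = 0,
) -> BinnedTrack:
    """Draw one sample's per-bin Poisson counts.

    Each (seed, sample kind, stream) triple seeds an independent generator,
    so samples are independent of each other but byte-identical across runs.
    *stream* distinguishes replicate samples of the same kind (e.g. the
    wild-type and attenuated tagged ChIPs).
    """
    rates = expected_rate(truth, cfg, sample_kind, cens)
    rng = np.random.default_rng([cfg.seed, _KIND_CODE[sample_kind], stream])
    data = {c: rng.poisson(rates[c]).astype(float) for c in truth.genome.names}
    return BinnedTrack(sample_kind, cfg.bin_width, data, truth.genome)


def write_fragments_bed(track: BinnedTrack, path, seed: int = 0,
                        frag_length: int = 50) -> int:
    """Expand a binned track into BED fragments (uniform within each bin).

    Each fragment's midpoint stays inside its source bin, so
    :func:`replichip.coverage.bin_fragments` reproduces the track exactly.
    Returns the number of fragments written.
    """
    rng = np.random.default_rng([seed, 991])
    half = frag_length // 2
    n_written = 0
    with open(path, "w") as fh:
        for chrom in track.genome.names:
            length = track.genome.length(chrom)
            counts = track.data[chrom]
            for b in np.nonzero(counts > 0)[0]:
                lo = int(b) * track.bin_width
                hi = min(lo + track.bin_width, length)
                mids = rng.integers(lo, hi, size=int(counts[b]))
                for mid in mids:
                    s = int(mid) - half
                    e = s + frag_length
                    if s < 0:
                        s, e = 0, min(frag_length, length)
                    elif e > length:
                        s, e = max(0, length - frag_length), length
                    if (s + e) // 2 // track.bin_width != b:
                        s, e = int(mid), int(mid) + 1  # degenerate bin at chromosome end
                    fh.write(f"{chrom}\t{s}\t{e}\n")
                    n_written += 1
    return n_written


def write_ground_truth_tsv(truth: GroundTruth, path) -> None:
    """Sidecar TSV of fired origins and their stalled-fork positions."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tt_rep\tfire_class\tfork_left\tfork_right\n")
        for o in truth.fired:
            length = truth.genome.length(o.chrom)
            fl = max(0, o.pos - truth.fork_distance)
            fr = min(length - 1, o.pos + truth.fork_distance)
            fh.write(f"{o.chrom}\t{o.pos}\t{o.t_rep:g}\t{o.fire_class or ''}\t{fl}\t{fr}\n")


# ---------------------------------------------------------------------------
# built-in desk-scale annotation set


def demo_annotations(
    seed: int = 0,
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    n_origins: int = 60,
    t_rep_range: tuple[float, float] = (10.0, 45.0),
    late_percentile: float = 75.0,
) -> tuple[GenomeIndex, OriginSet, CentromereSet]:
    """A desk-scale genome with realistic origin spacing and timing.

    Defaults give a 2-Mb two-chromosome genome with 60 origins (one per
    ~33 kb, matching the density of budding-yeast ARS elements).
    Replication timing follows the chromosomal gradient seen in yeast:
    pericentromeric origins fire early, subtelomeric ones late, with
    origin-to-origin scatter on top, so t_rep spans early-to-late S phase
    (~10–45 min) and late/dormant origins cluster near chromosome ends —
    which is what creates runs of adjacent dormant origins and hence
    calibratable dormant regions.  Origins are classified late/dormant
    above the 75th t_rep percentile; one centromere sits mid-chromosome.
    """
    rng = np.random.default_rng([seed, 7])
    names = tuple(f"chr{_roman(i + 1)}" for i in range(n_chrom))
    genome = GenomeIndex(names, tuple([chrom_length] * n_chrom))
    per_chrom = n_origins // n_chrom
    extras = n_origins - per_chrom * n_chrom
    t_lo, t_hi = t_rep_range
    origins: list[Origin] = []
    for ci, chrom in enumerate(names):
        k = per_chrom + (1 if ci < extras else 0)
        margin = 25_000
        base = np.linspace(margin, chrom_length - margin, k)
        spacing = (chrom_length - 2 * margin) / max(k - 1, 1)
        jitter = rng.uniform(-0.25 * spacing, 0.25 * spacing, size=k)
        positions = np.sort((base + jitter).astype(int))
        # timing gradient: early near the centromere, late near telomeres
        cen_mid = chrom_length // 2
        rel = np.abs(positions - cen_mid) / (chrom_length / 2)
        t_reps = t_lo + (t_hi - t_lo - 5.0) * rel ** 2 + rng.normal(0.0, 1.2, size=k)
        t_reps = np.clip(t_reps, t_lo - 2.0, t_hi)
        for j, (p, t) in enumerate(zip(positions, t_reps)):
            origins.append(Origin(chrom, int(p), float(t), name=f"ARS_{chrom}_{j + 1}"))
    oset = OriginSet(tuple(origins), genome)
    threshold = float(np.percentile(oset.t_reps, late_percentile))
    from .annotations import classify_origins

    oset = classify_origins(oset, threshold)
    cen_halfspan = 60
    cens = CentromereSet(
        {c: (chrom_length // 2 - cen_halfspan, chrom_length // 2 + cen_halfspan)
         for c in names},
        genome,
    )
    return genome, oset, cens


def _roman(n: int) -> str:
    vals = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
            (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
            (5, "V"), (4, "IV"), (1, "I")]
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)
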
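import numpy as np
import pytest

import replichip as rc


def make_origin_set(genome, records):
    """records: iterable of (chrom, pos, t_rep[, fire_class])."""
    origins = tuple(
        rc.Origin(r[0], r[1], r[2], r[3] if len(r) > 3 else None) for r in records
    )
    return rc.OriginSet(origins, genome)


@pytest.fixture(scope="session")
def toy_genome():
    return rc.GenomeIndex(("chrA", "chrB"), (500_000, 400_000))


@pytest.fixture(scope="session")
def demo():
    """Genome, classified origins and centromeres of the built-in demo set."""
    return rc.demo_annotations(seed=1)


class SimRun:
    """One full simulated experiment with all derived products cached."""

    def __init__(self, seed, **cfg_kwargs):
        self.genome, self.origins, self.cens = rc.demo_annotations(seed=seed)
        self.dormant = rc.select_dormant_regions(self.origins, self.genome)
        self.cfg = rc.SimulationConfig(seed=seed, **cfg_kwargs)
        self.truth = rc.simulate_copy_number(self.origins, self.genome, self.cfg)
        self.g1 = rc.sample_reads(self.truth, self.cfg, "G1")
        self.s = rc.sample_reads(self.truth, self.cfg, "S")
        self.chip_wt = rc.sample_reads(self.truth, self.cfg, "chip_tagged",
                                       self.cens, stream=0)
        self.chip_mut = rc.sample_reads(
            self.truth, self.cfg.replace(enrichment_attenuation=0.1),
            "chip_tagged", self.cens, stream=1)
        self.chip_bg = rc.sample_reads(self.truth, self.cfg, "chip_untagged",
                                       self.cens, stream=1)

    def calibrated_profile(self):
        raw = rc.ratio_track(self.s, self.g1)
        return rc.calibrate_to_1n(raw, self.dormant)

    def masked_profile(self):
        return rc.apply_mask(self.calibrated_profile())

    def pooled(self, profile, copy_n):
        """Calibrated values over bins with true copy number copy_n."""
        m = self.truth.copy_mask(copy_n)
        return np.concatenate(
            [profile.values[c][m[c]] for c in self.genome.names]
        )


@pytest.fixture(scope="session")
def sim42():
    """The reference simulated run: all origins fire, forks stall at 2 kb."""
    return SimRun(seed=42)


@pytest.fixture(scope="session")
def sim_seeds():
    """Independent replicate runs for recovery-rate checks."""
    return [SimRun(seed=s) for s in range(1, 6)]
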
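import numpy as np
import pandas as pd
import pytest

import hypertad as ht


@pytest.fixture(scope="session")
def small_genome() -> ht.GenomeSpec:
    return ht.default_genome(n_chromosomes=2, chrom_length=20_000_000,
                             bin_size=25_000)


@pytest.fixture(scope="session")
def strong_tads(small_genome) -> ht.TadTruth:
    return ht.regular_tads(small_genome, domain_size=2_000_000, strength=1.0)


def hic_pipeline(genome, tads, depth=60.0, seed=1):
    """Simulate, drop short-range artifacts, balance (caICB)."""
    mats, _ = ht.simulate_hic(
        genome, tads, depth=depth, decay_exponent=1.0, tad_enrichment=3.0,
        seed=seed,
    )
    mats = {c: ht.remove_short_range(m) for c, m in mats.items()}
    return ht.balance_genome(mats, method="caicb")


@pytest.fixture(scope="session")
def balanced_hic(small_genome, strong_tads):
    return hic_pipeline(small_genome, strong_tads, seed=1)


DOSAGE_GAINS = {f"chr{i}": frac
                for frac, block in ((0.0, range(1, 5)), (0.5, range(5, 9)),
                                    (1.0, range(9, 13)))
                for i in block}


@pytest.fixture(scope="session")
def dosage_genome() -> ht.GenomeSpec:
    chroms = [ht.Chromosome(f"chr{i + 1}", 10_000_000, 2) for i in range(12)]
    return ht.GenomeSpec(chromosomes=chroms, bin_size=25_000)


@pytest.fixture(scope="session")
def dosage_sim(dosage_genome):
    """20 HeH-like vs 20 control cohort; 4 chromosomes disomic, 4 gained in
    half the HeH samples, 4 gained in all of them."""
    tads = ht.regular_tads(dosage_genome, domain_size=1_000_000, strength=1.0)
    cohort = ht.make_cohort(dosage_genome, 20, 20, gain_fractions=DOSAGE_GAINS,
                            seed=3)
    sim = ht.simulate_expression(
        dosage_genome, cohort, tads, n_genes=1200, noise_sd=0.5, seed=3
    )
    return cohort, sim, tads


def truth_boundary_set(genome, tads, strength=1.0) -> ht.BoundarySet:
    rows = [
        {"chrom": c, "position": int(p), "strength": strength, "method": "truth"}
        for c in genome.names
        for p in tads.boundaries(c)
    ]
    return ht.BoundarySet(
        sample="truth", bin_size=genome.bin_size, table=pd.DataFrame(rows)
    )


def boundary_recovery(genome, tads, called: ht.BoundarySet, tol_bp: int) -> float:
    hit = total = 0
    for c in genome.names:
        truth = tads.boundaries(c)
        pos = called.positions(c)
        for p in truth:
            total += 1
            if len(pos) and np.min(np.abs(pos - p)) <= tol_bp:
                hit += 1
    return hit / total
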
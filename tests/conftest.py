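"""Shared fixtures: exact-test oracles and simulated scenarios."""

from fractions import Fraction
from math import comb

import pytest

from methsilence.simulate import (
    SimulationConfig,
    plant_ground_truth,
    simulate_annotation,
    simulate_methylome,
)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact two-sided Fisher p by full enumeration over all tables with the
    observed margins, summing hypergeometric probabilities <= the observed
    table's (point-probability rule). Exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    denom = comb(r1 + r2, c1)
    p_obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for i in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = Fraction(comb(r1, i) * comb(r2, c1 - i), denom)
        if p <= p_obs:
            total += p
    return total


def hypergeom_upper_tail_oracle(k: int, K: int, n: int, N: int) -> Fraction:
    """Exact upper-tail hypergeometric probability by direct summation with
    integer binomials."""
    denom = comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), denom)
    return total


def small_config(seed: int = 3) -> SimulationConfig:
    """A fast, fully planted scenario for pipeline-level tests."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=1,
        chromosome_length=60_000,
        n_genes=20,
        n_tes=30,
        n_dmrs_suvh29=8,
        n_dmrs_shared=3,
        n_dmrs_morc6_specific=2,
        n_up_tes={"suvh29": 6, "morc6": 6},
        n_up_tes_shared=2,
        n_up_genes={"suvh29": 4, "morc6": 5},
        n_up_genes_shared=1,
        n_meth_promoter_genes=6,
    )


class StudyScenario:
    """Lazily simulated default scenario (default config, seed 1)."""

    def __init__(self):
        self.config = SimulationConfig(seed=1)
        self.annotation = simulate_annotation(self.config)
        self.truth = plant_ground_truth(self.config, self.annotation)
        self._methylomes: dict = {}

    def methylome(self, genotype: str):
        if genotype not in self._methylomes:
            self._methylomes[genotype] = simulate_methylome(
                self.config, self.annotation, self.truth, genotype
            )
        return self._methylomes[genotype]


@pytest.fixture(scope="session")
def study_scenario() -> StudyScenario:
    return StudyScenario()
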
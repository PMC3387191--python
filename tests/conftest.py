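import numpy as np
import pytest

from prediagrs import SimulationConfig, build_analysis_table, default_panel, generate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def cohort(panel):
    """One default synthetic cohort (n=1442, seed 0): (genotypes, phenotypes, truth)."""
    return generate_cohort(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def analysis_table(panel, cohort):
    gm, phen, _ = cohort
    table, info = build_analysis_table(gm, phen, panel)
    return table


def hwe_enumeration_oracle(n_hom1: int, n_het: int, n_hom2: int):
    """Exact-rational HWE p-value by full enumeration over heterozygote counts.

    Conditions on the allele totals; uses integer multinomial arithmetic
    (fractions), fully independent of the package implementation.
    """
    from fractions import Fraction
    from math import factorial

    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het  # allele-1 count
    n_rare = min(n_a, 2 * n - n_a)
    probs = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        if hom_common < 0:
            continue
        probs[h] = Fraction(
            factorial(n) * 2**h,
            factorial(hom_rare) * factorial(h) * factorial(hom_common),
        )
    total = sum(probs.values())
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs) / total)
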
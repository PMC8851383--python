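import numpy as np
import pytest

from sexlink import (
    GenotypeMatrix,
    PresenceMatrix,
    Sex,
    SexRegistry,
    SyntheticConfig,
    simulate_dataset,
)
from sexlink.codes import ABSENT, ALT_HOM, HET, MISSING, PRESENT, REF_HOM


@pytest.fixture
def registry_15_15() -> SexRegistry:
    sexes = {f"M{i:03d}": Sex.MALE for i in range(1, 16)}
    sexes |= {f"F{i:03d}": Sex.FEMALE for i in range(1, 16)}
    return SexRegistry(sexes)


@pytest.fixture
def individual_ids_15_15(registry_15_15) -> list[str]:
    return list(registry_15_15.sexes)


def make_snp_matrix(rows: list[list[int]], individual_ids: list[str],
                    prefix: str = "SNP") -> GenotypeMatrix:
    return GenotypeMatrix(
        [f"{prefix}{i + 1:04d}" for i in range(len(rows))],
        list(individual_ids),
        np.array(rows, dtype=np.int8),
    )


def make_pa_matrix(rows: list[list[int]], individual_ids: list[str],
                   prefix: str = "PA") -> PresenceMatrix:
    return PresenceMatrix(
        [f"{prefix}{i + 1:04d}" for i in range(len(rows))],
        list(individual_ids),
        np.array(rows, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def xy_dataset():
    """Fully penetrant XY cohort: 5 planted male-linked loci per class
    among 2,000 loci, no missingness."""
    cfg = SyntheticConfig(
        n_snp_loci=2000, n_pa_loci=2000, architecture="XY",
        n_planted_male_linked=5, penetrance=1.0, leakage=0.0,
        missing_rate=0.0, seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def psd_dataset():
    """Mixed-architecture cohort: male- and female-linked loci at
    intermediate penetrance with some leakage and missingness."""
    cfg = SyntheticConfig(
        n_snp_loci=1000, n_pa_loci=1000, architecture="PSD",
        n_planted_male_linked=3, n_planted_female_linked=4,
        penetrance=0.85, leakage=0.1, missing_rate=0.05, seed=7,
    )
    return simulate_dataset(cfg)
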
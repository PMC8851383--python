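"""Synthetic DArT-style cohort generator with planted sex-linked loci.

The generator emulates the study design this package targets: a cohort of
~15 phenotyped males and ~15 females genotyped for codominant SNP and
dominant presence/absence (PA) markers, with a handful of loci tied to a
male-heterogametic (XY), female-heterogametic (ZW) or mixed polygenic
(PSD) sex-determination architecture planted among a large background of
sex-independent loci.

Planted-locus model
-------------------
At a male-linked SNP locus the Y-borne allele shows up as heterozygosity:
each male is HET with probability ``penetrance`` and REF_HOM otherwise;
each female is HET with probability ``leakage`` (X-Y recombination leak)
and REF_HOM otherwise.  ALT_HOM is never generated at planted loci — the
linked allele sits on one sex chromosome.  A male-linked PA locus is
PRESENT in males with probability ``penetrance`` and in females with
probability ``leakage``.  Female-linked loci mirror the rule with the
sexes swapped.  Background SNP loci draw a per-locus allele frequency
from a Beta law and genotype individuals under Hardy-Weinberg
independently of sex; background PA loci draw a per-locus presence
probability the same way.  Missingness then overwrites any cell i.i.d.

All randomness flows from one seed; each variable stream (SNP calls, PA
calls, missingness, metadata, tags) uses its own deterministically
derived substream, so e.g. adding PA loci never perturbs the SNP draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as dart_io
from .codes import (
    ABSENT,
    HET,
    MISSING,
    PRESENT,
    REF_HOM,
    GenotypeMatrix,
    MarkerMetadata,
    PresenceMatrix,
    Sex,
    SexRegistry,
)

ARCHITECTURES = ("XY", "ZW", "PSD", "NULL")

MALE_LINKED = "MALE_LINKED"
FEMALE_LINKED = "FEMALE_LINKED"
BACKGROUND = "BACKGROUND"

_TAG_LENGTH = 30

# substream spawn keys — fixed so streams stay independent of each other
_STREAM_SNP, _STREAM_PA, _STREAM_MISS_SNP, _STREAM_MISS_PA = 0, 1, 2, 3
_STREAM_META_SNP, _STREAM_META_PA, _STREAM_PARENT, _STREAM_OFFSPRING = 4, 5, 6, 7


@dataclass
class QCProfile:
    """Uniform ranges the metadata fields are drawn from."""

    reproducibility: tuple[float, float] = (0.95, 1.0)
    read_depth_snp: tuple[float, float] = (5.0, 40.0)
    read_depth_pa: tuple[float, float] = (7.0, 40.0)


@dataclass
class SyntheticConfig:
    """Full specification of one simulated cohort.

    Defaults describe the reference study design: 15 + 15 individuals, an
    XY architecture with 5 planted fully penetrant male-linked loci, a
    Beta(2, 2) background allele-frequency law and 5% missingness.  Locus
    counts default to 2,000 per class, a desk-scale stand-in for the
    ~50k-per-class panels a DArTseq run yields.
    """

    n_males: int = 15
    n_females: int = 15
    n_snp_loci: int = 2000
    n_pa_loci: int = 2000
    architecture: str = "XY"
    n_planted_male_linked: int = 5
    n_planted_female_linked: int = 0
    penetrance: float = 1.0
    leakage: float = 0.0
    background_allele_freq_law: tuple[float, float] = (2.0, 2.0)
    missing_rate: float = 0.05
    qc_profile: QCProfile = field(default_factory=QCProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_males < 1 or self.n_females < 1:
            raise ValueError("need at least one individual of each sex")
        if min(self.n_snp_loci, self.n_pa_loci) < 0:
            raise ValueError("locus counts must be nonnegative")
        if not 0.0 < self.penetrance <= 1.0:
            raise ValueError("penetrance must be in (0, 1]")
        if not 0.0 <= self.leakage < 1.0:
            raise ValueError("leakage must be in [0, 1)")
        if self.penetrance <= self.leakage:
            raise ValueError("penetrance must exceed leakage")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.architecture in ("XY", "NULL") and self.n_planted_female_linked:
            raise ValueError(f"{self.architecture} plants no female-linked loci")
        if self.architecture in ("ZW", "NULL") and self.n_planted_male_linked:
            raise ValueError(f"{self.architecture} plants no male-linked loci")
        n_planted = self.n_planted_male_linked + self.n_planted_female_linked
        # planted loci are split across both marker classes
        if self.n_snp_loci and n_planted > self.n_snp_loci:
            raise ValueError("more planted loci than SNP loci")
        if self.n_pa_loci and n_planted > self.n_pa_loci:
            raise ValueError("more planted loci than PA loci")
        a, b = self.background_allele_freq_law
        if a <= 0 or b <= 0:
            raise ValueError("Beta law parameters must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "qc_profile" in d and isinstance(d["qc_profile"], dict):
            d["qc_profile"] = QCProfile(**{k: tuple(v) for k, v in d["qc_profile"].items()})
        if "background_allele_freq_law" in d:
            d["background_allele_freq_law"] = tuple(d["background_allele_freq_law"])
        return cls(**d)


@dataclass
class TruthTable:
    """Ground-truth role of every generated locus."""

    roles: dict[str, str]

    def loci_with_role(self, role: str) -> list[str]:
        return [l for l, r in self.roles.items() if r == role]


@dataclass
class SimulatedDataset:
    snp: GenotypeMatrix
    pa: PresenceMatrix
    snp_metadata: list[MarkerMetadata]
    pa_metadata: list[MarkerMetadata]
    registry: SexRegistry
    truth: TruthTable
    config: SyntheticConfig


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(key,))))


def _planted_calls(
    rng: np.random.Generator,
    n_loci: int,
    is_male: np.ndarray,
    male_linked: bool,
    penetrance: float,
    leakage: float,
    carrier_code: int,
    noncarrier_code: int,
) -> np.ndarray:
    """Locus x individual planted calls under the penetrance/leakage model."""
    het_sex = is_male if male_linked else ~is_male
    prob = np.where(het_sex, penetrance, leakage)
    carrier = rng.random((n_loci, is_male.size)) < prob
    return np.where(carrier, carrier_code, noncarrier_code).astype(np.int8)


def _background_snp(rng: np.random.Generator, n_loci: int, n_ind: int, law: tuple[float, float]) -> np.ndarray:
    p = rng.beta(law[0], law[1], size=n_loci)
    dosage = rng.binomial(2, p[:, None], size=(n_loci, n_ind))
    return np.select([dosage == 0, dosage == 1], [REF_HOM, HET], default=np.int8(1)).astype(np.int8)


def _background_pa(rng: np.random.Generator, n_loci: int, n_ind: int, law: tuple[float, float]) -> np.ndarray:
    q = rng.beta(law[0], law[1], size=n_loci)
    present = rng.random((n_loci, n_ind)) < q[:, None]
    return np.where(present, PRESENT, ABSENT).astype(np.int8)


def _apply_missing(rng: np.random.Generator, calls: np.ndarray, rate: float) -> np.ndarray:
    if rate > 0:
        mask = rng.random(calls.shape) < rate
        calls = np.where(mask, np.int8(MISSING), calls)
    return calls.astype(np.int8)


def _random_tags(rng: np.random.Generator, n: int) -> list[str]:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    raw = lut[rng.integers(0, 4, size=(n, _TAG_LENGTH))].tobytes()
    return [raw[i * _TAG_LENGTH:(i + 1) * _TAG_LENGTH].decode("ascii") for i in range(n)]


def _metadata(
    rng: np.random.Generator,
    locus_ids: list[str],
    calls: np.ndarray,
    profile_repro: tuple[float, float],
    profile_depth: tuple[float, float],
) -> list[MarkerMetadata]:
    n = len(locus_ids)
    repro = rng.uniform(*profile_repro, size=n)
    depth = rng.uniform(*profile_depth, size=n)
    tags = _random_tags(rng, n)
    call_rates = (calls != MISSING).mean(axis=1)
    return [
        MarkerMetadata(locus_ids[i], round(float(repro[i]), 4), round(float(call_rates[i]), 4),
                       round(float(depth[i]), 2), tags[i])
        for i in range(n)
    ]


def _class_calls(
    cfg: SyntheticConfig,
    is_male: np.ndarray,
    n_loci: int,
    snp: bool,
    rng_calls: np.random.Generator,
    rng_miss: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Build one marker class: planted male-linked, planted female-linked,
    then background loci, in that fixed order."""
    n_m = cfg.n_planted_male_linked if n_loci else 0
    n_f = cfg.n_planted_female_linked if n_loci else 0
    carrier = HET if snp else PRESENT
    noncarrier = REF_HOM if snp else ABSENT
    blocks, roles = [], []
    if n_m:
        blocks.append(_planted_calls(rng_calls, n_m, is_male, True, cfg.penetrance, cfg.leakage, carrier, noncarrier))
        roles += [MALE_LINKED] * n_m
    if n_f:
        blocks.append(_planted_calls(rng_calls, n_f, is_male, False, cfg.penetrance, cfg.leakage, carrier, noncarrier))
        roles += [FEMALE_LINKED] * n_f
    n_bg = n_loci - n_m - n_f
    if n_bg:
        maker = _background_snp if snp else _background_pa
        blocks.append(maker(rng_calls, n_bg, is_male.size, cfg.background_allele_freq_law))
        roles += [BACKGROUND] * n_bg
    calls = np.vstack(blocks) if blocks else np.empty((0, is_male.size), dtype=np.int8)
    calls = _apply_missing(rng_miss, calls, cfg.missing_rate)
    return calls, roles


def simulate_dataset(config: SyntheticConfig) -> SimulatedDataset:
    """Generate a full cohort: SNP + PA matrices, metadata, registry, truth.

    Identical (seed, config) pairs yield bit-identical outputs.
    """
    cfg = config
    n_ind = cfg.n_males + cfg.n_females
    individual_ids = [f"M{i + 1:03d}" for i in range(cfg.n_males)] + [
        f"F{i + 1:03d}" for i in range(cfg.n_females)
    ]
    is_male = np.array([True] * cfg.n_males + [False] * cfg.n_females)
    registry = SexRegistry(
        {i: (Sex.MALE if m else Sex.FEMALE) for i, m in zip(individual_ids, is_male)}
    )

    snp_calls, snp_roles = _class_calls(
        cfg, is_male, cfg.n_snp_loci, True,
        _stream(cfg.seed, _STREAM_SNP), _stream(cfg.seed, _STREAM_MISS_SNP),
    )
    pa_calls, pa_roles = _class_calls(
        cfg, is_male, cfg.n_pa_loci, False,
        _stream(cfg.seed, _STREAM_PA), _stream(cfg.seed, _STREAM_MISS_PA),
    )

    snp_ids = [f"SNP{i + 1:06d}" for i in range(cfg.n_snp_loci)]
    pa_ids = [f"PA{i + 1:06d}" for i in range(cfg.n_pa_loci)]
    snp = GenotypeMatrix(snp_ids, individual_ids, snp_calls.reshape(cfg.n_snp_loci, n_ind))
    pa = PresenceMatrix(pa_ids, individual_ids, pa_calls.reshape(cfg.n_pa_loci, n_ind))

    prof = cfg.qc_profile
    snp_meta = _metadata(_stream(cfg.seed, _STREAM_META_SNP), snp_ids, snp.calls,
                         prof.reproducibility, prof.read_depth_snp)
    pa_meta = _metadata(_stream(cfg.seed, _STREAM_META_PA), pa_ids, pa.calls,
                        prof.reproducibility, prof.read_depth_pa)

    truth = TruthTable(dict(zip(snp_ids, snp_roles)) | dict(zip(pa_ids, pa_roles)))
    return SimulatedDataset(snp, pa, snp_meta, pa_meta, registry, truth, cfg)


def simulate_parent_offspring_pair(
    config: SyntheticConfig,
    overlap_fraction: float,
    offspring_config: SyntheticConfig | None = None,
) -> tuple[SimulatedDataset, SimulatedDataset, set[str]]:
    """Generate a "parent" and an "offspring" cohort sharing marker tags.

    Exactly ``floor(overlap_fraction * n_parent_loci)`` parent loci (taken
    from the head of the combined SNP + PA locus list) reuse their tag
    sequence verbatim in the offspring dataset, emulating markers carried
    across a cross; sex-linkage roles stay independent per dataset.
    Returns ``(parent, offspring, shared_tags)``.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    parent = simulate_dataset(replace(config, seed=_derived_seed(config.seed, _STREAM_PARENT)))
    off_cfg = offspring_config if offspring_config is not None else config
    offspring = simulate_dataset(replace(off_cfg, seed=_derived_seed(config.seed, _STREAM_OFFSPRING)))

    parent_meta = parent.snp_metadata + parent.pa_metadata
    offspring_meta = offspring.snp_metadata + offspring.pa_metadata
    n_shared = math.floor(overlap_fraction * len(parent_meta))
    if n_shared > len(offspring_meta):
        raise ValueError("offspring dataset has too few loci to host the shared tags")
    shared: set[str] = set()
    for p_meta, o_meta in zip(parent_meta[:n_shared], offspring_meta[:n_shared]):
        o_meta.tag_sequence = p_meta.tag_sequence
        shared.add(p_meta.tag_sequence)
    return parent, offspring, shared


def _derived_seed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(seed, spawn_key=(key,)).generate_state(1)[0] % (2**31 - 1))


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the canonical CSV/TSV files plus the truth table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "snp": outdir / "snp_report.csv",
        "pa": outdir / "pa_report.csv",
        "registry": outdir / "sex_registry.tsv",
        "truth": outdir / "truth.tsv",
    }
    dart_io.write_genotype_report(dataset.snp, dataset.snp_metadata, paths["snp"])
    dart_io.write_genotype_report(dataset.pa, dataset.pa_metadata, paths["pa"])
    dart_io.write_sex_registry(dataset.registry, paths["registry"])
    with paths["truth"].open("w", encoding="utf-8") as fh:
        fh.write("locus_id\trole\n")
        for locus, role in dataset.truth.roles.items():
            fh.write(f"{locus}\t{role}\n")
    return paths
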
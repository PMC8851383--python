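"""Cell-code alphabets and core typed containers.

DArT-style reports score codominant SNP calls as 0 (reference homozygote,
the most common allele), 1 (alternate homozygote), 2 (heterozygote) and
"-" for the double-null/missing state.  Dominant presence/absence (PA,
silicoDArT) calls are 1 (fragment present), 0 (absent) and "-" for a
putative heterozygote, which this package treats as missing throughout.

Internally every call matrix is a locus x individual ``int8`` array using
the integer codes below; ``MISSING`` is -1 for both marker classes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import ClassVar

import numpy as np

# SNP call codes (match the DArT report digits where possible)
REF_HOM: int = 0
ALT_HOM: int = 1
HET: int = 2

# PA call codes
ABSENT: int = 0
PRESENT: int = 1

MISSING: int = -1

SNP_CODES = frozenset({REF_HOM, ALT_HOM, HET, MISSING})
PA_CODES = frozenset({ABSENT, PRESENT, MISSING})

SNP_CODE_LABELS = {REF_HOM: "REF_HOM", ALT_HOM: "ALT_HOM", HET: "HET", MISSING: "MISSING"}
PA_CODE_LABELS = {ABSENT: "ABSENT", PRESENT: "PRESENT", MISSING: "MISSING"}


class MarkerClass(str, enum.Enum):
    """Codominant SNP markers vs dominant presence/absence markers."""

    SNP = "SNP"
    PA = "PA"


class Sex(str, enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class Hypothesis(str, enum.Enum):
    """Which sex is heterogametic: XY (males) or ZW (females)."""

    XY = "XY"
    ZW = "ZW"

    @property
    def heterogametic_sex(self) -> Sex:
        return Sex.MALE if self is Hypothesis.XY else Sex.FEMALE


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class _CallMatrix:
    """Base locus x individual call grid.

    ``calls[i, j]`` is the code of locus ``locus_ids[i]`` in individual
    ``individual_ids[j]``.
    """

    locus_ids: list[str]
    individual_ids: list[str]
    calls: np.ndarray

    _ALPHABET: ClassVar[frozenset] = frozenset()
    marker_class: ClassVar[MarkerClass]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.locus_ids), len(self.individual_ids)):
            raise ValueError(
                f"call grid shape {self.calls.shape} does not match "
                f"{len(self.locus_ids)} loci x {len(self.individual_ids)} individuals"
            )
        _check_unique(self.locus_ids, "locus")
        _check_unique(self.individual_ids, "individual")
        bad = ~np.isin(self.calls, list(self._ALPHABET))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid code {self.calls[i, j]} at locus {self.locus_ids[i]!r}, "
                f"individual {self.individual_ids[j]!r}"
            )

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def locus_index(self, locus_id: str) -> int:
        return self.locus_ids.index(locus_id)

    def subset_loci(self, locus_ids: list[str]) -> "_CallMatrix":
        idx = [self.locus_ids.index(l) for l in locus_ids]
        return type(self)(list(locus_ids), list(self.individual_ids), self.calls[idx])

    def call_rates(self) -> np.ndarray:
        """Per-locus fraction of non-missing calls (the DArT call rate)."""
        return (self.calls != MISSING).mean(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, type(self)):
            return NotImplemented
        return (
            self.locus_ids == other.locus_ids
            and self.individual_ids == other.individual_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(eq=False)
class GenotypeMatrix(_CallMatrix):
    """Codominant SNP calls over {REF_HOM, ALT_HOM, HET, MISSING}."""

    _ALPHABET: ClassVar[frozenset] = SNP_CODES
    marker_class: ClassVar[MarkerClass] = MarkerClass.SNP


@dataclass(eq=False)
class PresenceMatrix(_CallMatrix):
    """Dominant PA calls over {PRESENT, ABSENT, MISSING}."""

    _ALPHABET: ClassVar[frozenset] = PA_CODES
    marker_class: ClassVar[MarkerClass] = MarkerClass.PA


@dataclass
class MarkerMetadata:
    """Per-marker quality metadata shipped alongside a DArT report."""

    locus_id: str
    reproducibility: float
    call_rate: float
    mean_read_depth: float
    tag_sequence: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.reproducibility <= 1.0:
            raise ValueError(f"{self.locus_id}: reproducibility {self.reproducibility} not in [0,1]")
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError(f"{self.locus_id}: call_rate {self.call_rate} not in [0,1]")
        if self.mean_read_depth < 0:
            raise ValueError(f"{self.locus_id}: negative read depth {self.mean_read_depth}")
        if set(self.tag_sequence.upper()) - set("ACGTN"):
            raise ValueError(f"{self.locus_id}: tag sequence has non-DNA characters")


@dataclass
class SexRegistry:
    """Phenotypic-sex assignment for every genotyped individual."""

    sexes: dict[str, Sex] = field(default_factory=dict)

    def __getitem__(self, individual_id: str) -> Sex:
        return self.sexes[individual_id]

    def __len__(self) -> int:
        return len(self.sexes)

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.sexes

    @property
    def males(self) -> list[str]:
        return [i for i, s in self.sexes.items() if s is Sex.MALE]

    @property
    def females(self) -> list[str]:
        return [i for i, s in self.sexes.items() if s is Sex.FEMALE]

    def is_male_vector(self, individual_ids: list[str]) -> np.ndarray:
        """Boolean mask aligned with ``individual_ids``; errors on unknowns.

        Individuals missing from the registry are a hard error rather than
        being dropped, so a mislabelled cohort cannot silently distort the
        sex ratio a scan sees.
        """
        missing = [i for i in individual_ids if i not in self.sexes]
        if missing:
            raise KeyError(f"individuals absent from sex registry: {missing}")
        return np.array([self.sexes[i] is Sex.MALE for i in individual_ids], dtype=bool)

    def swapped(self) -> "SexRegistry":
        """Registry with every male relabelled female and vice versa."""
        flip = {Sex.MALE: Sex.FEMALE, Sex.FEMALE: Sex.MALE}
        return SexRegistry({i: flip[s] for i, s in self.sexes.items()})
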
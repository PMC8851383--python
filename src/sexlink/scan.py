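"""Sex-linkage scan: classify loci as perfectly or moderately sex-linked.

Under the XY hypothesis males are heterogametic, so a Y-linked SNP allele
shows up as heterozygosity (or, with X-Y recombination, alternate
homozygosity) enriched in males, and a Y-linked PA fragment as presence
enriched in males; under ZW the same logic applies to females.  The
"x:y" criterion tiers (70:30, 80:20, 90:10, 100:0) are read as: the
carrier fraction among scored heterogametic-sex individuals is at least
x% AND the carrier fraction in the other sex is at most y% = (100 - x)%.
A locus passing at 100:0 is PERFECTLY sex-linked; one passing only at a
70-90% tier is MODERATELY sex-linked.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .codes import (
    ABSENT,
    ALT_HOM,
    HET,
    MISSING,
    PRESENT,
    REF_HOM,
    Hypothesis,
    MarkerClass,
    SexRegistry,
)

logger = logging.getLogger(__name__)

DEFAULT_TIERS = (0.70, 0.80, 0.90, 1.00)


class CarrierState(str, enum.Enum):
    CARRIER = "CARRIER"
    NONCARRIER = "NONCARRIER"
    MISSING = "MISSING"


class LinkageClass(str, enum.Enum):
    PERFECT = "PERFECT"
    MODERATE = "MODERATE"
    NONE = "NONE"
    UNSCORABLE = "UNSCORABLE"


@dataclass(frozen=True)
class LinkageCriterion:
    hypothesis: Hypothesis
    tier: float
    marker_class: MarkerClass

    def __post_init__(self) -> None:
        if not 0.0 < self.tier <= 1.0:
            raise ValueError(f"tier {self.tier} not in (0, 1]")

    @property
    def label(self) -> str:
        """The field's "x:y" notation, heterogametic sex first."""
        return f"{round(self.tier * 100)}:{round((1 - self.tier) * 100)}"


@dataclass
class ScanResult:
    locus_id: str
    criterion: LinkageCriterion
    carrier_fraction_het_sex: float | None
    carrier_fraction_hom_sex: float | None
    linkage_class: LinkageClass
    n_scored_males: int
    n_scored_females: int

    @property
    def is_candidate(self) -> bool:
        return self.linkage_class in (LinkageClass.PERFECT, LinkageClass.MODERATE)


def carrier_state(call: int, marker_class: MarkerClass | str,
                  hypothesis: Hypothesis | str = Hypothesis.XY) -> CarrierState:
    """Map one call to CARRIER / NONCARRIER / MISSING.

    The rule is identical under XY and ZW — the hypothesis decides which
    sex must be enriched for carriers, not what a carrier is.  ALT_HOM
    counts as a carrier: with recombining sex chromosomes the
    heterogametic sex can be homozygous for the linked allele.
    """
    marker_class = MarkerClass(marker_class)
    if call == MISSING:
        return CarrierState.MISSING
    if marker_class is MarkerClass.SNP:
        return CarrierState.CARRIER if call in (HET, ALT_HOM) else CarrierState.NONCARRIER
    return CarrierState.CARRIER if call == PRESENT else CarrierState.NONCARRIER


def _carrier_matrix(calls: np.ndarray, marker_class: MarkerClass) -> np.ndarray:
    """Float matrix: 1 carrier, 0 noncarrier, NaN missing."""
    if MarkerClass(marker_class) is MarkerClass.SNP:
        carrier = np.isin(calls, (HET, ALT_HOM))
    else:
        carrier = calls == PRESENT
    out = carrier.astype(float)
    out[calls == MISSING] = np.nan
    return out


def _classify(f_het: float, f_hom: float, tier: float) -> LinkageClass:
    # 1e-12 guards the >= / <= comparisons against float representation of
    # tiers like 0.7 (10.5/15 vs 0.7 differ in the last ulp)
    if f_het >= tier - 1e-12 and f_hom <= 1.0 - tier + 1e-12:
        return LinkageClass.PERFECT if tier == 1.0 else LinkageClass.MODERATE
    return LinkageClass.NONE


def scan_locus(calls: np.ndarray, is_male: np.ndarray, criterion: LinkageCriterion,
               locus_id: str = "") -> ScanResult:
    """Evaluate one locus against one criterion.

    Fractions are computed over scored (non-missing) individuals only; a
    sex with no scored individual makes the locus UNSCORABLE.
    """
    carrier = _carrier_matrix(np.asarray(calls).reshape(1, -1),
                              criterion.marker_class)[0]
    male_scored = ~np.isnan(carrier[is_male])
    female_scored = ~np.isnan(carrier[~is_male])
    n_m, n_f = int(male_scored.sum()), int(female_scored.sum())
    if n_m == 0 or n_f == 0:
        return ScanResult(locus_id, criterion, None, None, LinkageClass.UNSCORABLE, n_m, n_f)
    f_male = float(np.nanmean(carrier[is_male]))
    f_female = float(np.nanmean(carrier[~is_male]))
    if criterion.hypothesis is Hypothesis.XY:
        f_het, f_hom = f_male, f_female
    else:
        f_het, f_hom = f_female, f_male
    return ScanResult(locus_id, criterion, f_het, f_hom,
                      _classify(f_het, f_hom, criterion.tier), n_m, n_f)


def scan_dataset(matrix, registry: SexRegistry,
                 criteria: list[LinkageCriterion]):
    """Evaluate every locus against every criterion.

    Returns ``(results, counts)`` where ``counts`` maps
    ``(hypothesis, tier, marker_class)`` to the number of candidate
    (PERFECT or MODERATE) loci.  Results are ordered by
    (locus_id, hypothesis, tier); UNSCORABLE loci are excluded from the
    candidate counts.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty matrix")
    is_male = registry.is_male_vector(matrix.individual_ids)
    if not is_male.any() or is_male.all():
        raise ValueError("scan requires at least one individual of each sex")

    carrier = _carrier_matrix(matrix.calls, criteria[0].marker_class if criteria else MarkerClass.SNP)
    results: list[ScanResult] = []
    counts: dict[tuple[str, float, str], int] = {}
    n_m_scored = (~np.isnan(carrier[:, is_male])).sum(axis=1)
    n_f_scored = (~np.isnan(carrier[:, ~is_male])).sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        f_male = np.nanmean(carrier[:, is_male], axis=1)
        f_female = np.nanmean(carrier[:, ~is_male], axis=1)

    for criterion in criteria:
        if MarkerClass(criterion.marker_class) is not matrix.marker_class:
            continue
        key = (criterion.hypothesis.value, criterion.tier, criterion.marker_class.value)
        counts[key] = 0
        f_het = f_male if criterion.hypothesis is Hypothesis.XY else f_female
        f_hom = f_female if criterion.hypothesis is Hypothesis.XY else f_male
        for i, locus_id in enumerate(matrix.locus_ids):
            if n_m_scored[i] == 0 or n_f_scored[i] == 0:
                results.append(ScanResult(locus_id, criterion, None, None,
                                          LinkageClass.UNSCORABLE,
                                          int(n_m_scored[i]), int(n_f_scored[i])))
                continue
            cls = _classify(float(f_het[i]), float(f_hom[i]), criterion.tier)
            results.append(ScanResult(locus_id, criterion, float(f_het[i]), float(f_hom[i]),
                                      cls, int(n_m_scored[i]), int(n_f_scored[i])))
            if cls in (LinkageClass.PERFECT, LinkageClass.MODERATE):
                counts[key] += 1

    results.sort(key=lambda r: (r.locus_id, r.criterion.hypothesis.value, r.criterion.tier))
    logger.info("scanned %d loci x %d criteria; candidate counts: %s",
                matrix.n_loci, len(criteria), counts)
    return results, counts


def scan_counts(matrix, registry: SexRegistry, criteria: list[LinkageCriterion]):
    """Vectorised candidate counting for large panels.

    Same classification rule as :func:`scan_dataset` but returns only
    ``(counts, candidate_indices)`` — per-criterion candidate totals and
    the locus index arrays behind them — without materialising a
    ScanResult per (locus, criterion).  Suitable for panels of 1e6+ loci.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty matrix")
    is_male = registry.is_male_vector(matrix.individual_ids)
    if not is_male.any() or is_male.all():
        raise ValueError("scan requires at least one individual of each sex")
    carrier = _carrier_matrix(matrix.calls, matrix.marker_class)
    male_part, female_part = carrier[:, is_male], carrier[:, ~is_male]
    scorable = (~np.isnan(male_part)).any(axis=1) & (~np.isnan(female_part)).any(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f_male = np.nanmean(male_part, axis=1)
        f_female = np.nanmean(female_part, axis=1)

    counts: dict[tuple[str, float, str], int] = {}
    candidate_indices: dict[tuple[str, float, str], np.ndarray] = {}
    for criterion in criteria:
        if MarkerClass(criterion.marker_class) is not matrix.marker_class:
            continue
        f_het = f_male if criterion.hypothesis is Hypothesis.XY else f_female
        f_hom = f_female if criterion.hypothesis is Hypothesis.XY else f_male
        t = criterion.tier
        cand = scorable & (f_het >= t - 1e-12) & (f_hom <= 1.0 - t + 1e-12)
        key = (criterion.hypothesis.value, t, criterion.marker_class.value)
        counts[key] = int(cand.sum())
        candidate_indices[key] = np.flatnonzero(cand)
    return counts, candidate_indices


def default_criteria(marker_class: MarkerClass | str,
                     hypotheses: tuple[Hypothesis, ...] = (Hypothesis.XY, Hypothesis.ZW),
                     tiers: tuple[float, ...] = DEFAULT_TIERS) -> list[LinkageCriterion]:
    marker_class = MarkerClass(marker_class)
    return [LinkageCriterion(Hypothesis(h), t, marker_class) for h in hypotheses for t in tiers]


@dataclass
class MatchResult:
    n_a: int
    n_b: int
    shared: set[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def match_candidate_loci(tags_a: list[str], tags_b: list[str]) -> MatchResult:
    """Cross-dataset candidate matching by exact tag-sequence identity.

    Matching is case-insensitive; empty tags are skipped with a warning.
    """
    def clean(tags: list[str], name: str) -> set[str]:
        out = set()
        n_empty = 0
        for t in tags:
            if not t:
                n_empty += 1
                continue
            out.add(t.upper())
        if n_empty:
            warnings.warn(f"{n_empty} empty tag(s) skipped in {name}", stacklevel=3)
        return out

    a, b = clean(tags_a, "tags_a"), clean(tags_b, "tags_b")
    return MatchResult(len(a), len(b), a & b)
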
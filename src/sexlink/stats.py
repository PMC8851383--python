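"""Association statistics and the spurious-linkage probability model.

Covers the per-locus and cross-criterion statistics used in a sex-linked
marker screen: the Cochran-Armitage trend test (CATT) between genotype
category and phenotypic sex, Pearson chi-square goodness-of-fit and
homogeneity tests, polymorphism information content (PIC), per-individual
heterozygosity profiles, the Kruskal-Wallis test with a Nemenyi
chi-square post-hoc, and the binomial model for how many loci are
expected to look perfectly sex-linked purely by chance.

Spurious-linkage model
----------------------
With n sexed individuals, a sex-independent biallelic locus mimics a
perfectly sex-linked pattern when every individual independently lands on
the "right" side (probability 1/2 each, e.g. every female homozygous and
every male heterozygous), so P_i = 0.5**n per locus and the expected
number of spurious hits over L loci is L * 0.5**n.  At n = 30 this is
9.31e-10 per locus — vanishingly small even for ~1e5 loci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .codes import ABSENT, ALT_HOM, HET, MISSING, PRESENT, REF_HOM, MarkerClass, SexRegistry

SNP_WEIGHTS = (0.0, 1.0, 2.0)  # REF_HOM, HET, ALT_HOM dosage scores
PA_WEIGHTS = (0.0, 1.0)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: int
    method: str
    degenerate: bool = False


# ---------------------------------------------------------------- CATT

def catt(counts: np.ndarray, weights: tuple[float, ...] | None = None) -> TestResult:
    """Cochran-Armitage trend test on a 2 x k table.

    ``counts[0]`` is the case row (one sex), ``counts[1]`` the other;
    columns are ordered genotype/presence categories scored by
    ``weights`` (default dosage scores (0,1,2) for k=3, (0,1) for k=2).
    The statistic uses the N-scaled variance form

        T = N [N Σw_i r_i − R Σw_i n_i]² /
            { R (N−R) [N Σw_i² n_i − (Σw_i n_i)²] }

    with R the case-row total, r_i its per-category counts and n_i the
    column totals; T is referred to chi-square with 1 df.  A zero
    variance (all mass in one category) is DEGENERATE with p = 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 2:
        raise ValueError("counts must be a 2 x k table")
    if (counts < 0).any():
        raise ValueError("negative counts")
    k = counts.shape[1]
    if weights is None:
        weights = SNP_WEIGHTS if k == 3 else PA_WEIGHTS
    w = np.asarray(weights, dtype=float)
    if w.size != k:
        raise ValueError("weights length must match number of categories")
    if not (np.diff(w) > 0).all():
        raise ValueError("weights must be strictly increasing")

    n_i = counts.sum(axis=0)
    r_i = counts[0]
    N = counts.sum()
    R = r_i.sum()
    if N < 2 or (n_i > 0).sum() < 2 or R == 0 or R == N:
        return TestResult(0.0, 1.0, 1, "CATT", degenerate=True)
    var_term = N * (w**2 @ n_i) - (w @ n_i) ** 2
    if var_term <= 0:
        return TestResult(0.0, 1.0, 1, "CATT", degenerate=True)
    num = N * (N * (w @ r_i) - R * (w @ n_i)) ** 2
    stat = float(num / (R * (N - R) * var_term))
    p = float(sps.chi2.sf(stat, df=1))
    return TestResult(stat, p, 1, "CATT")


def catt_table(calls: np.ndarray, is_male: np.ndarray,
               marker_class: MarkerClass | str) -> np.ndarray:
    """Build the 2 x k CATT table for one locus (males = case row)."""
    calls = np.asarray(calls)
    if MarkerClass(marker_class) is MarkerClass.SNP:
        cats = (REF_HOM, HET, ALT_HOM)  # dosage order 0,1,2
    else:
        cats = (ABSENT, PRESENT)
    rows = []
    for sex_mask in (is_male, ~is_male):
        sub = calls[sex_mask]
        sub = sub[sub != MISSING]
        rows.append([int((sub == c).sum()) for c in cats])
    return np.array(rows)


# ---------------------------------------------------------- chi-square

def chisq_goodness_of_fit(observed: np.ndarray, expected_proportions: np.ndarray) -> TestResult:
    """Pearson goodness-of-fit of observed counts to expected proportions.

    Categories with zero expectation are dropped; df = (#kept) - 1.
    """
    observed = np.asarray(observed, dtype=float)
    expected_proportions = np.asarray(expected_proportions, dtype=float)
    if observed.shape != expected_proportions.shape:
        raise ValueError("observed and expected shapes differ")
    if not math.isclose(expected_proportions.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    keep = expected_proportions > 0
    if not keep.any():
        raise ValueError("all expected proportions are zero")
    obs = observed[keep]
    exp = expected_proportions[keep] * observed.sum()
    if keep.sum() < 2:
        return TestResult(0.0, 1.0, 0, "chisq_gof", degenerate=True)
    stat, p = sps.chisquare(obs, exp)
    return TestResult(float(stat), float(p), int(keep.sum() - 1), "chisq_gof")


def chisq_homogeneity(groups: np.ndarray) -> TestResult:
    """Pearson homogeneity test across rows of category counts.

    Empty rows/columns are dropped before computation; df = (r-1)(c-1).
    """
    table = np.asarray(groups, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return TestResult(0.0, 1.0, 0, "chisq_homogeneity", degenerate=True)
    stat, p, df, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(float(stat), float(p), int(df), "chisq_homogeneity")


# ------------------------------------------------------------ PIC & het

def pic(p: float) -> float:
    """Polymorphism information content of a biallelic locus, as the
    expected heterozygosity 2p(1-p): 0 at fixation, maximal 0.5 at
    p = 0.5."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"allele frequency {p} not in [0,1]")
    return 2.0 * p * (1.0 - p)


def allele_frequency(calls: np.ndarray) -> float:
    """Alternate-allele frequency from SNP calls:
    (2*ALT_HOM + HET) / (2 * scored)."""
    calls = np.asarray(calls)
    scored = calls[calls != MISSING]
    if scored.size == 0:
        raise ValueError("no scored calls")
    return float((2 * (scored == ALT_HOM).sum() + (scored == HET).sum()) / (2 * scored.size))


def presence_frequency(calls: np.ndarray) -> float:
    calls = np.asarray(calls)
    scored = calls[calls != MISSING]
    if scored.size == 0:
        raise ValueError("no scored calls")
    return float((scored == PRESENT).mean())


@dataclass
class HeterozygosityProfile:
    per_individual: dict[str, float]
    male_mean: float
    male_sd: float
    female_mean: float
    female_sd: float
    excluded: list[str]


def heterozygosity_profile(matrix, registry: SexRegistry,
                           candidate_loci: list[str]) -> HeterozygosityProfile:
    """Per-individual heterozygous fraction over candidate loci, with
    per-sex mean and sample sd.

    For SNP matrices the statistic is the fraction of scored candidate
    loci called HET; for PA matrices, the fraction called PRESENT (the
    dominant analogue — the "-" putative-heterozygote code carries no
    usable count and is treated as missing).  Individuals with no scored
    candidate locus are excluded and reported.
    """
    if not candidate_loci:
        raise ValueError("candidate set is empty")
    sub = matrix.subset_loci(candidate_loci)
    target = HET if MarkerClass(sub.marker_class) is MarkerClass.SNP else PRESENT
    is_male = registry.is_male_vector(sub.individual_ids)

    per_individual: dict[str, float] = {}
    excluded: list[str] = []
    for j, ind in enumerate(sub.individual_ids):
        col = sub.calls[:, j]
        scored = col[col != MISSING]
        if scored.size == 0:
            excluded.append(ind)
            continue
        per_individual[ind] = float((scored == target).mean())

    def _summ(ids):
        vals = np.array([per_individual[i] for i in ids if i in per_individual])
        if vals.size == 0:
            return float("nan"), float("nan")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        return float(vals.mean()), sd

    m_ids = [i for i, m in zip(sub.individual_ids, is_male) if m]
    f_ids = [i for i, m in zip(sub.individual_ids, is_male) if not m]
    m_mean, m_sd = _summ(m_ids)
    f_mean, f_sd = _summ(f_ids)
    return HeterozygosityProfile(per_individual, m_mean, m_sd, f_mean, f_sd, excluded)


# ----------------------------------------------- rank tests (KW/Nemenyi)

def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal-Wallis H with mid-rank tie correction, chi-square p on
    k-1 df.  All-identical observations give H = 0, p = 1."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, len(groups) - 1, "kruskal_wallis", degenerate=True)
    stat, p = sps.kruskal(*arrs)
    return TestResult(float(stat), float(p), len(groups) - 1, "kruskal_wallis")


def nemenyi_posthoc(groups: list[np.ndarray]) -> np.ndarray:
    """Nemenyi pairwise post-hoc with the chi-square approximation for
    independent (possibly unequal-sized) samples.

    For groups i, j with mean pooled mid-ranks Rbar and sizes n, the
    statistic is

        q_ij = (Rbar_i - Rbar_j)^2 / [ C * N(N+1)/12 * (1/n_i + 1/n_j) ]

    with tie correction C = 1 - Σ(t³ - t)/(N³ - N), referred to
    chi-square on k-1 df.  Returns the symmetric p-value matrix with a
    unit diagonal.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = np.array([a.size for a in arrs])
    if (sizes == 0).any():
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate(arrs)
    N = pooled.size
    if N < 3:
        raise ValueError("need at least three observations in total")
    ranks = sps.rankdata(pooled)
    edges = np.cumsum(sizes)[:-1]
    mean_ranks = np.array([r.mean() for r in np.split(ranks, edges)])

    _, tie_counts = np.unique(pooled, return_counts=True)
    C = 1.0 - (tie_counts**3 - tie_counts).sum() / (N**3 - N)
    pmat = np.ones((k, k))
    if C <= 0:  # every observation identical
        return pmat
    base_var = C * N * (N + 1) / 12.0
    for i in range(k):
        for j in range(i + 1, k):
            q = (mean_ranks[i] - mean_ranks[j]) ** 2 / (base_var * (1 / sizes[i] + 1 / sizes[j]))
            p = float(sps.chi2.sf(q, df=k - 1))
            pmat[i, j] = pmat[j, i] = p
    return pmat


# ----------------------------------------------- spurious-linkage model

@dataclass
class SpuriousEstimate:
    n: int
    p_single: float
    n_loci: int
    expected_spurious: float


def spurious_probability(n: int) -> float:
    """P_i = 0.5**n: chance a sex-independent locus looks perfectly
    sex-linked in a cohort of n sexed individuals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return 0.5**n


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 passes through)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + sig - 1)


def expected_spurious(n_loci: int, p_single: float) -> float:
    """Expected number of spuriously perfect sex-linked loci over a
    panel: n_loci * p_single.  Pass ``round_sig(spurious_probability(n))``
    to reproduce reported values computed from a 3-significant-figure
    per-locus probability."""
    if n_loci < 0:
        raise ValueError("n_loci must be nonnegative")
    return n_loci * p_single


def spurious_estimate(n: int, n_loci: int, round_p: bool = False) -> SpuriousEstimate:
    p = spurious_probability(n)
    if round_p:
        p = round_sig(p, 3)
    return SpuriousEstimate(n, p, n_loci, expected_spurious(n_loci, p))


def required_sample_size(n_loci: int, max_expected: float) -> int:
    """Smallest cohort size n with n_loci * 0.5**n < max_expected."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    if max_expected <= 0:
        raise ValueError("max_expected must be positive")
    n = 1
    while n_loci * 0.5**n >= max_expected:
        n += 1
    return n


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Optional BH-adjusted p-values (raw p-values are the default
    reporting mode)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
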
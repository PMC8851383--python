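"""Proportional Hamming distances among individuals over a locus subset.

The distance between two individuals is the fraction of loci — among
those scored in both — at which their call codes differ.  SNP codes are
compared as categorical symbols (REF_HOM, HET and ALT_HOM are three
distinct states, not dosages).  Pairs with no co-scored locus are
undefined (NaN) and excluded from summaries.  In a cohort segregating a
sex-linked region, distances between the sexes over candidate loci
exceed distances within either sex; the within/between summary makes
that separation explicit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .codes import MISSING, Sex, SexRegistry


@dataclass
class DistanceMatrix:
    individual_ids: list[str]
    values: np.ndarray       # symmetric, NaN where undefined, zero diagonal
    n_loci_used: np.ndarray  # co-scored locus count per pair

    @property
    def n(self) -> int:
        return len(self.individual_ids)

    def pair(self, a: str, b: str) -> float:
        i, j = self.individual_ids.index(a), self.individual_ids.index(b)
        return float(self.values[i, j])


@dataclass
class SexDistanceSummary:
    within_male_mean: float | None
    within_male_sd: float | None
    within_female_mean: float | None
    within_female_sd: float | None
    between_mean: float
    between_sd: float
    n_undefined_pairs: int = 0

    def as_dict(self) -> dict:
        return {
            "within_male": {"mean": self.within_male_mean, "sd": self.within_male_sd},
            "within_female": {"mean": self.within_female_mean, "sd": self.within_female_sd},
            "between_sex": {"mean": self.between_mean, "sd": self.between_sd},
            "n_undefined_pairs": self.n_undefined_pairs,
        }


def hamming_matrix(matrix, loci_subset: list[str] | None = None) -> DistanceMatrix:
    """Pairwise proportional Hamming distances with pairwise deletion.

    ``loci_subset`` restricts the computation (typically to candidate
    sex-linked loci); ``None`` uses every locus.  Raises on a
    single-individual matrix or an empty subset.
    """
    sub = matrix if loci_subset is None else matrix.subset_loci(list(loci_subset))
    if sub.n_loci == 0:
        raise ValueError("empty locus subset")
    if sub.n_individuals < 2:
        raise ValueError("need at least two individuals")
    calls = sub.calls
    scored = calls != MISSING
    n = sub.n_individuals
    values = np.zeros((n, n))
    n_used = np.zeros((n, n), dtype=int)
    for i in range(n):
        n_used[i, i] = int(scored[:, i].sum())
        for j in range(i + 1, n):
            both = scored[:, i] & scored[:, j]
            m = int(both.sum())
            n_used[i, j] = n_used[j, i] = m
            if m == 0:
                values[i, j] = values[j, i] = np.nan
            else:
                d = float((calls[both, i] != calls[both, j]).sum() / m)
                values[i, j] = values[j, i] = d
    return DistanceMatrix(list(sub.individual_ids), values, n_used)


def _pair_values(dm: DistanceMatrix, idx_a: np.ndarray, idx_b: np.ndarray,
                 within: bool) -> np.ndarray:
    vals = []
    if within:
        for ii, a in enumerate(idx_a):
            for b in idx_a[ii + 1:]:
                vals.append(dm.values[a, b])
    else:
        for a in idx_a:
            for b in idx_b:
                vals.append(dm.values[a, b])
    return np.array(vals)


def summarize_by_sex(dm: DistanceMatrix, registry: SexRegistry) -> SexDistanceSummary:
    """Mean +/- sample sd over within-male, within-female and
    between-sex pairs; undefined pairs are dropped and counted.  A sex
    with fewer than two members has no within-sex summary."""
    is_male = registry.is_male_vector(dm.individual_ids)
    males = np.flatnonzero(is_male)
    females = np.flatnonzero(~is_male)
    if males.size == 0 or females.size == 0:
        raise ValueError("both sexes required for a between-sex summary")

    n_undef = 0

    def _summ(vals: np.ndarray):
        nonlocal n_undef
        n_undef += int(np.isnan(vals).sum())
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return None, None
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    wm = _summ(_pair_values(dm, males, males, True)) if males.size >= 2 else (None, None)
    wf = _summ(_pair_values(dm, females, females, True)) if females.size >= 2 else (None, None)
    bm, bs = _summ(_pair_values(dm, males, females, False))
    return SexDistanceSummary(wm[0], wm[1], wf[0], wf[1], bm, bs, n_undef)


def export_heatmap_table(dm: DistanceMatrix, path: str | Path,
                         ordering: str = "by_id",
                         registry: SexRegistry | None = None) -> list[str]:
    """Write the distance matrix as a heatmap-ready TSV.

    ``ordering="by_sex"`` blocks all males (sorted by id) before all
    females, matching how sex-linkage heatmaps are usually displayed;
    ``"by_id"`` sorts lexicographically.  Values print to 6 decimals so
    repeated exports are byte-identical.  Returns the row order used.
    """
    if ordering == "by_id":
        order = sorted(dm.individual_ids)
    elif ordering == "by_sex":
        if registry is None:
            raise ValueError("by_sex ordering needs a sex registry")
        order = sorted(dm.individual_ids, key=lambda i: (registry[i] is not Sex.MALE, i))
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    idx = [dm.individual_ids.index(i) for i in order]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("individual_id\t" + "\t".join(order) + "\n")
        for a in idx:
            row = ["nan" if np.isnan(dm.values[a, b]) else f"{dm.values[a, b]:.6f}" for b in idx]
            fh.write(dm.individual_ids[a] + "\t" + "\t".join(row) + "\n")
    return order


def render_heatmap(dm: DistanceMatrix, image_path: str | Path,
                   ordering: str = "by_id",
                   registry: SexRegistry | None = None) -> None:
    """Optional image companion to :func:`export_heatmap_table`
    (requires matplotlib/seaborn, the ``plot`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    if ordering == "by_sex":
        if registry is None:
            raise ValueError("by_sex ordering needs a sex registry")
        order = sorted(dm.individual_ids, key=lambda i: (registry[i] is not Sex.MALE, i))
    else:
        order = sorted(dm.individual_ids)
    idx = [dm.individual_ids.index(i) for i in order]
    fig, ax = plt.subplots(figsize=(8, 7))
    sns.heatmap(dm.values[np.ix_(idx, idx)], xticklabels=order, yticklabels=order,
                cmap="viridis", vmin=0.0, vmax=1.0, square=True, ax=ax)
    ax.set_title("pairwise proportional Hamming distance")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)


ALLELIC_STATE_LABELS = {0: "REF_HOM", 1: "ALT_HOM", 2: "HET", MISSING: "MISSING"}
PA_STATE_LABELS = {0: "ABSENT", 1: "PRESENT", MISSING: "MISSING"}


def export_allelic_index(matrix, loci_subset: list[str], path: str | Path,
                         registry: SexRegistry | None = None) -> None:
    """Candidate-locus x individual allelic-state table (the tabular
    form of a per-individual sex-linkage index plot)."""
    from .codes import GenotypeMatrix

    sub = matrix.subset_loci(list(loci_subset))
    labels = ALLELIC_STATE_LABELS if isinstance(matrix, GenotypeMatrix) else PA_STATE_LABELS
    ids = list(sub.individual_ids)
    if registry is not None:
        ids = sorted(ids, key=lambda i: (registry[i] is not Sex.MALE, i))
    cols = [sub.individual_ids.index(i) for i in ids]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("locus_id\t" + "\t".join(ids) + "\n")
        for r, locus in enumerate(sub.locus_ids):
            fh.write(locus + "\t" + "\t".join(labels[int(sub.calls[r, c])] for c in cols) + "\n")
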
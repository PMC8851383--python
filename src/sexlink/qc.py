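"""Marker-retention filters applied before any linkage scan.

A locus is kept only if reproducibility, mean read depth and call rate
all clear their thresholds with strict inequality (the platform reports
markers "at >90%" reproducibility, depth ">3.5" for SNPs and ">5" for PA,
call rate ">80%").  Call rate is recomputed from the matrix — the
fraction of individuals actually scored — and that recomputed value is
authoritative over whatever the metadata claims.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .codes import MarkerClass, MarkerMetadata, MISSING

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    min_reproducibility: float = 0.90
    min_depth_snp: float = 3.5
    min_depth_pa: float = 5.0
    min_call_rate: float = 0.80

    def __post_init__(self) -> None:
        for name in ("min_reproducibility", "min_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0,1]")
        if self.min_depth_snp < 0 or self.min_depth_pa < 0:
            raise ValueError("depth thresholds must be nonnegative")

    def min_depth(self, marker_class: MarkerClass) -> float:
        return self.min_depth_snp if MarkerClass(marker_class) is MarkerClass.SNP else self.min_depth_pa


@dataclass
class Rejection:
    locus_id: str
    reason: str  # first failed criterion
    value: float
    threshold: float


def qc_filter(matrix, metadata: list[MarkerMetadata], thresholds: QCThresholds,
              marker_class: MarkerClass | str):
    """Return ``(retained_matrix, retained_metadata, rejections)``.

    Criteria are evaluated in a fixed order (reproducibility, depth, call
    rate) and the rejection log records the first one a locus fails.
    """
    marker_class = MarkerClass(marker_class)
    meta_by_id = {m.locus_id: m for m in metadata}
    missing_meta = [l for l in matrix.locus_ids if l not in meta_by_id]
    if missing_meta:
        raise ValueError(f"loci missing metadata: {missing_meta[:5]}")

    min_depth = thresholds.min_depth(marker_class)
    call_rates = (matrix.calls != MISSING).mean(axis=1)

    keep_idx: list[int] = []
    retained_meta: list[MarkerMetadata] = []
    rejections: list[Rejection] = []
    for i, locus_id in enumerate(matrix.locus_ids):
        m = meta_by_id[locus_id]
        if not m.reproducibility > thresholds.min_reproducibility:
            rejections.append(Rejection(locus_id, "reproducibility", m.reproducibility,
                                        thresholds.min_reproducibility))
        elif not m.mean_read_depth > min_depth:
            rejections.append(Rejection(locus_id, "read_depth", m.mean_read_depth, min_depth))
        elif not call_rates[i] > thresholds.min_call_rate:
            rejections.append(Rejection(locus_id, "call_rate", float(call_rates[i]),
                                        thresholds.min_call_rate))
        else:
            keep_idx.append(i)
            retained_meta.append(m)

    retained = type(matrix)(
        [matrix.locus_ids[i] for i in keep_idx],
        list(matrix.individual_ids),
        matrix.calls[np.array(keep_idx, dtype=int)] if keep_idx
        else np.empty((0, matrix.n_individuals), dtype=np.int8),
    )
    logger.info(
        "QC %s: retained %d / %d loci (%d rejected)",
        marker_class.value, retained.n_loci, matrix.n_loci, len(rejections),
    )
    return retained, retained_meta, rejections
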
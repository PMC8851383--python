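"""Readers and writers for DArT-style genotype reports, sex registries
and scan reports.

The canonical on-disk dialect is a simplified one-row-per-locus CSV:

    locus_id,reproducibility,call_rate,read_depth,tag_sequence,Ind1,...,IndN

with SNP cells in {0,1,2,-} and PA cells in {0,1,-}.  The missing token is
accepted as "-" (hyphen), "–" (en dash) or an empty cell, and always
written back as "-".  The authentic DArTsoft two-row SNP export is
deliberately not emulated: the analysis operates on called scores.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from .codes import (
    ABSENT,
    ALT_HOM,
    HET,
    MISSING,
    PRESENT,
    REF_HOM,
    GenotypeMatrix,
    MarkerClass,
    MarkerMetadata,
    PresenceMatrix,
    Sex,
    SexRegistry,
)

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ["locus_id", "reproducibility", "call_rate", "read_depth", "tag_sequence"]

_MISSING_TOKENS = {"-", "–", ""}
_SNP_TOKEN_MAP = {"0": REF_HOM, "1": ALT_HOM, "2": HET}
_PA_TOKEN_MAP = {"0": ABSENT, "1": PRESENT}
_SNP_CODE_TOKEN = {REF_HOM: "0", ALT_HOM: "1", HET: "2", MISSING: "-"}
_PA_CODE_TOKEN = {ABSENT: "0", PRESENT: "1", MISSING: "-"}

_SEX_TOKENS = {"m": Sex.MALE, "male": Sex.MALE, "f": Sex.FEMALE, "female": Sex.FEMALE}


def read_genotype_report(path: str | Path, marker_class: MarkerClass | str):
    """Read a one-row-per-locus CSV report.

    Returns ``(matrix, metadata)`` where ``matrix`` is a
    :class:`GenotypeMatrix` (SNP) or :class:`PresenceMatrix` (PA) and
    ``metadata`` is a list of :class:`MarkerMetadata`, one per locus in
    file order.  Unknown cell tokens and duplicate locus/individual ids
    are hard errors naming the offending entity.
    """
    marker_class = MarkerClass(marker_class)
    token_map = _SNP_TOKEN_MAP if marker_class is MarkerClass.SNP else _PA_TOKEN_MAP
    path = Path(path)

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty report") from None
        if header[: len(METADATA_COLUMNS)] != METADATA_COLUMNS:
            raise ValueError(
                f"{path}: header must start with {METADATA_COLUMNS}, got {header[:5]}"
            )
        individual_ids = header[len(METADATA_COLUMNS):]
        if not individual_ids:
            raise ValueError(f"{path}: no individual columns")
        if len(set(individual_ids)) != len(individual_ids):
            dup = sorted({i for i in individual_ids if individual_ids.count(i) > 1})
            raise ValueError(f"{path}: duplicate individual id(s): {dup}")

        locus_ids: list[str] = []
        metadata: list[MarkerMetadata] = []
        rows: list[list[int]] = []
        seen: set[str] = set()
        for row in reader:
            if not row:
                continue
            locus_id = row[0]
            if locus_id in seen:
                raise ValueError(f"{path}: duplicate locus id {locus_id!r}")
            seen.add(locus_id)
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: locus {locus_id!r} has {len(row)} fields, expected {len(header)}"
                )
            metadata.append(
                MarkerMetadata(
                    locus_id=locus_id,
                    reproducibility=float(row[1]),
                    call_rate=float(row[2]),
                    mean_read_depth=float(row[3]),
                    tag_sequence=row[4],
                )
            )
            coded: list[int] = []
            for ind, token in zip(individual_ids, row[len(METADATA_COLUMNS):]):
                tok = token.strip()
                if tok in _MISSING_TOKENS:
                    coded.append(MISSING)
                elif tok in token_map:
                    coded.append(token_map[tok])
                else:
                    raise ValueError(
                        f"{path}: unknown {marker_class.value} token {token!r} at "
                        f"locus {locus_id!r}, individual {ind!r}"
                    )
            locus_ids.append(locus_id)
            rows.append(coded)

    calls = np.array(rows, dtype=np.int8).reshape(len(locus_ids), len(individual_ids))
    cls = GenotypeMatrix if marker_class is MarkerClass.SNP else PresenceMatrix
    matrix = cls(locus_ids, individual_ids, calls)
    logger.info(
        "read %s report %s: %d loci x %d individuals",
        marker_class.value, path, matrix.n_loci, matrix.n_individuals,
    )
    return matrix, metadata


def write_genotype_report(matrix, metadata: list[MarkerMetadata], path: str | Path) -> None:
    """Write a matrix + metadata back to the canonical CSV dialect."""
    code_token = (
        _SNP_CODE_TOKEN if isinstance(matrix, GenotypeMatrix) else _PA_CODE_TOKEN
    )
    meta_by_id = {m.locus_id: m for m in metadata}
    missing = [l for l in matrix.locus_ids if l not in meta_by_id]
    if missing:
        raise ValueError(f"metadata missing for loci: {missing[:5]}")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS + list(matrix.individual_ids))
        for i, locus_id in enumerate(matrix.locus_ids):
            m = meta_by_id[locus_id]
            writer.writerow(
                [
                    locus_id,
                    repr(m.reproducibility),
                    repr(m.call_rate),
                    repr(m.mean_read_depth),
                    m.tag_sequence,
                ]
                + [code_token[int(c)] for c in matrix.calls[i]]
            )


def read_sex_registry(path: str | Path) -> SexRegistry:
    """Read a two-column TSV of (individual_id, sex).

    Sex tokens are case-insensitive M/F/male/female.  Duplicates and
    unrecognised tokens are hard errors.
    """
    path = Path(path)
    sexes: dict[str, Sex] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and row[0].strip().lower() in {"individual_id", "individual", "sample"}:
                continue  # optional header
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {row!r}")
            ind, tok = row[0].strip(), row[1].strip().lower()
            if ind in sexes:
                raise ValueError(f"{path}:{lineno}: duplicate individual {ind!r}")
            if tok not in _SEX_TOKENS:
                raise ValueError(f"{path}:{lineno}: unrecognised sex token {row[1]!r}")
            sexes[ind] = _SEX_TOKENS[tok]
    if not sexes:
        raise ValueError(f"{path}: empty sex registry")
    reg = SexRegistry(sexes)
    logger.info("read sex registry %s: %d males, %d females", path, len(reg.males), len(reg.females))
    return reg


def write_sex_registry(registry: SexRegistry, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["individual_id", "sex"])
        for ind, sex in registry.sexes.items():
            writer.writerow([ind, "M" if sex is Sex.MALE else "F"])


SCAN_REPORT_COLUMNS = [
    "locus_id",
    "hypothesis",
    "tier",
    "marker_class",
    "carrier_fraction_het_sex",
    "carrier_fraction_hom_sex",
    "linkage_class",
    "n_scored_males",
    "n_scored_females",
]


def write_scan_report(results, path: str | Path) -> None:
    """Write per-(locus, hypothesis, tier) scan verdicts as a TSV.

    Rows are sorted by (locus_id, hypothesis, tier) so repeated runs are
    byte-identical; an empty result list yields a header-only file.
    """
    ordered = sorted(results, key=lambda r: (r.locus_id, r.criterion.hypothesis.value, r.criterion.tier))
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(SCAN_REPORT_COLUMNS)
        for r in ordered:
            writer.writerow(
                [
                    r.locus_id,
                    r.criterion.hypothesis.value,
                    f"{r.criterion.tier:.2f}",
                    r.criterion.marker_class.value,
                    "NA" if r.carrier_fraction_het_sex is None else f"{r.carrier_fraction_het_sex:.6f}",
                    "NA" if r.carrier_fraction_hom_sex is None else f"{r.carrier_fraction_hom_sex:.6f}",
                    r.linkage_class.value,
                    r.n_scored_males,
                    r.n_scored_females,
                ]
            )
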
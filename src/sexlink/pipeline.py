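"""End-to-end pipeline: simulate (or load) → QC → linkage scan →
association statistics → Hamming distances → consolidated report.

A run is a pure function of its configuration (and input files, when
loading): the same :class:`RunConfig` always produces byte-identical
outputs, including ``summary.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as dart_io
from .codes import GenotypeMatrix, MarkerClass, PresenceMatrix, SexRegistry
from .distance import export_allelic_index, export_heatmap_table, hamming_matrix, summarize_by_sex
from .qc import QCThresholds, qc_filter
from .scan import DEFAULT_TIERS, Hypothesis, LinkageClass, default_criteria, scan_dataset
from .simulate import SimulatedDataset, SyntheticConfig, simulate_dataset, write_dataset
from .stats import (
    allele_frequency,
    catt,
    catt_table,
    pic,
    presence_frequency,
    spurious_estimate,
)

logger = logging.getLogger(__name__)


@dataclass
class InputPaths:
    snp_report: str | None = None
    pa_report: str | None = None
    sex_registry: str | None = None


@dataclass
class RunConfig:
    """Exactly one of ``inputs`` / ``synthetic`` must be supplied."""

    inputs: InputPaths | None = None
    synthetic: SyntheticConfig | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    tiers: tuple[float, ...] = DEFAULT_TIERS
    hypotheses: tuple[Hypothesis, ...] = (Hypothesis.XY, Hypothesis.ZW)
    compute_stats: bool = True
    compute_distance: bool = True
    outdir: str = "sexlink_run"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("supply exactly one of input paths or a synthetic config")
        self.tiers = tuple(float(t) for t in self.tiers)
        self.hypotheses = tuple(Hypothesis(h) for h in self.hypotheses)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "inputs" in raw:
            kwargs["inputs"] = InputPaths(**raw["inputs"])
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        if "thresholds" in raw:
            kwargs["thresholds"] = QCThresholds(**raw["thresholds"])
        for key in ("tiers", "hypotheses", "compute_stats", "compute_distance", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _load_inputs(paths: InputPaths):
    snp = pa = None
    snp_meta = pa_meta = []
    if paths.snp_report:
        snp, snp_meta = dart_io.read_genotype_report(paths.snp_report, MarkerClass.SNP)
    if paths.pa_report:
        pa, pa_meta = dart_io.read_genotype_report(paths.pa_report, MarkerClass.PA)
    if not paths.sex_registry:
        raise ValueError("a sex registry path is required")
    registry = dart_io.read_sex_registry(paths.sex_registry)
    return snp, pa, snp_meta, pa_meta, registry


def _stats_rows(matrix, registry: SexRegistry, candidate_ids: list[str],
                marker_class: MarkerClass):
    is_male = registry.is_male_vector(matrix.individual_ids)
    rows = []
    for locus in candidate_ids:
        calls = matrix.calls[matrix.locus_index(locus)]
        res = catt(catt_table(calls, is_male, marker_class))
        freq = (allele_frequency(calls) if marker_class is MarkerClass.SNP
                else presence_frequency(calls))
        rows.append({
            "locus_id": locus,
            "marker_class": marker_class.value,
            "catt_statistic": round(res.statistic, 6),
            "catt_p": float(f"{res.p_value:.6g}"),
            "degenerate": res.degenerate,
            "allele_frequency": round(freq, 6),
            "pic": round(pic(freq), 6),
        })
    return rows


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Returns the ``summary.json`` payload.  Stage order is fixed:
    simulate/load, QC, scan, statistics, distances.  Any stage error
    aborts the run with the stage named in the exception.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    # --- stage 1: acquire data
    if config.synthetic is not None:
        dataset: SimulatedDataset = simulate_dataset(config.synthetic)
        write_dataset(dataset, outdir / "simulated")
        snp, pa = dataset.snp, dataset.pa
        snp_meta, pa_meta = dataset.snp_metadata, dataset.pa_metadata
        registry = dataset.registry
        summary["seed"] = config.synthetic.seed
        summary["stages"].append("simulate")
    else:
        try:
            snp, pa, snp_meta, pa_meta, registry = _load_inputs(config.inputs)
        except Exception as e:
            raise RuntimeError(f"stage 'load' failed: {e}") from e
        summary["stages"].append("load")

    n_m, n_f = len(registry.males), len(registry.females)
    summary["cohort"] = {"n_males": n_m, "n_females": n_f}

    # --- stage 2: QC
    panels: dict[MarkerClass, tuple] = {}
    for mc, matrix, meta in ((MarkerClass.SNP, snp, snp_meta), (MarkerClass.PA, pa, pa_meta)):
        if matrix is None or matrix.n_loci == 0:
            continue
        try:
            retained, retained_meta, rejections = qc_filter(matrix, meta, config.thresholds, mc)
        except Exception as e:
            raise RuntimeError(f"stage 'qc' failed for {mc.value}: {e}") from e
        panels[mc] = (retained, retained_meta)
        summary.setdefault("qc", {})[mc.value] = {
            "input_loci": matrix.n_loci,
            "retained": retained.n_loci,
            "rejected": len(rejections),
        }
    summary["stages"].append("qc")

    # --- stage 3: linkage scan
    all_results = []
    candidate_counts: dict[str, int] = {}
    candidates_by_class: dict[MarkerClass, list[str]] = {}
    for mc, (matrix, _meta) in panels.items():
        if matrix.n_loci == 0:
            continue
        criteria = default_criteria(mc, config.hypotheses, config.tiers)
        try:
            results, counts = scan_dataset(matrix, registry, criteria)
        except Exception as e:
            raise RuntimeError(f"stage 'scan' failed for {mc.value}: {e}") from e
        all_results.extend(results)
        for (hyp, tier, mclass), c in counts.items():
            candidate_counts[f"{mclass}|{hyp}|{tier:.2f}"] = c
        candidates_by_class[mc] = sorted(
            {r.locus_id for r in results if r.is_candidate}
        )
    dart_io.write_scan_report(all_results, outdir / "scan_report.tsv")
    summary["candidate_counts"] = dict(sorted(candidate_counts.items()))
    summary["stages"].append("scan")

    # --- stage 4: statistics
    n_total_loci = sum(m.n_loci for m, _ in panels.values())
    est = spurious_estimate(n_m + n_f, n_total_loci, round_p=True)
    summary["spurious"] = {
        "n_individuals": est.n,
        "p_single": est.p_single,
        "n_loci": est.n_loci,
        "expected_spurious": est.expected_spurious,
    }
    if config.compute_stats:
        stats_rows = []
        for mc, (matrix, _meta) in panels.items():
            cands = candidates_by_class.get(mc, [])
            try:
                stats_rows.extend(_stats_rows(matrix, registry, cands, mc))
            except Exception as e:
                raise RuntimeError(f"stage 'stats' failed for {mc.value}: {e}") from e
        with (outdir / "candidate_stats.tsv").open("w", encoding="utf-8") as fh:
            cols = ["locus_id", "marker_class", "catt_statistic", "catt_p",
                    "degenerate", "allele_frequency", "pic"]
            fh.write("\t".join(cols) + "\n")
            for row in sorted(stats_rows, key=lambda r: r["locus_id"]):
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        summary["stages"].append("stats")

    # --- stage 5: distances over candidate loci
    if config.compute_distance:
        summary["distance"] = {}
        for mc, (matrix, _meta) in panels.items():
            cands = candidates_by_class.get(mc, [])
            if len(cands) == 0 or matrix.n_individuals < 2:
                continue
            try:
                dm = hamming_matrix(matrix, cands)
                sexsum = summarize_by_sex(dm, registry)
            except Exception as e:
                raise RuntimeError(f"stage 'distance' failed for {mc.value}: {e}") from e
            export_heatmap_table(dm, outdir / f"distance_matrix_{mc.value.lower()}.tsv",
                                 ordering="by_sex", registry=registry)
            export_allelic_index(matrix, cands,
                                 outdir / f"allelic_index_{mc.value.lower()}.tsv", registry)
            summary["distance"][mc.value] = sexsum.as_dict()
        summary["stages"].append("distance")

    payload = json.dumps(summary, indent=2, sort_keys=True)
    (outdir / "summary.json").write_text(payload, encoding="utf-8")
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return summary
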
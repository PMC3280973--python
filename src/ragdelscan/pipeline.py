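"""End-to-end orchestration: simulate -> scan -> decompose -> classify -> stats.

``run_full`` executes the whole simulation study under one seed and
writes a machine-readable report plus all intermediate artifacts (locus
FASTA, truth BEDs, cohort TSV, junction FASTA, deletion VCF, Ct tables).
Each stage derives its random stream deterministically from the run seed,
so identical configurations produce byte-identical outputs and stages can
be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import chip_qpcr, cohort_stats, io, junction_analyzer, rss_scanner
from . import synthetic_data as sd

__all__ = ["RunConfig", "StageError", "validate_config", "run_full", "stage_rng"]

logger = logging.getLogger(__name__)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream: run seed + stage-name hash."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 42
    outdir: str = "ragdelscan_out"
    simulator: sd.SimulatorConfig = field(default_factory=sd.SimulatorConfig)
    max_heptamer_mm: int = 3
    max_nonamer_mm: int = 6
    scan_window: int = 150
    annotate_window: int = 50
    cluster_tolerance: int = 10
    classify_tolerance: int = 50
    hotspot_fraction: float = 0.75
    min_anchor: int = 10
    decompose_extra: int = 20
    report_format: str = "json"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("simulator", {})
        for tup_key in ("extra_clone_probs", "subclonal_clone_probs", "insertion_len_range"):
            if tup_key in sim_raw:
                sim_raw[tup_key] = tuple(sim_raw[tup_key])
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        cfg.simulator = sd.SimulatorConfig(**sim_raw)
        cfg.simulator = replace(cfg.simulator, seed=cfg.seed)
        return cfg


def validate_config(config: RunConfig) -> List[str]:
    """Check every config invariant; returns human-readable violations."""
    problems = list(config.simulator.validate())
    min_scale = sd.minimal_feasible_scale()
    if 0 < config.simulator.scale_factor < min_scale:
        problems.append(
            f"simulator.scale_factor={config.simulator.scale_factor} below the "
            f"minimal feasible scale {min_scale:.5f} (distal RSS sites would overlap)"
        )
    if config.simulator.seed != config.seed:
        problems.append(
            f"seed mismatch: RunConfig.seed={config.seed} but "
            f"simulator.seed={config.simulator.seed}; the run seed must propagate"
        )
    if not config.outdir:
        problems.append("outdir must be a non-empty path")
    if not 0 < config.hotspot_fraction <= 1:
        problems.append(f"hotspot_fraction={config.hotspot_fraction} outside (0,1]")
    if config.report_format not in ("json", "tsv"):
        problems.append(f"report_format={config.report_format!r} not in {{json, tsv}}")
    for name in ("cluster_tolerance", "classify_tolerance", "min_anchor"):
        if getattr(config, name) <= 0:
            problems.append(f"{name} must be positive")
    return problems


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def run_full(config: RunConfig) -> Dict[str, Any]:
    """Run the full pipeline and write the report bundle into ``outdir``.

    The report contains per-sample deletion calls and types, unique
    junction counts, the breakpoint hotspot window, RSS annotation per
    breakpoint cluster, subgroup contingency tables with P-values, the
    subclonal-detection summary, and the ChIP/expression quantification.
    A stage failure raises :class:`StageError`; artifacts produced before
    the failure stay on disk, listed in ``manifest.json``.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.simulator
    manifest: List[str] = []
    report: Dict[str, Any] = {"seed": config.seed, "scale_factor": sim.scale_factor}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest.append(name)

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(name, exc) from exc
        logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
        return result

    # --- simulate ---------------------------------------------------------
    locus = run_stage("locus", lambda: sd.simulate_locus(sim))
    emit("locus.fa", lambda p: io.write_fasta([(locus.contig, locus.sequence)], p))
    emit("rss_truth.bed", lambda p: io.write_bed(sd.locus_rss_bed(locus), p))
    emit("deletions_truth.bed", lambda p: io.write_bed(sd.locus_deletion_bed(locus), p))

    records = run_stage("cohort", lambda: sd.simulate_cohort(sim, locus))
    cohort_frame = sd.cohort_to_frame(records, sim)
    emit("cohort.tsv", lambda p: io.write_tsv(cohort_frame, p))
    junction_recs = sd.cohort_junction_records(records)
    if junction_recs:
        emit("junctions.fa", lambda p: io.write_fasta(junction_recs, p))
    emit("events_truth.tsv", lambda p: io.write_tsv(sd.event_truth_frame(records), p))

    events = [(rec, clone) for rec in records for clone in rec.clones]

    # --- decompose junctions ---------------------------------------------
    def decompose_all():
        calls = []
        for rec, clone in events:
            prox, dist = clone.flanking_references(locus, extra=config.decompose_extra)
            call = junction_analyzer.decompose(
                clone.junction_sequence,
                prox,
                dist,
                min_anchor=config.min_anchor,
                junction_id=clone.clone_id,
                sample_id=rec.sample_id,
            )
            calls.append((clone, call))
        return calls

    calls = run_stage("decompose", decompose_all)
    ok_calls = [(clone, c) for clone, c in calls if c.status == "ok"]
    proximal_positions = [
        clone.deleted_interval[0] - clone.junction_flank + c.proximal_break
        for clone, c in ok_calls
    ]
    distal_positions = [
        clone.deleted_interval[1] - config.decompose_extra + c.distal_break
        for clone, c in ok_calls
    ]
    unique_counts = junction_analyzer.count_unique_junctions([c for _, c in calls])
    call_frame = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "clone_id": c.junction_id,
                "status": c.status,
                "proximal_break": p,
                "distal_break": d,
                "inserted_nt": c.inserted_nt,
                "microhomology_len": c.microhomology_len,
            }
            for (clone, c), p, d in zip(
                ok_calls, proximal_positions, distal_positions
            )
        ]
    )
    if not call_frame.empty:
        emit("junction_calls.tsv", lambda p: io.write_tsv(call_frame, p))
        emit(
            "deletions.vcf",
            lambda p: io.write_deletions_vcf(
                [
                    {
                        "start": int(row.proximal_break),
                        "end": int(row.distal_break),
                        "id": row.clone_id,
                        "inserted_nt": row.inserted_nt,
                        "microhomology_len": row.microhomology_len,
                    }
                    for row in call_frame.itertuples(index=False)
                ],
                locus.contig,
                locus.locus_length,
                locus.sequence,
                p,
            ),
        )

    # --- breakpoint clustering, hotspot, classification -------------------
    def breakpoint_stage():
        if not distal_positions:
            return {
                "n_junctions": 0,
                "hotspot_window_bp": None,
                "hotspot_interval": None,
                "n_deletion_types": 0,
                "type_frequencies": [],
            }
        catalog = junction_analyzer.cluster_breakpoints(
            distal_positions, tolerance=config.cluster_tolerance
        )
        labels = [
            junction_analyzer.classify_deletion(
                pos, catalog, tolerance=config.classify_tolerance
            )
            for pos in distal_positions
        ]
        win_len, win_iv = junction_analyzer.hotspot_window(
            proximal_positions, config.hotspot_fraction
        )
        freq = cohort_stats.deletion_type_frequencies(labels)
        return {
            "n_junctions": len(distal_positions),
            "hotspot_window_bp": win_len,
            "hotspot_interval": list(win_iv),
            "hotspot_fraction": config.hotspot_fraction,
            "n_deletion_types": len(catalog),
            "catalog": [
                {
                    "cluster_id": c.cluster_id,
                    "representative": c.representative,
                    "n_members": len(c.members),
                }
                for c in catalog
            ],
            "type_frequencies": freq,
            "_catalog_obj": catalog,
        }

    bp_section = run_stage("breakpoints", breakpoint_stage)
    catalog = bp_section.pop("_catalog_obj", [])
    report["breakpoints"] = bp_section
    report["unique_junctions"] = {
        "per_sample": unique_counts,
        "max_per_sample": max(unique_counts.values(), default=0),
        "samples_with_multiple": sum(1 for v in unique_counts.values() if v >= 2),
    }

    # --- RSS annotation ----------------------------------------------------
    def rss_stage():
        hot_edge = locus.hotspot_rss.cleavage_edge
        targets = [("HOTSPOT", hot_edge)] + [
            (c.cluster_id, c.representative) for c in catalog
        ]
        annotations = []
        hotspot_cands: List[rss_scanner.CandidateRSS] = []
        distal_cands: List[rss_scanner.CandidateRSS] = []
        for label, pos in targets:
            lo = max(0, pos - config.scan_window)
            hi = min(locus.locus_length, pos + config.scan_window)
            cands = [
                replace(c, heptamer_start=c.heptamer_start + lo)
                for c in rss_scanner.scan(
                    locus.sequence[lo:hi],
                    "both",
                    max_heptamer_mm=config.max_heptamer_mm,
                    max_nonamer_mm=config.max_nonamer_mm,
                    contig=locus.contig,
                )
            ]
            best = rss_scanner.annotate_breakpoints(
                cands, [pos], window=config.annotate_window
            )[pos]
            if label == "HOTSPOT":
                hotspot_cands = [c for c in cands if c.spacer_class == 23]
            elif best is not None:
                distal_cands.append(best)
            annotations.append(
                {
                    "breakpoint": label,
                    "position": pos,
                    "rss_found": best is not None,
                    "spacer_class": best.spacer_class if best else None,
                    "spacer_len": best.spacer_len if best else None,
                    "strand": best.strand if best else None,
                    "total_score": best.total_score if best else None,
                }
            )
        hotspot_best = (
            rss_scanner.annotate_breakpoints(
                hotspot_cands, [hot_edge], window=config.annotate_window
            )[hot_edge]
            if hotspot_cands
            else None
        )
        pairs = (
            rss_scanner.pair_rss([hotspot_best], distal_cands)
            if hotspot_best is not None
            else []
        )
        return {
            "annotations": annotations,
            "n_valid_pairs": len(pairs),
            "pairs": [
                {
                    "predicted_deletion": list(p.predicted_deletion),
                    "combined_score": p.combined_score,
                }
                for p in pairs
            ],
        }

    report["rss"] = run_stage("rss_scan", rss_stage)

    # --- cohort statistics -------------------------------------------------
    def stats_stage():
        samples = cohort_stats.samples_from_cohort(
            cohort_frame,
            mlpa_detect_fraction=sim.mlpa_detect_fraction,
            pcr_detect_fraction=sim.pcr_detect_fraction,
        )
        bcp = samples[samples["lineage"] == "BCP-ALL"]
        tables = cohort_stats.build_tables(bcp) if len(bcp) else []
        results = []
        for t in tables:
            try:
                res = cohort_stats.test_table(t)
            except ValueError:
                continue
            results.append(
                {
                    "group": t.group_label,
                    "counts": [t.a, t.b, t.c, t.d],
                    "test": res.test_used,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        summary = cohort_stats.subclonal_summary(samples, unique_counts, by="lineage")
        emit("sample_calls.tsv", lambda p: io.write_tsv(samples, p))
        return {
            "n_samples": len(samples),
            "mlpa_positive_bcp": int(bcp["mlpa_positive"].sum()) if len(bcp) else 0,
            "subgroup_tests": results,
            "subclonal_summary": summary,
        }

    report["cohort"] = run_stage("cohort_stats", stats_stage)

    # --- ChIP / qPCR -------------------------------------------------------
    def chip_stage():
        chip_df, expr_df = sd.simulate_ct_tables(sim)
        emit("chip_ct.tsv", lambda p: io.write_tsv(chip_df, p))
        emit("expression_ct.tsv", lambda p: io.write_tsv(expr_df, p))
        recovery = chip_qpcr.recovery_table(chip_df)
        lineage_of = {
            line: lineage
            for lineage, lines in sd.CHIP_CELL_LINES.items()
            for line in lines
        }
        recovery["lineage"] = recovery["sample_id"].map(lineage_of)
        tests = []
        for (antibody, region), grp in recovery.groupby(["antibody", "region"]):
            a = grp.loc[grp["lineage"] == "BCP-ALL", "pct_recovery"]
            b = grp.loc[grp["lineage"] == "T-ALL", "pct_recovery"]
            t, p, sig = chip_qpcr.compare_groups(a, b)
            tests.append(
                {
                    "antibody": antibody,
                    "region": region,
                    "mean_recovery_bcp": float(a.mean()),
                    "mean_recovery_tall": float(b.mean()),
                    "t": t,
                    "p_value": p,
                    "significant": sig,
                }
            )
        folds = chip_qpcr.fold_changes(expr_df, "BTG1", "HPRT", "Nalm6")
        return {
            "lineage_tests": tests,
            "fold_changes": {k: float(v) for k, v in folds.items()},
        }

    report["chip_qpcr"] = run_stage("chip_qpcr", chip_stage)

    # --- report ------------------------------------------------------------
    report = _jsonable(report)
    if config.report_format == "json":
        emit(
            "report.json",
            lambda p: p.write_text(json.dumps(report, indent=1, sort_keys=True)),
        )
    else:
        for key in ("breakpoints", "cohort", "rss", "chip_qpcr"):
            section = report.get(key, {})
            emit(
                f"report_{key}.tsv",
                lambda p, s=section: io.write_tsv(pd.json_normalize(s), p),
            )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
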
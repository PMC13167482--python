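"""End-to-end orchestration: simulate -> filter -> concord -> fragsize.

Every run writes a ``manifest.json`` recording the package version, the
resolved config hash, the seed, per-stage status and every output path.
Randomness flows exclusively from the single config seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .concordance import cohort_detection_rates
from .config import PipelineConfig, config_hash
from .filtering import apply_filter_cascade, write_variant_table
from .fragmentomics import analyze_locus, classify_fragments, read_sam, write_split_sam
from .simulate import (
    sam_header,
    simulate_cohort,
    simulate_read_pairs,
    simulate_variant_table,
    write_fasta,
    write_sam,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]

DEFAULT_STRATA = {
    "pass_all": 20,
    "fail_vaf": 8,
    "fail_status": 5,
    "fail_pon": 5,
    "fail_popfreq": 4,
    "fail_clinvar": 4,
    "fail_noncoding": 6,
}


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are preserved with a failure marker."""


def _result_dict(res) -> dict:
    return res.to_dict()


def run_pipeline(cfg: PipelineConfig, strata: dict[str, int] | None = None) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "stages": {},
        "outputs": {},
    }
    manifest_path = out_dir / "manifest.json"
    try:
        if "simulate" in cfg.stages:
            _stage_simulate(cfg, out_dir, manifest, strata or DEFAULT_STRATA)
        if "filter" in cfg.stages:
            _stage_filter(cfg, out_dir, manifest)
        if "concord" in cfg.stages:
            _stage_concord(cfg, out_dir, manifest)
        if "fragsize" in cfg.stages:
            _stage_fragsize(cfg, out_dir, manifest)
    except Exception as exc:
        manifest["failed"] = str(exc)
        _write_json(manifest_path, manifest)
        raise PipelineError(f"pipeline failed: {exc}") from exc
    _write_json(manifest_path, manifest)
    manifest["outputs"]["manifest"] = str(manifest_path)
    return manifest


def _write_json(path: Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_simulate(cfg, out_dir, manifest, strata) -> None:
    log.info("stage simulate: %d fragments", cfg.simulate.n_fragments)
    records, truth, reference = simulate_read_pairs(cfg.simulate)
    v = cfg.simulate.variant
    fasta = out_dir / "reference.fasta"
    sam = out_dir / "reads.sam"
    truth_path = out_dir / "read_truth.tsv"
    write_fasta(v.chrom, reference, fasta)
    write_sam(records, v.chrom, cfg.simulate.reference_length, sam)
    truth.to_csv(truth_path, sep="\t", index=False)

    variants, expected_pass = simulate_variant_table(cfg.seed, strata)
    vt_path = out_dir / "variants.tsv"
    write_variant_table(variants, vt_path)

    manifest["stages"]["simulate"] = {
        "n_fragments": cfg.simulate.n_fragments,
        "variant_rows": len(variants),
        "expected_pass": expected_pass,
    }
    manifest["outputs"].update(
        {"reference": str(fasta), "reads": str(sam),
         "read_truth": str(truth_path), "variants": str(vt_path)}
    )


def _stage_filter(cfg, out_dir, manifest) -> None:
    from .filtering import read_variant_table

    vt_path = out_dir / "variants.tsv"
    variants = read_variant_table(vt_path)
    report = apply_filter_cascade(variants, cfg.filter)
    filtered_path = out_dir / "variants.filtered.tsv"
    report_path = out_dir / "filter_report.json"
    write_variant_table(report.retained, filtered_path)
    _write_json(report_path, report.to_dict())
    manifest["stages"]["filter"] = report.to_dict()
    manifest["outputs"].update(
        {"filtered_variants": str(filtered_path), "filter_report": str(report_path)}
    )


def _stage_concord(cfg, out_dir, manifest) -> None:
    tissue, plasma, truth = simulate_cohort(cfg.cohort)
    rates = cohort_detection_rates(
        tissue, plasma, key_mode="coordinate",
        conf=cfg.reporting.conf, places=cfg.reporting.places,
    )
    report = {
        "overall": rates["overall"].to_dict(),
        "per_patient": {pid: r.to_dict() for pid, r in rates["per_patient"].items()},
        "plasma_only_count": rates["plasma_only_count"],
    }
    path = out_dir / "concordance.json"
    truth_path = out_dir / "cohort_truth.tsv"
    _write_json(path, report)
    truth.to_csv(truth_path, sep="\t", index=False)
    manifest["stages"]["concord"] = {"overall": report["overall"]}
    manifest["outputs"].update(
        {"concordance": str(path), "cohort_truth": str(truth_path)}
    )


def _stage_fragsize(cfg, out_dir, manifest) -> None:
    sam = out_dir / "reads.sam"
    records = read_sam(sam)
    v = cfg.simulate.variant
    fp = cfg.fragmentomics
    report = analyze_locus(
        records, v,
        min_mapq=fp.min_mapq, min_anchor=fp.min_anchor,
        threshold=fp.threshold, max_size=fp.max_size,
        mono=fp.mono, di=fp.di,
    )
    fragments = classify_fragments(records, v, fp.min_mapq, fp.min_anchor)
    split = write_split_sam(
        records, fragments, out_dir,
        header_lines=sam_header(v.chrom, cfg.simulate.reference_length),
    )
    path = out_dir / "fragsize.json"
    _write_json(path, report)
    manifest["stages"]["fragsize"] = {
        "fragment_counts": report["fragment_counts"],
        "mutant_percent_below_threshold": report["mutant_percent_below_threshold"],
        "non_mutant_percent_below_threshold": report["non_mutant_percent_below_threshold"],
    }
    manifest["outputs"].update(
        {"fragsize": str(path),
         "mutant_sam": str(split["mutant"]),
         "non_mutant_sam": str(split["non_mutant"])}
    )
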
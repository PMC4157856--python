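"""End-to-end pipeline orchestration.

Runs build-ref -> clean -> drop-singletons -> map -> test -> enrich on a
configured set of inputs, writing every stage's output plus a run report
(reference and mapping accounting, DEG summary, top enriched terms) under one
output directory.  Fully deterministic given the config; a failed stage
leaves partial outputs plus a FAILED marker naming the stage and cause.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import io as dio
from .reference import extract_reference_tags, reference_summary, InputError
from .tagproc import clean_tags, drop_singletons, map_tags, combine_libraries
from .detest import TwoLibraryDE
from .enrich import enrich_terms, top_k_report
from .simulate import ADAPTOR

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    reference_fasta: str = ""
    tags1: str = ""
    tags2: str = ""
    annotations: str = ""
    outdir: str = "dgetag_run"
    adaptor: str = ADAPTOR
    p_threshold: float = 0.005
    fdr_threshold: float = 0.001
    log2_threshold: float = 1.0
    enrich_alpha: float = 0.05
    top_k: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("p_threshold", "fdr_threshold", "enrich_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InputError(f"{name} must lie in (0, 1], got {v}")
        if self.log2_threshold < 0:
            raise InputError("log2_threshold must be non-negative")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and return the run report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "inputs": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001 - report stage + cause
                (out / "FAILED").write_text(f"{name}: {exc}\n")
                raise PipelineError(name, exc) from exc
        return wrap

    for key in ("reference_fasta", "tags1", "tags2", "annotations"):
        path = getattr(config, key)
        if path:
            if not Path(path).exists():
                (out / "FAILED").write_text(f"inputs: missing {key}: {path}\n")
                raise PipelineError("inputs", FileNotFoundError(path))
            report["inputs"][key] = {"path": str(path), "sha256": _sha256(path)}

    genes = stage("build-ref")(lambda: dio.read_fasta(config.reference_fasta))
    index = stage("build-ref")(lambda: extract_reference_tags(genes))
    ref_sum = reference_summary(index)
    dio.write_tsv(ref_sum, out / "reference_summary.tsv")
    report["reference"] = {
        row.category: {"count": int(row.count), "percentage": row.percentage}
        for row in ref_sum.itertuples()
        if row.percentage == row.percentage  # drop NaN-percentage rows
    }

    libs = []
    for key, lib_id in (("tags1", "deformed"), ("tags2", "normal")):
        raw = stage("clean")(lambda k=key, l=lib_id: dio.read_tag_table(
            getattr(config, k), l, stage="raw"))
        clean = stage("clean")(lambda r=raw: clean_tags(r, config.adaptor))
        analysis = stage("clean")(lambda c=clean: drop_singletons(c))
        expr, mapping = stage("map")(lambda a=analysis, c=clean: map_tags(
            a, index, clean_total=c.total))
        dio.write_tsv(mapping.to_frame(), out / f"mapping_{lib_id}.tsv")
        libs.append((clean, expr, mapping))

    (clean1, expr1, map1), (clean2, expr2, map2) = libs
    table = combine_libraries(expr1, expr2)

    def do_test():
        model = TwoLibraryDE(table)
        return model.fit(
            p_threshold=config.p_threshold,
            fdr_threshold=config.fdr_threshold,
            log2_threshold=config.log2_threshold,
        )

    res = stage("test")(do_test)
    dio.write_tsv(res.frame.reset_index(), out / "de_results.tsv")
    report["de_summary"] = res.de_summary
    (out / "de_summary.txt").write_text(res.summary() + "\n")

    if config.annotations:
        annotations = stage("enrich")(lambda: dio.read_annotations(config.annotations))
        detected = set(table.frame.index[(table.frame[["x", "y"]].sum(axis=1)) > 0])
        degs = set(res.degs.index) & detected
        enr = stage("enrich")(lambda: enrich_terms(
            degs, annotations, detected, alpha=config.enrich_alpha))
        dio.write_tsv(enr, out / "enrichment.tsv")
        top = top_k_report(enr, config.top_k) if len(enr) else enr
        report["top_enriched"] = top.to_dict("records") if len(top) else []

    report["mapping"] = {
        "deformed": {"clean_total": clean1.total,
                     "unambiguous_total": map1.total_unambiguous,
                     "genes_unambiguous": map1.genes_unambiguous},
        "normal": {"clean_total": clean2.total,
                   "unambiguous_total": map2.total_unambiguous,
                   "genes_unambiguous": map2.genes_unambiguous},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.name not in {"manifest.json"}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
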
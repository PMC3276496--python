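"""End-to-end orchestration: counts -> DE partition -> stats -> distances.

A :class:`RunConfig` names either a count-table path or a simulation
spec, plus the analysis parameters (control label, fold-change
thresholds, zero policy, read filter, log base, seed).  ``run_pipeline``
executes every stage, writes all result tables under an output
directory, and records a manifest with SHA-256 checksums so a rerun with
the same config and seed can be verified byte-for-byte on the numeric
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import counts_io, diffexpr, geometry, infotheo, synthetic_data

logger = logging.getLogger("transdiv")

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    input_path: str | None = None
    simulation: Mapping[str, Any] | None = None  # kwargs for make_truth
    control_id: str = "C"
    up_threshold: float = 2.0
    down_threshold: float = 0.5
    zero_policy: str = "sentinel"
    min_count: int = 3
    ratio_on: str = "frequencies"
    log_base: float = 2.0
    seed: int = 0
    outdir: str = "transdiv_run"
    make_figure: bool = True

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ValueError(
                "exactly one of input_path and simulation must be set"
            )
        if not (self.up_threshold > 1.0 > self.down_threshold > 0.0):
            raise ValueError("thresholds must satisfy up > 1 > down > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["simulation"] is not None:
            d["simulation"] = dict(d["simulation"])
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write results; returns the manifest dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # provenance hash covers analysis parameters only, not file locations,
    # so identical analyses in different directories hash identically
    config_dict = {
        k: v
        for k, v in cfg.to_dict().items()
        if k not in ("outdir", "input_path", "make_figure")
    }
    written: list[Path] = []

    def emit(obj, name):
        path = outdir / name
        counts_io.write_outputs(obj, path, config=config_dict)
        written.append(path)
        return path

    # --- stage 1: obtain counts -------------------------------------------
    if cfg.input_path is not None:
        m = counts_io.read_count_table(cfg.input_path, cfg.control_id)
        logger.info("read %d genes x %d conditions from %s",
                    len(m.gene_ids), len(m.condition_ids), cfg.input_path)
    else:
        sim = dict(cfg.simulation or {})
        sim.setdefault("control_id", cfg.control_id)
        sim.pop("seed", None)
        truth = synthetic_data.make_truth(seed=cfg.seed, **sim)
        m = synthetic_data.sample_libraries(truth, seed=cfg.seed + 1)
        emit(m, "counts.tsv")
        emit(
            {
                "seed": truth.seed,
                "depths": {c: int(truth.depths[c]) for c in truth.condition_ids},
                "renorm_constants": {
                    t: float(truth.renorm_constants[t])
                    for t in truth.treatment_ids
                },
                "n_induced": {
                    t: int((truth.fold_factors[t] > 1).sum())
                    for t in truth.treatment_ids
                },
                "n_repressed": {
                    t: int((truth.fold_factors[t] < 1).sum())
                    for t in truth.treatment_ids
                },
            },
            "truth_summary.json",
        )
        logger.info("simulated %d genes x %d conditions (seed %d)",
                    len(m.gene_ids), len(m.condition_ids), cfg.seed)

    # --- stage 2: validation ----------------------------------------------
    report = counts_io.validate_counts(m)
    emit(report, "validation.json")
    if not report.ok:
        raise counts_io.CountTableFormatError(
            "input failed validation: "
            + "; ".join(msg for sev, msg in report.issues if sev == "error")
        )

    # --- stage 3: differential expression ---------------------------------
    de = diffexpr.compute_de(
        m,
        up_threshold=cfg.up_threshold,
        down_threshold=cfg.down_threshold,
        policy=cfg.zero_policy,  # type: ignore[arg-type]
        min_count=cfg.min_count,
        ratio_on=cfg.ratio_on,  # type: ignore[arg-type]
    )
    emit(de.ratios, "ratios.tsv")
    emit(de.symbols().fillna("NA"), "calls.tsv")
    part = diffexpr.overlap_partition(de)
    emit(part, "partition.json")
    blocks = part.direction_tables()
    emit(blocks["upregulated"], "partition_up.tsv")
    emit(blocks["downregulated"], "partition_down.tsv")
    n_up = int(blocks["upregulated"]["genes"].sum()) if len(blocks["upregulated"]) else 0
    n_dn = int(blocks["downregulated"]["genes"].sum()) if len(blocks["downregulated"]) else 0
    logger.info("DE: %d genes in, %d excluded, %d up-pattern, %d down-pattern",
                part.n_genes, part.n_excluded, n_up, n_dn)

    # --- stage 4: information theory --------------------------------------
    stats = infotheo.transcriptome_stats(m, log_base=cfg.log_base)
    emit(stats, "stats.json")
    emit(stats.Si.to_frame(), "gene_specificity.tsv")

    # --- stage 5: geometry -------------------------------------------------
    points = geometry.embed(stats)
    emit(points, "embedding.tsv")
    dmat = geometry.euclidean_distances(points)
    emit(dmat.d, "distances.tsv")
    emit(dmat.lower_triangle(), "distances_lower.tsv")
    prox = geometry.proximity_report(dmat)
    emit(prox, "proximity.json")
    if cfg.make_figure:
        fig_path = outdir / "embedding.png"
        geometry.plot_embedding(stats, fig_path)
        written.append(fig_path)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": cfg.to_dict(),
        "files": {p.name: _sha256(p) for p in written},
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
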
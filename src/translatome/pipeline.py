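"""End-to-end orchestration: (simulate | load) -> model selection ->
classification -> UTR features -> enrichment report.

Driven by a :class:`PipelineConfig`, typically loaded from a YAML file.
All artifacts are written into one output directory:

* ``transcript_results.tsv`` — per-transcript model comparison
* ``gene_results.tsv``       — collapsed to one isoform per gene
* ``dependence.rnk``         — signed ranking for enrichment tools
* ``utr_features.tsv``       — per-UTR feature vector
* ``enrichment.json``        — between-class statistics
* ``manifest.json``          — config echo, seed, versions, class counts
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from translatome import io as tio
from translatome.bayes import PriorSpec, select_transcripts
from translatome.simulate import SimConfig, UTRSimSpec, simulate_expression, simulate_utrs
from translatome.utr import (
    MaxPairingFolder,
    UTRRecord,
    ViennaFolder,
    compute_features,
    longest_utr_per_gene,
)
from translatome.stats import enrichment_report

logger = logging.getLogger(__name__)

FOLDERS = {"vienna": ViennaFolder, "maxpair": MaxPairingFolder, "none": None}


@dataclass
class PipelineConfig:
    """Pipeline run configuration.

    Exactly one of ``expression_tsv`` (with ``design_tsv``) or
    ``simulation`` must be provided.
    """

    output_dir: str | Path = "translatome_run"
    expression_tsv: str | None = None
    design_tsv: str | None = None
    utr_fasta: str | None = None
    gene_map_tsv: str | None = None
    simulation: SimConfig | None = None
    utr_simulation: UTRSimSpec | None = None
    # when set, transcripts with a true negative shift get UTRs simulated
    # at this G/C target instead of utr_simulation.gc_target
    utr_gc_dependent: float | None = None
    prior: PriorSpec = field(default_factory=PriorSpec)
    threshold: float = 0.2
    folder_engine: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.expression_tsv is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError(
                "provide exactly one of expression_tsv(+design_tsv) or simulation"
            )
        if has_paths and self.design_tsv is None:
            raise ValueError("expression_tsv requires design_tsv")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.folder_engine not in FOLDERS:
            raise ValueError(f"unknown folder engine {self.folder_engine!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            sim = dict(raw["simulation"])
            for key in ("baseline_range", "meas_sd_range"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["simulation"] = SimConfig(**sim)
        if "utr_simulation" in raw and isinstance(raw["utr_simulation"], dict):
            utr = dict(raw["utr_simulation"])
            if "planted_motifs" in utr:
                utr["planted_motifs"] = tuple(
                    (str(p), float(q)) for p, q in utr["planted_motifs"]
                )
            if "length_bounds" in utr:
                utr["length_bounds"] = tuple(utr["length_bounds"])
            raw["utr_simulation"] = UTRSimSpec(**utr)
        if "prior" in raw and isinstance(raw["prior"], dict):
            raw["prior"] = PriorSpec(**raw["prior"])
        return cls(**raw)


def validate_inputs(
    expression_tsv: str | Path,
    design_tsv: str | Path,
    utr_fasta: str | Path | None = None,
    gene_map_tsv: str | Path | None = None,
) -> dict:
    """Schema and cross-file consistency checks.

    Returns ``{"errors": [...], "warnings": [...]}``; hard schema
    violations appear as errors, incomplete joins as warnings.
    """
    errors: list[str] = []
    warnings: list[str] = []
    expr = design = None
    try:
        expr = tio.read_expression(expression_tsv)
    except Exception as exc:  # noqa: BLE001 - collected into the report
        errors.append(str(exc))
    try:
        design = tio.read_design(design_tsv)
    except Exception as exc:  # noqa: BLE001
        errors.append(str(exc))
    if expr is not None and design is not None:
        missing = set(expr["sample_id"]) - set(design.sample_ids)
        if missing:
            errors.append(f"expression samples absent from design: {sorted(missing)[:5]}")
        counts = expr.groupby("transcript_id").size()
        if counts.nunique() > 1:
            errors.append("transcripts have unequal numbers of samples")
    gene_map = None
    if gene_map_tsv is not None:
        try:
            gene_map = tio.read_gene_map(gene_map_tsv)
        except Exception as exc:  # noqa: BLE001
            errors.append(str(exc))
    if utr_fasta is not None and expr is not None:
        try:
            utrs = tio.read_utr_fasta(utr_fasta, gene_map)
            have = {u.transcript_id for u in utrs}
            lack = set(expr["transcript_id"]) - have
            if lack:
                warnings.append(f"{len(lack)} transcripts lack a UTR sequence")
        except Exception as exc:  # noqa: BLE001
            errors.append(str(exc))
    return {"errors": errors, "warnings": warnings}


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run manifest.

    Outputs are written to ``config.output_dir``; on failure the partial
    output directory is removed.  Idempotent for a fixed config + seed.
    """
    out = Path(config.output_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        return _run(config, out)
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise


def _run(config: PipelineConfig, out: Path) -> dict:
    import translatome

    gene_map: dict[str, str] | None = None
    utr_records: list[UTRRecord] | None = None

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        expression, design, truth = simulate_expression(sim)
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        tio.write_expression(expression, out / "expression.tsv")
        tio.write_design(design, out / "design.tsv")
        if config.utr_simulation is not None:
            # one UTR per simulated transcript, one gene each; transcripts
            # with a true negative shift optionally get a distinct G/C target
            tids = sorted(expression["transcript_id"].unique())
            dep = set(
                truth.loc[truth["true_delta"] < 0, "transcript_id"]
            ) if config.utr_gc_dependent is not None else set()
            groups = [
                ([t for t in tids if t not in dep], config.utr_simulation.gc_target, 1),
                ([t for t in tids if t in dep], config.utr_gc_dependent, 2),
            ]
            utr_records = []
            truth_frames = []
            for members, gc, offset in groups:
                if not members:
                    continue
                spec = dataclasses.replace(
                    config.utr_simulation,
                    n_sequences=len(members),
                    gc_target=float(gc),
                    seed=config.seed + offset,
                )
                raw, utr_truth = simulate_utrs(spec)
                utr_truth["transcript_id"] = members
                truth_frames.append(utr_truth)
                utr_records.extend(
                    UTRRecord(tid, f"G_{tid}", seq)
                    for tid, (_, _, seq) in zip(members, raw)
                )
            utr_records.sort(key=lambda r: r.transcript_id)
            gene_map = {r.transcript_id: r.gene_id for r in utr_records}
            tio.write_utr_fasta(utr_records, out / "utrs.fasta")
            pd.concat(truth_frames, ignore_index=True).to_csv(
                out / "utr_truth.tsv", sep="\t", index=False
            )
    else:
        report = validate_inputs(
            config.expression_tsv, config.design_tsv, config.utr_fasta, config.gene_map_tsv
        )
        if report["errors"]:
            raise ValueError("input validation failed: " + "; ".join(report["errors"]))
        for msg in report["warnings"]:
            logger.warning("%s", msg)
        expression = tio.read_expression(config.expression_tsv)
        design = tio.read_design(config.design_tsv)
        if config.gene_map_tsv is not None:
            gene_map = tio.read_gene_map(config.gene_map_tsv)
        if config.utr_fasta is not None:
            utr_records = tio.read_utr_fasta(config.utr_fasta, gene_map)
            if gene_map is None:
                gene_map = {r.transcript_id: r.gene_id for r in utr_records}

    results = select_transcripts(
        expression, design, config.prior, config.threshold, gene_map
    )
    results.to_csv(out / "transcript_results.tsv", sep="\t")

    if "gene_id" not in results.columns:
        results = results.assign(gene_id=results.index)
    gene_results = (
        results.reset_index()
        .sort_values(["posterior_prob", "transcript_id"], ascending=[False, True])
        .drop_duplicates("gene_id", keep="first")
        .sort_values("gene_id")
        .set_index("transcript_id")
    )
    gene_results.to_csv(out / "gene_results.tsv", sep="\t")
    tio.write_rnk(
        gene_results.reset_index()[["gene_id", "rank_score"]], out / "dependence.rnk"
    )

    counts = results["class"].value_counts().to_dict()
    manifest = {
        "version": translatome.__version__,
        "seed": config.seed,
        "threshold": config.threshold,
        "prior": _jsonable(config.prior),
        "config": _jsonable(
            {
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k not in ("prior",)
            }
        ),
        "n_transcripts": int(len(results)),
        "n_genes": int(len(gene_results)),
        "class_counts": {
            k: int(counts.get(k, 0)) for k in ("dependent", "independent", "unclassified")
        },
    }

    if utr_records is not None:
        folder_cls = FOLDERS[config.folder_engine]
        folder = folder_cls() if folder_cls is not None else None
        longest = longest_utr_per_gene(utr_records)
        features = compute_features(longest, folder)
        features.to_csv(out / "utr_features.tsv", sep="\t")
        classes = results["class"]
        shared = features.index.intersection(classes.index)
        n_groups = classes.loc[shared].value_counts()
        if n_groups.get("dependent", 0) > 0 and n_groups.get("independent", 0) > 0:
            report = enrichment_report(features, classes)
            with open(out / "enrichment.json", "w") as fh:
                json.dump(report, fh, indent=2)
            manifest["enrichment"] = {
                "n_dependent": report["groups"]["dependent"],
                "n_independent": report["groups"]["independent"],
            }
        else:
            logger.warning("skipping enrichment: need both classes among UTRs")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
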
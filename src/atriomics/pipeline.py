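"""Pipeline orchestration: stage graph, config, manifest, seed flow.

Stages: ``simulate`` writes every synthetic input; ``diff`` runs the
permutation-FDR differential analysis per proteomics fraction; ``enrich``
runs the integrated pathway MANOVA; ``glycogen`` and ``assay`` are
independent of the omics chain. All randomness derives from one global seed
via stable per-stage hashing, so a re-run of any stage in isolation
reproduces its outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from ._utils import stage_seed
from .containers import PROTEOMICS_TAGS, RNA_TAG
from .enrichment import EnrichmentConfig, enrich_pathways, harmonize_ids, vst_transform
from .proteome import VolcanoConfig, filter_missing, normalize_matrix, permutation_volcano
from .synthetic import (GranuleImageSpec, SimStudyConfig, simulate_assay_plate,
                        simulate_em_image, simulate_pathway_annotation,
                        simulate_rois, simulate_study)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "diff", "enrich", "glycogen", "assay")
#: omics stages depend on the simulated inputs
STAGE_DEPS = {"diff": ("simulate",), "enrich": ("simulate",),
              "glycogen": ("simulate",), "assay": ("simulate",)}


@dataclass
class PipelineConfig:
    """Everything one run needs: stage selection, parameters, paths, seed."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    sim: SimStudyConfig = field(default_factory=SimStudyConfig)
    volcano: VolcanoConfig = field(default_factory=VolcanoConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (10, 30)
    n_images_per_group: int = 2
    image_spec: GranuleImageSpec = field(default_factory=GranuleImageSpec)
    log_level: str = "INFO"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, sub in (("sim", SimStudyConfig), ("volcano", VolcanoConfig),
                         ("enrichment", EnrichmentConfig),
                         ("image_spec", GranuleImageSpec)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "pathway_size_range" in kwargs:
            kwargs["pathway_size_range"] = tuple(kwargs["pathway_size_range"])
        return cls(**kwargs)


@dataclass
class RunManifest:
    """What a run produced: per-stage status, row counts and warnings."""

    version: str = __version__
    seed: int = 0
    config_hash: str = ""
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, **counts) -> None:
        self.stages[stage] = {"status": status, **counts}

    @property
    def ok(self) -> bool:
        return all(s["status"] == "ok" for s in self.stages.values())

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1,
                                         sort_keys=True, default=str))


def _stage_simulate(config: PipelineConfig, out: Path, manifest: RunManifest,
                    state: dict) -> None:
    sim = dataclasses.replace(config.sim,
                              seed=stage_seed(config.seed, "simulate"))
    matrices, truth = simulate_study(sim)
    annotation, ann_truth = simulate_pathway_annotation(
        sim, n_pathways=config.n_pathways,
        size_range=config.pathway_size_range)
    truth.regulated_pathways = ann_truth.regulated_pathways

    for tag, matrix in matrices.items():
        io.write_matrix(matrix, out / f"matrix_{tag}.tsv", seed=config.seed)
    io.write_design(list(matrices.values()), out / "design.tsv",
                    seed=config.seed)
    io.write_gmt(annotation, out / "pathways.gmt")
    idmap = {f: [f] for f in sim.feature_ids()}      # identity homolog map
    io.write_idmap(idmap, out / "idmap.tsv")

    images, rois_by_image, image_groups = {}, {}, {}
    for g, group in enumerate(("AF", "sham")):
        for i in range(config.n_images_per_group):
            spec = dataclasses.replace(
                config.image_spec,
                seed=stage_seed(config.seed, f"image-{group}-{i}"),
                n_granules=(config.image_spec.n_granules * (2 if group == "AF" else 1)))
            image, im_truth = simulate_em_image(spec)
            image.image_id = f"{group}_{i}"
            image.group = group
            images[image.image_id] = image
            roi_size = max(32, min(128, min(image.shape) // 4))
            rois_by_image[image.image_id] = simulate_rois(
                image, im_truth, roi_size=roi_size,
                seed=stage_seed(config.seed, f"rois-{group}-{i}"))
            image_groups[image.image_id] = group
            io.write_image(image, out / f"em_{image.image_id}.tif")
            truth.granule_coordinates.extend(im_truth.granule_coordinates)
    io.write_rois(rois_by_image, out / "rois.tsv")

    truth.true_activities = {
        f"{g}{i+1}": (3.0 if g == "AF" else 2.0) + 0.3 * i
        for g in ("AF", "sham") for i in range(sim.n_per_group)}
    plate = simulate_assay_plate(truth.true_activities, curve_slope=120.0,
                                 curve_intercept=50.0, noise_sd=5.0,
                                 seed=stage_seed(config.seed, "plate"))
    io.write_plate(plate, out / "plate.tsv", seed=config.seed)
    io.write_ground_truth(truth, out / "ground_truth.json")

    state.update(matrices=matrices, annotation=annotation, idmap=idmap,
                 truth=truth, images=images, rois=rois_by_image,
                 image_groups=image_groups, plate=plate)
    manifest.record("simulate", "ok",
                    n_features=sim.n_features,
                    n_datasets=len(matrices),
                    n_pathways=len(annotation),
                    n_images=len(images))


def _stage_diff(config: PipelineConfig, out: Path, manifest: RunManifest,
                state: dict) -> None:
    counts = {}
    volcano = dataclasses.replace(config.volcano,
                                  seed=stage_seed(config.seed, "diff"))
    for tag in [t for t in state["matrices"] if t != RNA_TAG]:
        matrix = state["matrices"][tag]
        filtered = filter_missing(matrix, volcano.max_missing)
        # S0 lives on the log2 fold-change scale: the volcano consumes log2
        # intensities; Z-scored matrices are for heatmap/correlation QC
        normalized = normalize_matrix(filtered, zscore=False)
        result = permutation_volcano(normalized, volcano)
        io._write_tsv(result, out / f"diff_{tag}.tsv", index_label="feature_id",
                      seed=config.seed)
        counts[f"{tag}_in"] = matrix.n_features
        counts[f"{tag}_filtered"] = filtered.n_features
        counts[f"{tag}_significant"] = int(result["significant"].sum())
    manifest.record("diff", "ok", **counts)


def _stage_enrich(config: PipelineConfig, out: Path, manifest: RunManifest,
                  state: dict) -> None:
    matrices = state["matrices"]
    transformed = {tag: vst_transform(m) for tag, m in matrices.items()}
    harmonized = harmonize_ids(list(transformed.values()), state["idmap"])
    by_tag = {m.dataset_tag: m for m in harmonized}
    result = enrich_pathways(by_tag, state["annotation"], config.enrichment)
    io._write_tsv(result, out / "enrichment.tsv", index_label="pathway_id",
                  seed=config.seed)
    skipped = int((result["skip_reason"] != "").sum())
    manifest.record("enrich", "ok", n_pathways_tested=len(result) - skipped,
                    n_pathways_skipped=skipped,
                    n_significant=int(result["significant"].sum()))


def _stage_glycogen(config: PipelineConfig, out: Path, manifest: RunManifest,
                    state: dict) -> None:
    from .assays import two_sample_t
    from .imaging import GranuleConfig, count_image

    gconfig = GranuleConfig()
    tables = []
    for image_id, image in state["images"].items():
        table = count_image(image, state["rois"][image_id], gconfig)
        table["group"] = state["image_groups"][image_id]
        tables.append(table)
    results = pd.concat(tables, ignore_index=True)
    io._write_tsv(results, out / "glycogen_counts.tsv", index_label=None,
                  seed=config.seed, write_index=False)
    dens_af = results.loc[results["group"] == "AF", "density"]
    dens_sham = results.loc[results["group"] == "sham", "density"]
    test = two_sample_t(dens_af, dens_sham)
    manifest.record("glycogen", "ok", n_rois=len(results),
                    t=round(test.t, 4), p=round(test.p, 6))


def _stage_assay(config: PipelineConfig, out: Path, manifest: RunManifest,
                 state: dict) -> None:
    from .assays import activities_from_plate, group_summary, two_sample_t

    activities = activities_from_plate(state["plate"])
    af = [v for s, v in activities.items() if s.startswith("AF")]
    sham = [v for s, v in activities.items() if not s.startswith("AF")]
    s_af = group_summary(af, group="AF")
    s_sham = group_summary(sham, group="sham")
    test = two_sample_t(af, sham)
    frame = pd.DataFrame([
        {"group": "AF", "n": s_af.n, "mean": s_af.mean, "sd": s_af.sd},
        {"group": "sham", "n": s_sham.n, "mean": s_sham.mean, "sd": s_sham.sd},
    ])
    io._write_tsv(frame, out / "assay_summary.tsv", index_label=None,
                  seed=config.seed, write_index=False)
    manifest.record("assay", "ok", n_samples=len(activities),
                    t=round(test.t, 4), p=round(test.p, 6))


_STAGE_FUNCS = {"simulate": _stage_simulate, "diff": _stage_diff,
                "enrich": _stage_enrich, "glycogen": _stage_glycogen,
                "assay": _stage_assay}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the selected stages in dependency order.

    A stage failure is recorded in the manifest and aborts its dependents;
    independent stages still run. The manifest is always written to
    ``<out_dir>/manifest.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed,
                           config_hash=io.config_hash(config.as_dict()))
    state: dict = {}
    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        deps = STAGE_DEPS.get(stage, ())
        broken = [d for d in deps if d in stages
                  and manifest.stages.get(d, {}).get("status") != "ok"]
        if broken:
            manifest.record(stage, "skipped",
                            reason=f"dependency failed: {broken}")
            continue
        if any(d not in stages and d not in manifest.stages for d in deps):
            # dependency not selected: run it silently to build state
            for d in deps:
                if d not in manifest.stages:
                    _STAGE_FUNCS[d](config, out, manifest, state)
        try:
            _STAGE_FUNCS[stage](config, out, manifest, state)
        except Exception as exc:      # recorded, not raised: manifest contract
            logger.error("stage %s failed: %s", stage, exc)
            manifest.record(stage, "failed", error=str(exc),
                            trace=traceback.format_exc(limit=3))
    manifest.write(out / "manifest.json")
    return manifest
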
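"""End-to-end orchestration: inputs -> images -> model -> pathway table.

``run_full_pipeline`` executes simulate-or-read, image building, ordering,
optional cross-validation, interpretation-model training, X-Grad-CAM
explanation and key-pathway identification, writing every artifact plus a
manifest (config echo, seed, per-file SHA-256 checksums) into one run
directory.  With a fixed seed the whole run is bit-reproducible, so two
manifests from the same config are identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .att_cnn import ModelSpec, TrainedModel, AttCnn, train_model
from .evaluation import repeated_cv, fit_fold_transforms
from .key_pathways import identify_key_pathways
from .synthetic import SyntheticCohortSpec, generate_cohort

logger = logging.getLogger("pathcam")

__all__ = ["RunConfig", "run_full_pipeline", "save_model", "load_model"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; ``seed`` is required."""

    seed: int
    out_dir: str
    # either synthetic generation ...
    synthetic: dict | None = None
    # ... or paths to real inputs
    expression_paths: dict[str, str] = field(default_factory=dict)  # omics -> path
    gmt_path: str | None = None
    annotations_path: str | None = None
    min_genes: int = 2
    max_genes: int = 500
    # image construction
    q: int = 1
    # model (fields merged into ModelSpec)
    model: dict = field(default_factory=dict)
    # cross-validation
    run_cv: bool = True
    cv_k: int = 5
    cv_repeats: int = 30
    # interpretation
    alpha_sig: float = 0.001
    min_hotspot_size: int = 1
    cam_layer: str = "attended_input"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.synthetic is None and not self.expression_paths:
            raise ValueError("either synthetic spec or expression paths required")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in d:
            raise ValueError("config missing required seed")
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_model(trained: TrainedModel, model_dir: str | Path) -> None:
    model_dir = Path(model_dir)
    model_dir.mkdir(parents=True, exist_ok=True)
    np.savez(model_dir / "params.npz", **trained.model.params,
             cov_mean=trained.cov_mean, cov_std=trained.cov_std,
             class_weights=trained.class_weights)
    spec_d = dataclasses.asdict(trained.spec)
    spec_d["conv_kernel"] = list(spec_d["conv_kernel"])
    hist = {k: v for k, v in trained.history.items()}
    (model_dir / "spec.json").write_text(json.dumps(
        {"spec": spec_d, "history": hist}, indent=2))


def load_model(model_dir: str | Path) -> TrainedModel:
    model_dir = Path(model_dir)
    meta = json.loads((model_dir / "spec.json").read_text())
    spec_d = meta["spec"]
    spec_d["conv_kernel"] = tuple(spec_d["conv_kernel"])
    spec = ModelSpec(**spec_d)
    data = np.load(model_dir / "params.npz")
    model = AttCnn(spec)
    model.set_params({k: data[k] for k in AttCnn.PARAM_NAMES})
    return TrainedModel(model, spec, data["class_weights"],
                        data["cov_mean"], data["cov_std"], meta["history"])


def _load_inputs(config: RunConfig, out: Path):
    if config.synthetic is not None:
        syn = dict(config.synthetic)
        syn.setdefault("seed", config.seed)
        cohort = generate_cohort(SyntheticCohortSpec(**syn))
        data_dir = out / "data"
        cohort.write(data_dir)
        gt = {k: v for k, v in cohort.ground_truth.items() if k != "factors"}
        gt["planted"] = list(gt["planted"])
        (data_dir / "ground_truth.json").write_text(json.dumps(gt, indent=2))
        return cohort.exprs, cohort.pathways, cohort.annotations
    exprs = [pio.read_expression_matrix(path, omics_name=name)
             for name, path in config.expression_paths.items()]
    universe = set().union(*(e.gene_ids for e in exprs))
    pathways = pio.read_gene_sets(config.gmt_path, config.min_genes,
                                  config.max_genes, universe)
    annotations = pio.read_sample_annotations(config.annotations_path)
    return exprs, pathways, annotations


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        exprs, pathways, annotations = _load_inputs(config, out)
        ann = annotations.aligned_to(exprs[0].sample_ids)
        n_cov = ann.covariate_matrix().shape[1]

        stage = "images"
        all_idx = np.arange(exprs[0].n_samples)
        projections, order_names, images = fit_fold_transforms(
            exprs, pathways, config.q, all_idx)
        pio.save_image_set(images, out / "images")
        pd.DataFrame({"rank": np.arange(1, len(order_names) + 1),
                      "pathway": order_names}).to_csv(
            out / "order.tsv", sep="\t", index=False)

        spec = ModelSpec(
            in_channels=len(exprs), image_height=len(pathways),
            image_width=config.q, n_covariates=n_cov,
            seed=config.seed, **config.model)

        if config.run_cv:
            stage = "cv"
            cv = repeated_cv(exprs, pathways, ann, spec, config.q,
                             k=config.cv_k, repeats=config.cv_repeats,
                             seed=config.seed)
            rows = [{"repeat": r, "fold": f, "auc": cv.aucs[r, f]}
                    for r in range(cv.repeats) for f in range(cv.k)]
            pd.DataFrame(rows).to_csv(out / "cv_results.tsv", sep="\t",
                                      index=False, float_format="%.6f")
            (out / "cv_summary.json").write_text(json.dumps(
                {"mean_auc": round(cv.mean, 6), "sd_auc": round(cv.std, 6),
                 "k": cv.k, "repeats": cv.repeats}, indent=2))
            logger.info("CV mean AUC %.3f ± %.3f", cv.mean, cv.std)

        stage = "train"
        trained = train_model(images, ann, spec, validation=None)
        save_model(trained, out / "model")

        stage = "interpret"
        diffs, result = identify_key_pathways(
            trained, images, ann, alpha_sig=config.alpha_sig,
            min_size=config.min_hotspot_size, layer=config.cam_layer)
        result.table.to_csv(out / "key_pathways.tsv", sep="\t", index=False,
                            float_format="%.6g")
        hs = [{"omics": result.omics_names[h.omics_index],
               "size": h.size, "pixels": h.pixels} for h in result.hotspots]
        (out / "hotspots.json").write_text(json.dumps(hs, indent=2))
        np.savetxt(out / "adjusted_p.tsv", result.adjusted_p,
                   delimiter="\t", fmt="%.6g")
    except Exception:
        logger.error("pipeline failed at stage %r; partial outputs kept in %s",
                     stage, out)
        raise

    stage_files = sorted(p for p in out.rglob("*") if p.is_file()
                         and p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in stage_files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
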
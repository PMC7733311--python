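"""End-to-end orchestration: simulate -> cluster -> features -> select ->
classify -> report, driven by a single YAML-able config with a mandatory seed.

Every stage writes its artifact to the output directory so stages can be
inspected and re-run independently; a manifest records config, seed, stage
timings and SHA-256 hashes of all outputs.  Reruns with identical config and
seed reproduce identical numbers.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, features, mixture, report, selection, synth
from .io import FixationDataset, filter_image, load_fixations, write_fixations

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    seed: int
    input_path: str | None = None  # fixation CSV; None -> synthetic cohort
    synthetic_images: list[str] = field(default_factory=lambda: ["P2"])
    effect_scale: float = 1.0  # 0 = null cohort
    images: list[str] | None = None  # None -> all images present
    k_min: int = 2
    k_max: int = 20
    fixed_k: int | None = None  # skip BIC search when set
    n_restarts: int = 10
    em_tol: float = 1e-6
    em_max_iter: int = 500
    assignment_rule: str = "paper_ratio"
    normalizations: list[str] = field(
        default_factory=lambda: ["Z0", "Z1", "Z2", "Z3"]
    )
    selector_method: str = "sfs"  # "sfs", "t_statistic" or "none"
    selector_n: int = 5
    classifiers: list[dict] = field(
        default_factory=lambda: [{"family": "svm", "kernel": "sigmoid"}]
    )
    cv_mode: str = "replicate_paper"
    output_dir: str = "gazeclass_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for z in self.normalizations:
            if z not in features.NORMALIZATIONS:
                raise ValueError(f"unknown normalization {z!r}")
        if self.selector_method not in ("sfs", "t_statistic", "none"):
            raise ValueError(f"unknown selector {self.selector_method!r}")
        if self.cv_mode not in ("replicate_paper", "strict"):
            raise ValueError(f"unknown cv mode {self.cv_mode!r}")
        for c in self.classifiers:
            classify.ClassifierSpec(**c)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


class _StageError(RuntimeError):
    pass


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    A stage failure aborts with the stage name after writing the partial
    manifest.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "stages": [],
        "outputs": {},
    }
    t_all = time.perf_counter()

    def stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest["failed_stage"] = name
            manifest["error"] = str(exc)
            _write_json(out / "manifest.json", manifest)
            raise _StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": name, "seconds": round(time.perf_counter() - t0, 4)}
        )
        return result

    def record(path: Path) -> None:
        manifest["outputs"][str(path.relative_to(out))] = _sha256(path)

    # ---- input ----------------------------------------------------------
    def load() -> FixationDataset:
        if cfg.input_path:
            return load_fixations(cfg.input_path)
        spec = synth.default_spec(image_ids=cfg.synthetic_images, seed=cfg.seed)
        spec = synth.amplify_effects(spec, cfg.effect_scale)
        ds, _truth = synth.generate_cohort(spec, seed=cfg.seed)
        path = out / "fixations.csv"
        write_fixations(ds, path)
        record(path)
        return ds

    ds = stage("input", load)
    image_ids = cfg.images or ds.images
    rng = np.random.default_rng(cfg.seed)

    grid_cells: dict[str, dict[tuple[str, str], float]] = {
        classify.ClassifierSpec(**c).name: {} for c in cfg.classifiers
    }
    image_stats: list[report.ImageGroupStats] = []

    for image_id in image_ids:
        ds_img = filter_image(ds, image_id)
        pts = ds_img.positions()
        em_seed = int(rng.integers(2**31 - 1))

        def cluster():
            kwargs = dict(
                tol=cfg.em_tol, max_iter=cfg.em_max_iter, n_restarts=cfg.n_restarts
            )
            if cfg.fixed_k is not None:
                model = mixture.fit_em(pts, cfg.fixed_k, seed=em_seed, **kwargs)
                trace = [{"k": cfg.fixed_k, "bic": mixture.bic(model)}]
            else:
                model, trace = mixture.select_k(
                    pts, cfg.k_min, cfg.k_max, seed=em_seed, **kwargs
                )
            path = out / f"model_{image_id}.json"
            _write_json(
                path,
                {
                    "model": model.to_dict(),
                    "bic": mixture.bic(model),
                    "bic_trace": trace,
                    "ellipses": mixture.cluster_ellipses(model),
                },
            )
            record(path)
            return model

        model = stage(f"cluster[{image_id}]", cluster)

        def assign():
            a = mixture.assign_clusters(pts, model, rule=cfg.assignment_rule)
            df = ds_img.to_dataframe()
            df["cluster"] = a.labels
            path = out / f"assignments_{image_id}.csv"
            df.to_csv(path, index=False)
            record(path)
            return a

        assignment = stage(f"assign[{image_id}]", assign)

        def extract():
            fm = features.extract_features(
                ds_img, assignment, model.n_components, image_id
            )
            path = out / f"features_{image_id}_Z0.csv"
            fm.write(path)
            record(path)
            record(path.with_suffix(".json"))
            return fm

        fm0 = stage(f"features[{image_id}]", extract)
        image_stats.append(
            report.group_cluster_stats(fm0, optimal_k=model.n_components)
        )

        def classify_all():
            for z in cfg.normalizations:
                fmz = features.normalize(fm0, z, all_images=[fm0])
                if z != "Z0":
                    path = out / f"features_{image_id}_{z}.csv"
                    fmz.write(path)
                    record(path)
                for cdict in cfg.classifiers:
                    spec = classify.ClassifierSpec(**cdict)
                    if cfg.selector_method == "none":
                        sel_idx = None
                        sel_doc = None
                    elif cfg.selector_method == "t_statistic":
                        sel = selection.t_rank_select(fmz, cfg.selector_n)
                        sel_idx, sel_doc = sel.selected, sel.to_dict()
                    else:
                        sel = selection.sfs_select(fmz, cfg.selector_n, spec)
                        sel_idx, sel_doc = sel.selected, sel.to_dict()
                    if cfg.cv_mode == "strict":
                        def selector(train_fm):
                            if cfg.selector_method == "none":
                                return list(range(train_fm.values.shape[1]))
                            if cfg.selector_method == "t_statistic":
                                return selection.t_rank_select(
                                    train_fm, cfg.selector_n
                                ).selected
                            return selection.sfs_select(
                                train_fm, cfg.selector_n, spec
                            ).selected

                        cv = classify.loocv(
                            fmz, spec, mode="strict", selector=selector
                        )
                    else:
                        cv = classify.loocv(fmz, spec, feature_idx=sel_idx)
                    path = out / f"cv_{image_id}_{z}_{spec.name}.json"
                    _write_json(
                        path,
                        {
                            "image": image_id,
                            "normalization": z,
                            "classifier": spec.name,
                            "selection": sel_doc,
                            "accuracy": cv.accuracy,
                            "subjects": cv.subject_ids,
                            "truth": cv.truth,
                            "predictions": cv.predictions,
                        },
                    )
                    record(path)
                    grid_cells[spec.name][(image_id, z)] = cv.accuracy

        stage(f"classify[{image_id}]", classify_all)

    def render_report():
        grids = []
        for name, cells in grid_cells.items():
            grid = report.build_accuracy_grid(cells, title=name)
            path = out / f"accuracy_{name}.csv"
            grid.to_dataframe().to_csv(path)
            record(path)
            (out / f"accuracy_{name}.md").write_text(grid.to_markdown())
            record(out / f"accuracy_{name}.md")
            grids.append(grid)
        summary = {
            "per_normalization_accuracy": report.aggregate_grids(grids),
            "group_stats": report.summarize_t_sums(image_stats),
        }
        path = out / "summary.json"
        _write_json(path, summary)
        record(path)
        return summary

    stage("report", render_report)
    manifest["total_seconds"] = round(time.perf_counter() - t_all, 4)
    _write_json(out / "manifest.json", manifest)
    return manifest
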
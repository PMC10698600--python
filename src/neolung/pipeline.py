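"""End-to-end orchestration: phantom -> raters -> segmentation ->
reconstruction -> features -> cohort models, with a provenance manifest.

Each stage reads its inputs from the output directory of the previous
stage and writes files plus a content hash into the run manifest, so a
run is resumable from any prefix of its stages and reruns with identical
seeds produce identical hashes for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import MriVolume
from .features import extract_features, features_to_frame
from .image_io import load_mask, load_volume, save_mask, save_volume
from .models import CVPlan, build_design, nested_cv_classify
from .phantom import CohortSpec, generate_cohort, generate_phantom, random_phantom_spec, simulate_raters
from .reconstruction import reconstruct
from .segmentation import SegModelConfig, majority_vote, predict_mask, train_segmenter

STAGES = ("phantom", "raters", "segment", "reconstruct", "features", "cohort", "classify")


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's output is missing; the message names the stage."""


@dataclass
class RunManifest:
    version: str = __version__
    seeds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256

    def record(self, path: Path) -> None:
        self.outputs[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing {path.name}; run the '{producing_stage}' stage first"
        )
    return path


def _subject_ids(cfg: dict) -> list[str]:
    return [f"sub{idx:02d}" for idx in range(int(cfg.get("n_subjects", 4)))]


def run_pipeline(config: dict, out_dir: str | Path, stages: list[str] | None = None) -> RunManifest:
    """Execute the requested stages in canonical order.

    ``config`` holds one section per stage (see :data:`STAGES`); a global
    ``seed`` drives every stage-level random draw.  Returns the manifest,
    which is also written to ``out_dir/manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages or config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")
    stages = [s for s in STAGES if s in stages]
    seed = int(config.get("seed", 0))
    manifest = RunManifest(seeds={"global": seed}, config=config)

    pcfg = dict(config.get("phantom", {}))
    subjects = _subject_ids(pcfg)
    spacing = tuple(pcfg.get("spacing", (1.5, 1.5, 4.4)))
    grid = tuple(pcfg.get("grid_shape", (64, 64, 24)))

    def timed(name, fn):
        t0 = time.perf_counter()
        fn()
        manifest.timings_s[name] = round(time.perf_counter() - t0, 3)

    if "phantom" in stages:
        def _phantom():
            for i, sid in enumerate(subjects):
                spec = random_phantom_spec(
                    seed + i,
                    grid_shape=grid,
                    spacing=spacing,
                    ap_gradient_slope=float(pcfg.get("ap_gradient_slope", 0.0)),
                    surface_perturbation_amplitude=float(
                        pcfg.get("surface_perturbation_amplitude", 0.0)
                    ),
                    noise_sd=float(pcfg.get("noise_sd", 4.0)),
                )
                vol, mask, truth = generate_phantom(spec)
                save_volume(vol, out / f"{sid}_volume.nii.gz")
                save_mask(mask, out / f"{sid}_truth.nii.gz")
                (out / f"{sid}_truth.json").write_text(truth.to_json())
                for name in (f"{sid}_volume.nii.gz", f"{sid}_truth.nii.gz", f"{sid}_truth.json"):
                    manifest.record(out / name)
        timed("phantom", _phantom)

    rcfg = dict(config.get("raters", {}))
    n_raters = int(rcfg.get("n_raters", 3))
    if "raters" in stages:
        def _raters():
            for i, sid in enumerate(subjects):
                mask = load_mask(_require(out / f"{sid}_truth.nii.gz", "phantom"))
                for r, rm in enumerate(
                    simulate_raters(mask, n_raters, float(rcfg.get("jitter_mm", 1.5)), seed + 100 + i)
                ):
                    path = out / f"{sid}_rater{r + 1}.nii.gz"
                    save_mask(rm, path)
                    manifest.record(path)
        timed("raters", _raters)

    scfg = dict(config.get("segment", {}))
    if "segment" in stages:
        def _segment():
            volumes = [load_volume(_require(out / f"{sid}_volume.nii.gz", "phantom")) for sid in subjects]
            models = []
            for r in range(n_raters):
                masks = [
                    load_mask(_require(out / f"{sid}_rater{r + 1}.nii.gz", "raters"))
                    for sid in subjects
                ]
                cfg = SegModelConfig(
                    depth=int(scfg.get("depth", 2)),
                    base_channels=int(scfg.get("base_channels", 4)),
                    epochs=int(scfg.get("epochs", 6)),
                    batch_size=int(scfg.get("batch_size", 8)),
                    learning_rate=float(scfg.get("learning_rate", 1e-3)),
                    seed=seed + 200 + r,
                )
                model = train_segmenter(volumes, masks, cfg)
                model.save(out / f"model_rater{r + 1}")
                models.append(model)
            for sid, vol in zip(subjects, volumes):
                members = [predict_mask(m, vol, threshold=0.5) for m in models]
                fused = majority_vote(members)
                path = out / f"{sid}_pred.nii.gz"
                save_mask(fused, path)
                manifest.record(path)
        timed("segment", _segment)

    if "reconstruct" in stages:
        def _reconstruct():
            for sid in subjects:
                pred = out / f"{sid}_pred.nii.gz"
                source = pred if pred.exists() else _require(out / f"{sid}_truth.nii.gz", "phantom or segment")
                mask = load_mask(source)
                vol = load_volume(_require(out / f"{sid}_volume.nii.gz", "phantom"))
                recon = reconstruct(mask, intensities=vol)
                np.save(out / f"{sid}_labels.npy", recon.labels)
                (out / f"{sid}_transform.json").write_text(recon.transform_json())
                manifest.record(out / f"{sid}_transform.json")
        timed("reconstruct", _reconstruct)

    if "features" in stages:
        def _features():
            sets = []
            for sid in subjects:
                labels = np.load(_require(out / f"{sid}_labels.npy", "reconstruct"))
                vol = load_volume(_require(out / f"{sid}_volume.nii.gz", "phantom"))
                transform = json.loads((out / f"{sid}_transform.json").read_text())
                from .reconstruction import LungReconstruction

                recon = LungReconstruction(
                    labels=labels,
                    spacing=tuple(transform["spacing"]),
                    intensities=vol.intensities,
                    rotation=np.array(transform["rotation"]),
                    translation=np.array(transform["translation"]),
                )
                sets.append(extract_features(recon, subject_id=sid))
            frame = features_to_frame(sets)
            frame.to_csv(out / "features.csv")
            manifest.record(out / "features.csv")
        timed("features", _features)

    ccfg = dict(config.get("cohort", {}))
    if "cohort" in stages:
        def _cohort():
            spec = CohortSpec(
                n_subjects=int(ccfg.get("n_subjects", 150)),
                effect_sizes={str(k): float(v) for k, v in ccfg.get("effect_sizes", {}).items()},
                seed=seed + 300,
            )
            generate_cohort(spec).to_csv(out / "cohort.csv", index=False)
            manifest.record(out / "cohort.csv")
        timed("cohort", _cohort)

    kcfg = dict(config.get("classify", {}))
    if "classify" in stages:
        def _classify():
            cohort = pd.read_csv(_require(out / "cohort.csv", "cohort"))
            X, y = build_design(cohort, kcfg.get("selector", "L"))
            plan = CVPlan(
                repetitions=int(kcfg.get("repetitions", 2)),
                seed=seed + 400,
            )
            result = nested_cv_classify(
                X,
                y,
                scenario=kcfg.get("scenario", "binary_any"),
                model_family=kcfg.get("model_family", "random_forest"),
                reduction=kcfg.get("reduction", "none"),
                plan=plan,
                n_search=int(kcfg.get("n_search", 5)),
            )
            (out / "classify_result.json").write_text(json.dumps(result.summary(), indent=2))
            manifest.record(out / "classify_result.json")
        timed("classify", _classify)

    manifest.save(out / "manifest.json")
    return manifest
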
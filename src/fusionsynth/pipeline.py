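"""End-to-end orchestration: configuration, data staging, training, evaluation.

The pipeline has three stages mirroring the model's structure —
self-supervised pretraining of each modality backbone, adversarial training
of the fused synthesis network, and evaluation/visualisation on a held-out
case split — driven by one :class:`RunConfig` and one seed.  Cases (never
individual slices) are split between train and test so adjacent-slice
correlation cannot leak across the split.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .backbone import BackboneConfig, UNetBackbone
from .gan import (Discriminator, DiscriminatorConfig, GANModels,
                  GANOptimizers, Generator, SynthesisModel, train_step)
from .fusion import FusionNetwork
from .metrics import MetricsRecord, evaluate_volumes
from .mri_io import (Volume, extract_patches, scale_intensity, slice_triplets,
                     stitch_volume, unscale_intensity)
from .phantoms import PhantomSpec, generate_dataset
from .pretext import (IndexBranch, TripletCompressor, pretrain_joint,
                      triplet_dataset)


@dataclass
class RunConfig:
    """Everything one reproducible run needs.

    The tiny profile (64×64 phantoms, narrow networks) is the default: it
    exercises the full method on one CPU in minutes.  Larger geometry is a
    matter of configuration, not code.
    """

    # data
    n_cases: int = 10
    phantom: PhantomSpec = field(default_factory=PhantomSpec.tiny)
    train_fraction: float = 0.8
    patch_shape: tuple[int, int] = (64, 64)
    # model
    backbone: BackboneConfig = field(default_factory=BackboneConfig.tiny)
    discriminator_channels: tuple[int, ...] = (8, 16, 32, 64, 1)
    attention_ratio: int = 8
    # optimisation
    lambda1: float = 100.0
    lambda2: float = 10.0
    lr: float = 1e-3
    batch_size: int = 4
    pretrain_steps: int = 60
    gan_steps: int = 400
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs/default"
    skip_pretrain: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        phantom = PhantomSpec(**raw.pop("phantom", {})) if "phantom" in raw \
            else PhantomSpec.tiny()
        backbone = BackboneConfig(**raw.pop("backbone", {})) if "backbone" in raw \
            else BackboneConfig.tiny()
        for key in ("patch_shape", "discriminator_channels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return RunConfig(phantom=phantom, backbone=backbone, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def split_cases(case_ids: list[str], fraction: float = 0.8,
                seed: int = 0) -> tuple[list[str], list[str]]:
    """Disjoint, exhaustive case-level train/test split (seeded shuffle)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"train fraction must be in (0,1), got {fraction}")
    if len(case_ids) < 2:
        raise ValueError("need at least 2 cases to split")
    ids = list(case_ids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = max(1, min(len(ids) - 1, int(round(fraction * len(ids)))))
    train = sorted(ids[i] for i in order[:n_train])
    test = sorted(ids[i] for i in order[n_train:])
    return train, test


# -- model construction ------------------------------------------------------


def build_models(cfg: RunConfig, seed: int | None = None) -> GANModels:
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    b1 = UNetBackbone(cfg.backbone, rng)
    b2 = UNetBackbone(cfg.backbone, rng)
    fusion = FusionNetwork(cfg.backbone, rng, attention_ratio=cfg.attention_ratio)
    generator = Generator(fusion, rng, attention_ratio=cfg.attention_ratio)
    d_pix = Discriminator(DiscriminatorConfig(
        channels=cfg.discriminator_channels, activation="leaky_relu"), rng)
    d_feat = Discriminator(DiscriminatorConfig(
        channels=cfg.discriminator_channels, activation="relu"), rng)
    return GANModels(model=SynthesisModel(b1, b2, fusion, generator),
                     d_pixel=d_pix, d_feature=d_feat)


def save_checkpoint(path: str | Path, modules: dict, config: dict) -> None:
    """Single-file .npz checkpoint: parameter arrays plus embedded config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for name, module in modules.items():
        for key, arr in module.state_dict().items():
            arrays[f"{name}/{key}"] = arr
    arrays["__config__"] = np.frombuffer(
        json.dumps(config, default=str).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_checkpoint(path: str | Path, modules: dict) -> dict:
    """Restore parameters in place; returns the embedded config dict."""
    with np.load(path) as data:
        for name, module in modules.items():
            prefix = f"{name}/"
            state = {k[len(prefix):]: data[k] for k in data.files
                     if k.startswith(prefix)}
            module.load_state_dict(state)
        cfg = json.loads(bytes(data["__config__"]).decode())
    return cfg


# -- data staging ------------------------------------------------------------


@dataclass
class CaseData:
    """One case's scaled patch stacks, ready for training/evaluation."""

    case_id: str
    volumes: dict[str, Volume]              # raw (unscaled)
    scaled: dict[str, Volume]
    scale_params: dict

    def paired_patches(self, patch_shape) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
        per_mod = {m: extract_patches(self.scaled[m], patch_shape)
                   for m in ("source1", "source2", "target")}
        out = []
        for p1, p2, pt in zip(*per_mod.values()):
            out.append((p1.pixels, p2.pixels, pt.pixels))
        return out


def stage_cases(cfg: RunConfig) -> dict[str, CaseData]:
    triples = generate_dataset(cfg.phantom, cfg.n_cases)
    staged = {}
    for (v1, v2, vt) in triples:
        scaled, params = {}, {}
        for v in (v1, v2, vt):
            sv, sp = scale_intensity(v)
            scaled[v.modality] = sv
            params[v.modality] = sp
        staged[v1.case_id] = CaseData(
            case_id=v1.case_id,
            volumes={v.modality: v for v in (v1, v2, vt)},
            scaled=scaled, scale_params=params)
    return staged


def _training_arrays(cases: dict[str, CaseData], train_ids: list[str],
                     patch_shape) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    out = []
    for cid in train_ids:
        out.extend(cases[cid].paired_patches(patch_shape))
    return out


# -- inference ---------------------------------------------------------------


def synthesize_volume(models: GANModels, source1: Volume, source2: Volume,
                      patch_shape: tuple[int, int],
                      target_scale=None) -> Volume:
    """Patch-wise synthesis of the target volume from two source volumes.

    Each source is scaled per-volume to [-1,1]; every slice is split into
    the overlapping corner patches, synthesized, stitched back with overlap
    averaging, and mapped out of [-1,1] with ``target_scale`` when given
    (e.g. the ground-truth scale at evaluation time) or the mean of the two
    source scales otherwise.
    """
    s1, p1 = scale_intensity(source1)
    s2, p2 = scale_intensity(source2)
    patches1 = extract_patches(s1, patch_shape)
    patches2 = extract_patches(s2, patch_shape)
    out_patches = []
    model = models.model
    was_training = model.training
    model.eval()
    for rec1, rec2 in zip(patches1, patches2):
        pred = model.synthesize(rec1.pixels[None, None],
                                rec2.pixels[None, None])[0, 0]
        out_patches.append(replace(rec1, pixels=pred, modality="synthesized"))
    model.train(was_training)
    stitched = stitch_volume(out_patches, source1.shape,
                             modality="synthesized", case_id=source1.case_id)
    if target_scale is None:
        from .mri_io import ScaleParams
        target_scale = ScaleParams(vmin=(p1.vmin + p2.vmin) / 2,
                                   vmax=(p1.vmax + p2.vmax) / 2)
    return Volume(unscale_intensity(stitched.data, target_scale),
                  modality="synthesized", case_id=source1.case_id)


def evaluate_cases(models: GANModels, cases: dict[str, CaseData],
                   case_ids: list[str], patch_shape) -> dict[str, MetricsRecord]:
    records = {}
    for cid in case_ids:
        case = cases[cid]
        pred = synthesize_volume(models, case.volumes["source1"],
                                 case.volumes["source2"], patch_shape,
                                 target_scale=case.scale_params["target"])
        records[cid] = evaluate_volumes(case.volumes["target"], pred)
    return records


def copy_source_baseline(cases: dict[str, CaseData],
                         case_ids: list[str],
                         source: str = "source1") -> dict[str, MetricsRecord]:
    """Metrics for the trivial predictor that copies one source volume."""
    return {cid: evaluate_volumes(cases[cid].volumes["target"],
                                  cases[cid].volumes[source])
            for cid in case_ids}


# -- full pipeline -----------------------------------------------------------


@dataclass
class PipelineResult:
    config: RunConfig
    train_ids: list[str]
    test_ids: list[str]
    models: GANModels
    pretrain_traces: dict[str, list[float]]
    gan_reports: list
    test_metrics: dict[str, MetricsRecord]
    baseline_metrics: dict[str, MetricsRecord]

    def mean_test(self, attr: str) -> float:
        return float(np.mean([getattr(r, attr)
                              for r in self.test_metrics.values()]))

    def mean_baseline(self, attr: str) -> float:
        return float(np.mean([getattr(r, attr)
                              for r in self.baseline_metrics.values()]))


def run_pipeline(cfg: RunConfig, write_artifacts: bool = True) -> PipelineResult:
    """Pretrain → adversarial training → test-split evaluation.

    Deterministic given ``cfg.seed``; artifacts (checkpoint, loss logs,
    manifest) go under ``cfg.out_dir`` unless ``write_artifacts`` is False.
    """
    cases = stage_cases(cfg)
    train_ids, test_ids = split_cases(sorted(cases), cfg.train_fraction,
                                      cfg.seed)
    models = build_models(cfg)

    pretrain_traces: dict[str, list[float]] = {}
    if not cfg.skip_pretrain and cfg.pretrain_steps > 0:
        rng = np.random.default_rng(cfg.seed + 1)
        for mod_name, backbone in (("source1", models.model.backbone1),
                                   ("source2", models.model.backbone2)):
            patches = []
            triplets = []
            for cid in train_ids:
                vol = cases[cid].scaled[mod_name]
                patches.extend(p.pixels for p in
                               extract_patches(vol, cfg.patch_shape))
                trips = slice_triplets(vol)
                triplets.extend(triplet_dataset(trips, vol.shape[0]))
            compressor = TripletCompressor(rng)
            branch = IndexBranch(cfg.backbone.channels_at(
                cfg.backbone.depth - 1), rng)
            mask_size = (max(4, cfg.patch_shape[0] // 4),) * 2
            pretrain_traces[mod_name] = pretrain_joint(
                backbone, compressor, branch, patches, triplets,
                steps=cfg.pretrain_steps, seed=cfg.seed + 17,
                batch_size=cfg.batch_size, lr=cfg.lr,
                mask_size=mask_size)

    train_data = _training_arrays(cases, train_ids, cfg.patch_shape)
    optimizers = GANOptimizers.build(models, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 2)
    reports = []
    for step in range(cfg.gan_steps):
        idx = rng.integers(0, len(train_data),
                           size=min(cfg.batch_size, len(train_data)))
        x1 = np.stack([train_data[i][0] for i in idx])[:, None]
        x2 = np.stack([train_data[i][1] for i in idx])[:, None]
        y = np.stack([train_data[i][2] for i in idx])[:, None]
        reports.append(train_step((x1, x2, y), models, optimizers,
                                  lambda1=cfg.lambda1, lambda2=cfg.lambda2))

    test_metrics = evaluate_cases(models, cases, test_ids, cfg.patch_shape)
    baseline = copy_source_baseline(cases, test_ids)

    result = PipelineResult(cfg, train_ids, test_ids, models,
                            pretrain_traces, reports, test_metrics, baseline)
    if write_artifacts:
        _write_artifacts(result)
    return result


def _write_artifacts(result: PipelineResult) -> None:
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models = result.models
    save_checkpoint(out / "checkpoint.npz",
                    {"model": models.model, "d_pixel": models.d_pixel,
                     "d_feature": models.d_feature},
                    result.config.to_dict())
    with open(out / "gan_losses.jsonl", "w") as fh:
        for i, rep in enumerate(result.gan_reports):
            fh.write(json.dumps({"step": i, "l_grec": rep.l_grec,
                                 "l_pixel_adv": rep.l_pixel_adv,
                                 "l_feature_adv": rep.l_feature_adv,
                                 "l_rec": rep.l_rec, "total": rep.total}) + "\n")
    for mod_name, trace in result.pretrain_traces.items():
        with open(out / f"pretrain_{mod_name}.csv", "w") as fh:
            fh.write("step,loss\n")
            fh.writelines(f"{i},{v}\n" for i, v in enumerate(trace))
    manifest = {
        "config": result.config.to_dict(),
        "config_hash": result.config.config_hash(),
        "seed": result.config.seed,
        "train_cases": result.train_ids,
        "test_cases": result.test_ids,
        "test_metrics": {cid: json.loads(rec.to_json())
                         for cid, rec in result.test_metrics.items()},
        "baseline_metrics": {cid: json.loads(rec.to_json())
                             for cid, rec in result.baseline_metrics.items()},
        "artifacts": ["checkpoint.npz", "gan_losses.jsonl"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
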
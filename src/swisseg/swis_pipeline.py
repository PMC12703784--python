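"""Model assembly and the two-phase training protocol.

Phase 1 trains the Style VAE on channel statistics of backbone features
(content from the laboratory domain, style from the small field validation
split) with Adam. Phase 2 freezes the VAE and trains the segmentation model
with SGD: per iteration a class-stratified laboratory batch is passed through
the first backbone stage, stochastically re-styled by RAIN, adversarially
re-normalized by DGB (whose statistics ascend the task loss through a
gradient reversal layer), and scored by the decode head; the objective is
pixel cross-entropy plus a weighted consistency penalty on pooled bottleneck
features of the stylized branch.

RAIN and DGB are training-time regularizers only — inference is the plain
network. The default backbone is a deliberately small 3-stage convolutional
encoder with a 1x1 decode head and nearest upsampling, sized so the full
benchmark runs on one CPU; any module exposing the same stage interface can
replace it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import SGD, Adam, Tensor, cross_entropy
from .data_io import stratified_batches
from .dgb import AdversarialStats, GrlConfig, adversarial_normalize, consistency_loss
from .feature_statistics import compute_channel_stats, moment_inject
from .layers import Conv2d, Module
from .metrics_eval import ClassMap, ConfusionCounts, compute_report, confusion_counts
from .rain import (
    RainWeights,
    StyleVAE,
    content_loss,
    kl_loss,
    rain_forward,
    rain_total_loss,
    reconstruction_loss,
    style_loss,
)

__all__ = [
    "TrainConfig",
    "AblationConfig",
    "SegmentationModel",
    "task_loss",
    "total_loss",
    "train_rain_phase",
    "train_segmentation_phase",
    "evaluate",
    "run_ablation",
    "summarize_ablation",
    "train_variant",
    "load_benchmark",
    "DEFAULT_VARIANTS",
]


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the published protocol,
    :meth:`desk` scales iteration counts and batch size for CPU runs."""

    n_iterations: int = 20_000
    rain_iterations: int = 2_000
    # brief supervised pre-training of the backbone shared by every variant;
    # stands in for an externally pretrained backbone so phase-1 style
    # statistics remain representative during phase 2 (0 = backbone already
    # pretrained)
    warmup_iterations: int = 0
    model_lr: float = 0.03  # alpha, phase-2 SGD
    rain_lr: float = 1e-3  # phase-1 Adam
    phi: float = 0.01  # beta, style perturbation rate (adversarial step size)
    lambda_consist: float = 0.8
    batch_size: int = 64
    style_prob: float = 0.5  # per-sample probability of feature perturbation
    lambda_grl: float = 1.0
    grl_schedule: str = "constant"
    rain_weights: RainWeights = field(default_factory=RainWeights)
    latent_dim: int = 64
    hidden_width: int = 256
    insertion_stage: int = 1  # where RAIN/AdaIN restyle features
    # DGB perturbs a deeper stage than RAIN so the two AdaIN-form transforms
    # compose instead of overwriting each other's channel moments
    dgb_stage: int = 2
    backbone_widths: tuple = (8, 16, 16)
    eps: float = 1e-5

    def __post_init__(self):
        if min(self.model_lr, self.rain_lr, self.phi) <= 0:
            raise ValueError("learning rates must be positive")
        if self.lambda_consist < 0:
            raise ValueError("lambda_consist must be nonnegative")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """CPU-scale profile: iteration counts x0.1, batch size 8."""
        base = dict(n_iterations=2_000, rain_iterations=200, batch_size=8,
                    warmup_iterations=300, grl_schedule="linear-ramp")
        base.update(overrides)
        return cls(**base)

    def grl_config(self) -> GrlConfig:
        return GrlConfig(lambda_grl=self.lambda_grl, phi=self.phi,
                         schedule=self.grl_schedule)


@dataclass
class AblationConfig:
    """Which style components are active; at most one of AdaIN / RAIN."""

    use_adain_fixed: bool = False
    use_rain: bool = False
    use_dgb: bool = False

    def __post_init__(self):
        if self.use_adain_fixed and self.use_rain:
            raise ValueError("AdaIN-fixed and RAIN are mutually exclusive")

    @property
    def any_style(self) -> bool:
        return self.use_adain_fixed or self.use_rain or self.use_dgb


class SegmentationModel(Module):
    """3-stage convolutional encoder + 1x1 decode head + nearest upsampling.

    Stages 1 and 2 stride by 2, so score maps are produced at 1/4 resolution
    and upsampled back: output spatial size equals input size (H, W must be
    multiples of 4).
    """

    def __init__(self, n_classes: int, rng: np.random.Generator,
                 widths=(8, 16, 16)):
        w1, w2, w3 = widths
        self.n_classes = n_classes
        self.widths = tuple(widths)
        self.stage1 = Conv2d(3, w1, 3, rng, stride=2, padding=1)
        self.stage2 = Conv2d(w1, w2, 3, rng, stride=2, padding=1)
        self.stage3 = Conv2d(w2, w3, 3, rng, stride=1, padding=1)
        self.head = Conv2d(w3, n_classes, 1, rng)
        # boundary refinement in class-score space at full resolution
        self.refine = Conv2d(n_classes, n_classes, 3, rng, stride=1, padding=1)

    def stage_channels(self, stage: int) -> int:
        return self.widths[stage - 1]

    def features(self, x: Tensor, upto: int = 1) -> Tensor:
        """Activations after backbone stage ``upto`` (1-based)."""
        f = self.stage1(x).leaky_relu(0.1)
        if upto >= 2:
            f = self.stage2(f).leaky_relu(0.1)
        if upto >= 3:
            f = self.stage3(f).leaky_relu(0.1)
        return f

    def forward_from(self, f: Tensor, stage: int):
        """Continue from post-stage-``stage`` features; returns (scores, pooled)."""
        if stage <= 1:
            f = self.stage2(f).leaky_relu(0.1)
        if stage <= 2:
            f = self.stage3(f).leaky_relu(0.1)
        pooled = f.mean(axis=(2, 3))
        coarse = self.head(f).upsample_nearest(4)
        scores = coarse + self.refine(coarse)
        return scores, pooled

    def extend_features(self, f: Tensor, from_stage: int, to_stage: int) -> Tensor:
        """Run the backbone stages in (from_stage, to_stage]."""
        if from_stage < 2 <= to_stage:
            f = self.stage2(f).leaky_relu(0.1)
        if from_stage < 3 <= to_stage:
            f = self.stage3(f).leaky_relu(0.1)
        return f

    def bottleneck_from(self, f: Tensor, stage: int) -> Tensor:
        """Pooled bottleneck features only (no decode head)."""
        if stage <= 1:
            f = self.stage2(f).leaky_relu(0.1)
        if stage <= 2:
            f = self.stage3(f).leaky_relu(0.1)
        return f.mean(axis=(2, 3))

    def forward(self, x: Tensor):
        return self.forward_from(self.features(x, upto=1), stage=1)


def set_requires_grad(module: Module, flag: bool) -> None:
    for p in module.parameters():
        p.requires_grad = flag


def task_loss(scores: Tensor, mask) -> Tensor:
    """Pixel cross-entropy averaged over non-ignored pixels."""
    return cross_entropy(scores, np.asarray(mask), ignore_index=255)


def total_loss(l_task, l_consist, lambda_consist: float):
    """Combined objective: task loss plus weighted consistency loss."""
    l_task = l_task if isinstance(l_task, Tensor) else Tensor(l_task)
    return l_task + lambda_consist * l_consist


def _to_nchw(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2).astype(np.float32))


def _presence_from_masks(masks: np.ndarray, n_classes: int) -> np.ndarray:
    return np.stack([[(m == c).any() for c in range(1, n_classes)]
                     for m in masks])


def train_rain_phase(vae: StyleVAE, lab_images: np.ndarray,
                     style_images: np.ndarray, cfg: TrainConfig,
                     model: SegmentationModel,
                     rng: np.random.Generator) -> list:
    """Phase 1: optimize the Style VAE losses with Adam; backbone held fixed.

    Returns the per-iteration total-loss trace; raises on divergence.
    """
    if len(lab_images) == 0 or len(style_images) == 0:
        raise ValueError("both domains must be nonempty")
    lab = _to_nchw(lab_images)
    sty = _to_nchw(style_images)
    opt = Adam(vae.parameters(), lr=cfg.rain_lr)
    stage = cfg.insertion_stage
    trace = []
    set_requires_grad(model, False)
    try:
        for it in range(cfg.rain_iterations):
            ci = rng.choice(len(lab), size=min(cfg.batch_size, len(lab)),
                            replace=False)
            si = rng.choice(len(sty), size=len(ci), replace=True)
            content_f = model.features(Tensor(lab[ci]), upto=stage).detach()
            style_f = model.features(Tensor(sty[si]), upto=stage).detach()
            rf = rain_forward(vae, content_f, style_f, rng, eps=cfg.eps)
            lc = content_loss(rf.stylized, content_f, eps=cfg.eps)
            ls = style_loss(rf.stylized, compute_channel_stats(style_f, cfg.eps),
                            eps=cfg.eps)
            lkl = kl_loss(rf.dist)
            lrec = reconstruction_loss(rf.style_vec, rf.style_vec_hat)
            loss = rain_total_loss(lc, ls, lkl, lrec, cfg.rain_weights)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"RAIN training diverged (NaN loss) at iteration {it}; "
                    f"trace={trace[-5:]}")
            trace.append(value)
            opt.zero_grad()
            loss.backward()
            opt.step()
    finally:
        set_requires_grad(model, True)
    return trace


def train_segmentation_phase(model: SegmentationModel, vae: StyleVAE | None,
                             adv: AdversarialStats | None,
                             lab_images: np.ndarray, lab_masks: np.ndarray,
                             style_images: np.ndarray | None,
                             cfg: TrainConfig,
                             ablation: AblationConfig,
                             rng: np.random.Generator) -> dict:
    """Phase 2: train the segmentation model; VAE frozen, DGB stats adversarial.

    Returns a trace dict with per-iteration task and consistency losses.
    """
    n_classes = model.n_classes
    lab = _to_nchw(lab_images)
    masks = np.asarray(lab_masks)
    needs_style = ablation.use_rain or ablation.use_adain_fixed
    if needs_style:
        if style_images is None or len(style_images) == 0:
            raise ValueError("style images required when RAIN/AdaIN is enabled")
        sty = _to_nchw(style_images)
    if ablation.use_rain and vae is None:
        raise ValueError("RAIN enabled but no Style VAE given")
    if ablation.use_dgb and adv is None:
        raise ValueError("DGB enabled but no AdversarialStats given")

    if vae is not None:
        set_requires_grad(vae, False)  # freeze contract
    presence = _presence_from_masks(masks, n_classes)
    manifest = pd.DataFrame({"i": np.arange(len(lab))})
    batches = stratified_batches(manifest, min(cfg.batch_size, len(lab)), rng,
                                 presence=presence)
    opt_model = SGD(model.parameters(), lr=cfg.model_lr)
    opt_adv = SGD(adv.parameters(), lr=cfg.phi) if ablation.use_dgb else None
    grl_cfg = cfg.grl_config()
    stage = cfg.insertion_stage
    use_consist = ablation.any_style and cfg.lambda_consist > 0
    trace = {"task": [], "consist": []}

    def _mix(perturbed, clean, apply_mask):
        # per-sample blend keeps clean statistics in the training stream, so
        # the plain inference network stays on-distribution
        sel = Tensor(apply_mask.astype(np.float32).reshape(-1, 1, 1, 1))
        return sel * perturbed + (1.0 - sel) * clean

    dgb_stage = max(cfg.dgb_stage, stage) if ablation.use_dgb else stage
    last_stage = dgb_stage if ablation.use_dgb else stage
    for it in range(cfg.n_iterations):
        idx = next(batches)
        x = Tensor(lab[idx])
        m = masks[idx]
        f = model.features(x, upto=stage)
        f_clean = f.detach()  # reference view for the consistency pairing
        if ablation.use_rain:
            si = rng.choice(len(sty), size=len(idx), replace=True)
            rain_mask = rng.random(len(idx)) < cfg.style_prob
            style_f = model.features(Tensor(sty[si]), upto=stage).detach()
            styl = rain_forward(vae, f, style_f, rng, eps=cfg.eps).stylized
            f = _mix(styl, f, rain_mask)
        elif ablation.use_adain_fixed:
            si = rng.choice(len(sty), size=len(idx), replace=True)
            rain_mask = rng.random(len(idx)) < cfg.style_prob
            style_f = model.features(Tensor(sty[si]), upto=stage).detach()
            styl = moment_inject(f, compute_channel_stats(style_f, cfg.eps),
                                 eps=cfg.eps)
            f = _mix(styl, f, rain_mask)
        if ablation.use_dgb:
            # DGB perturbs a deeper stage than RAIN (both transforms replace
            # channel moments outright, so same-stage stacking would erase
            # RAIN's style)
            f = model.extend_features(f, stage, dgb_stage)
            lam = grl_cfg.lambda_at(it, cfg.n_iterations)
            dgb_mask = rng.random(len(idx)) < cfg.style_prob
            f = _mix(adversarial_normalize(f, adv, eps=cfg.eps, lambda_grl=lam),
                     f, dgb_mask)
        scores, pooled = model.forward_from(f, stage=last_stage)
        l_task = task_loss(scores, m)
        if use_consist:
            # batch-mean consistency applied to each (clean, stylized) pair of
            # the same image: for a pair the formula reduces to 1/4 |a - b|^2.
            # The clean view is a detached reference, so style perturbations
            # are pulled toward the unperturbed representation without
            # collapsing distinct images onto each other.
            set_requires_grad(model, False)
            z_clean = model.bottleneck_from(f_clean, stage)
            set_requires_grad(model, True)
            l_cons = 0.25 * ((pooled - Tensor(z_clean.data)) ** 2).sum(axis=1).mean()
            loss = total_loss(l_task, l_cons, cfg.lambda_consist)
            trace["consist"].append(l_cons.item())
        else:
            loss = l_task
            trace["consist"].append(0.0)
        value = l_task.item()
        if not np.isfinite(loss.item()):
            raise RuntimeError(f"segmentation training hit NaN at iteration {it}")
        trace["task"].append(value)
        opt_model.zero_grad()
        if opt_adv is not None:
            opt_adv.zero_grad()
        loss.backward()
        opt_model.step()
        if opt_adv is not None:
            # gradients arrive reversed through the GRL, so this descent step
            # ascends the task loss: the iterative adversarial-style update
            opt_adv.step()
    if vae is not None:
        set_requires_grad(vae, True)
    return trace


def evaluate(model: SegmentationModel, images: np.ndarray, masks: np.ndarray,
             class_map: ClassMap, batch_size: int = 16):
    """Plain-network inference + metrics report on a labeled dataset."""
    if len(images) == 0:
        raise ValueError("empty evaluation dataset")
    x = _to_nchw(np.asarray(images))
    masks = np.asarray(masks)
    set_requires_grad(model, False)
    try:
        total = ConfusionCounts(
            np.zeros((class_map.n_classes, class_map.n_classes), dtype=np.int64))
        for start in range(0, len(x), batch_size):
            scores, _ = model.forward(Tensor(x[start:start + batch_size]))
            pred = scores.data.argmax(axis=1)
            total = total + confusion_counts(pred, masks[start:start + batch_size],
                                             class_map.n_classes)
    finally:
        set_requires_grad(model, True)
    return compute_report(total, class_map)


def load_benchmark(dataset_dir) -> dict:
    """Load a generated two-domain dataset into the training data dict.

    Laboratory train split provides labeled content; the field validation
    split provides unlabeled style images; the field test split is held out
    for cross-domain evaluation.
    """
    import json
    from pathlib import Path

    from .data_io import load_manifest, read_sample

    dataset_dir = Path(dataset_dir)
    manifest = load_manifest(dataset_dir)
    with open(dataset_dir / "classes.json") as fh:
        cj = json.load(fh)
    class_map = ClassMap(names=cj["names"], roles=cj["roles"])

    def _split(domain, split):
        rows = manifest[(manifest["domain"] == domain)
                        & (manifest["split"] == split)]
        pairs = [read_sample(r, dataset_dir, class_map.n_classes)
                 for _, r in rows.iterrows()]
        if not pairs:
            return (np.empty((0,)),) * 2
        images = np.stack([p[0] for p in pairs])
        masks = np.stack([p[1] for p in pairs])
        return images, masks

    train_images, train_masks = _split("lab", "train")
    style_images, _ = _split("field", "val")
    test_images, test_masks = _split("field", "test")
    return {
        "train_images": train_images, "train_masks": train_masks,
        "style_images": style_images,
        "test_images": test_images, "test_masks": test_masks,
        "class_map": class_map,
    }


DEFAULT_VARIANTS = {
    "baseline": AblationConfig(),
    "adain": AblationConfig(use_adain_fixed=True),
    "rain": AblationConfig(use_rain=True),
    "dgb": AblationConfig(use_dgb=True),
    "full": AblationConfig(use_rain=True, use_dgb=True),
}


def train_variant(data: dict, cfg: TrainConfig, ablation: AblationConfig,
                  seed: int):
    """Two-phase training of one ablation variant; returns (model, report, traces).

    ``data`` keys: train_images, train_masks, style_images, test_images,
    test_masks, class_map.
    """
    ss = np.random.SeedSequence(seed)
    s_model, s_warm, s_vae, s_loop = ss.spawn(4)
    class_map: ClassMap = data["class_map"]
    model = SegmentationModel(class_map.n_classes,
                              np.random.default_rng(s_model), cfg.backbone_widths)
    if cfg.warmup_iterations > 0:
        warm_cfg = replace(cfg, n_iterations=cfg.warmup_iterations)
        train_segmentation_phase(model, None, None, data["train_images"],
                                 data["train_masks"], None, warm_cfg,
                                 AblationConfig(), np.random.default_rng(s_warm))
    vae = None
    rain_trace = None
    if ablation.use_rain:
        vae_rng = np.random.default_rng(s_vae)
        vae = StyleVAE(model.stage_channels(cfg.insertion_stage),
                       latent_dim=cfg.latent_dim, hidden_width=cfg.hidden_width,
                       rng=vae_rng)
        rain_trace = train_rain_phase(vae, data["train_images"],
                                      data["style_images"], cfg, model, vae_rng)
    adv = None
    if ablation.use_dgb:
        # start the adversarial distribution at the source style statistics
        warm = _to_nchw(data["train_images"][:32])
        set_requires_grad(model, False)
        f_warm = model.features(Tensor(warm),
                                upto=max(cfg.dgb_stage, cfg.insertion_stage))
        set_requires_grad(model, True)
        adv = AdversarialStats.from_features(f_warm, eps=cfg.eps)
    loop_rng = np.random.default_rng(s_loop)
    seg_trace = train_segmentation_phase(
        model, vae, adv, data["train_images"], data["train_masks"],
        data.get("style_images"), cfg, ablation, loop_rng)
    report = evaluate(model, data["test_images"], data["test_masks"], class_map)
    return model, report, {"rain": rain_trace, "seg": seg_trace}


def run_ablation(data: dict, base_cfg: TrainConfig, seeds,
                 variants: dict | None = None) -> pd.DataFrame:
    """Train each ablation variant over the given seeds on laboratory data and
    evaluate cross-domain on the field test split.

    Returns a tidy DataFrame with one row per (variant, seed); aggregate with
    :func:`summarize_ablation`. A crashing variant is recorded and skipped.
    """
    seeds = list(seeds)
    if len(seeds) < 2:
        raise ValueError("ablation needs at least 2 seeds")
    if variants is None:
        variants = DEFAULT_VARIANTS
    rows = []
    for name, ab in variants.items():
        for seed in seeds:
            try:
                _, report, _ = train_variant(data, base_cfg, ab, seed)
                rows.append({"variant": name, "seed": seed, "error": "",
                             "miou": report.miou,
                             "precision": report.precision,
                             "recall": report.recall, "f1": report.f1,
                             "weed_iou": report.weed_iou})
            except Exception as e:  # record and continue with other variants
                rows.append({"variant": name, "seed": seed, "error": str(e),
                             "miou": np.nan, "precision": np.nan,
                             "recall": np.nan, "f1": np.nan,
                             "weed_iou": np.nan})
    return pd.DataFrame(rows)


def summarize_ablation(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation of each metric per variant."""
    metrics = ["miou", "precision", "recall", "f1", "weed_iou"]
    g = results.groupby("variant")[metrics]
    summary = g.agg(["mean", "std"])
    summary.columns = [f"{m}_{s}" for m, s in summary.columns]
    return summary.reset_index()
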
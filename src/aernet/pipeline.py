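"""Desk-scale training and inference loop.

Binds the pieces together: synthetic or on-disk patch pairs, joint
augmentation (flips shared by image and targets, blur on the image only),
the two-stage Adam schedule (lr 1e-4 stepped to 1e-5 at each stage's
midpoint, encoder trained throughout), and patch inference ending in
watershed post-processing and majority-vote typing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from scipy import ndimage

from .hv import compute_hv_map
from .losses import branch_losses, softmax
from .model import AERNet, BranchOutputs, load_checkpoint, save_checkpoint
from .nn.autograd import Tensor
from .nn.optim import Adam
from .postprocess import assign_types, watershed_instances
from .synthetic import generate_scene
from .types import (
    LossWeights,
    ModelConfig,
    PostprocConfig,
    SceneSpec,
    TrainConfig,
    validate_class_map,
)

__all__ = [
    "augment",
    "build_targets",
    "synthetic_dataset",
    "train",
    "overfit_one_batch",
    "infer",
    "infer_arrays",
]


def augment(patch: np.ndarray, targets: dict, seed: int) -> tuple[np.ndarray, dict]:
    """Seeded joint augmentation: flips, Gaussian blur, median blur.

    Flips are applied to the image, the instance map, the class map and the
    HV map together; the HV channels are sign-flipped consistently
    (horizontal flip negates the horizontal channel, vertical flip the
    vertical one — exact for the symmetric per-side normalization).  Blur
    touches the image only.
    """
    rng = np.random.default_rng(seed)
    img = patch.copy()
    out = {k: v.copy() for k, v in targets.items()}
    if rng.random() < 0.5:  # horizontal flip
        img = img[:, ::-1]
        for key in ("instances", "classes"):
            if key in out:
                out[key] = out[key][:, ::-1]
        if "hv" in out:
            out["hv"] = out["hv"][:, ::-1]
            out["hv"][:, :, 0] *= -1.0
    if rng.random() < 0.5:  # vertical flip
        img = img[::-1]
        for key in ("instances", "classes"):
            if key in out:
                out[key] = out[key][::-1]
        if "hv" in out:
            out["hv"] = out["hv"][::-1]
            out["hv"][:, :, 1] *= -1.0
    draw = rng.random()
    if draw < 0.25:
        img = np.clip(
            ndimage.gaussian_filter(img.astype(np.float64), sigma=(1.0, 1.0, 0)),
            0,
            255,
        ).astype(np.uint8)
    elif draw < 0.5:
        img = ndimage.median_filter(img, size=(3, 3, 1))
    return img, {k: np.ascontiguousarray(v) for k, v in out.items()}


def build_targets(
    instances: np.ndarray,
    classes: np.ndarray,
    num_classes: int,
    hv: np.ndarray | None = None,
    crop: tuple[int, int] | None = None,
) -> dict:
    """Per-patch training targets in NCHW-friendly layout (no batch axis).

    Returns ``fg_onehot`` (2,H,W), ``hv`` (2,H,W), ``class_onehot``
    (K+1,H,W) and ``mask`` (H,W).  ``crop`` centre-crops all targets to the
    model's output geometry.
    """
    validate_class_map(classes, instances)
    if hv is None:
        hv = compute_hv_map(instances)
    if crop is not None:
        ch, cw = crop
        top = (instances.shape[0] - ch) // 2
        left = (instances.shape[1] - cw) // 2
        sl = (slice(top, top + ch), slice(left, left + cw))
        instances, classes, hv = instances[sl], classes[sl], hv[sl]
    mask = (instances > 0).astype(np.float64)
    fg_onehot = np.stack([1.0 - mask, mask])
    class_onehot = np.stack(
        [(classes == c).astype(np.float64) for c in range(num_classes + 1)]
    )
    return {
        "fg_onehot": fg_onehot,
        "hv": hv.transpose(2, 0, 1),
        "class_onehot": class_onehot,
        "mask": mask,
    }


def synthetic_dataset(
    spec: SceneSpec, n_images: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """n seeded scenes; per-scene seeds derive from (seed, index)."""
    triples = []
    for i in range(n_images):
        spec_i = SceneSpec(
            height=spec.height,
            width=spec.width,
            n_nuclei=spec.n_nuclei,
            radius_range=spec.radius_range,
            class_probabilities=spec.class_probabilities,
            allow_touching=spec.allow_touching,
            seed=int((seed * 100_003 + i) % (2**31 - 1)),
        )
        triples.append(generate_scene(spec_i))
    return triples


def _image_to_input(img: np.ndarray) -> np.ndarray:
    return (img.astype(np.float32) / np.float32(255.0)).transpose(2, 0, 1)


def _stack_targets(per_patch: list[dict]) -> dict:
    return {
        k: np.stack([t[k] for t in per_patch]).astype(np.float32)
        for k in per_patch[0]
    }


def _learning_rate(cfg: TrainConfig, epoch_in_stage: int) -> float:
    return cfg.lr_initial if epoch_in_stage < cfg.lr_step_epoch else cfg.lr_final


def train(
    model: AERNet,
    data: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    train_cfg: TrainConfig | None = None,
    loss_weights: LossWeights | None = None,
    checkpoint_path=None,
    log_path=None,
    use_augmentation: bool = True,
) -> list[dict]:
    """Two-stage Adam training on (image, instance map, class map) triples.

    Returns the per-epoch history of mean loss terms; optionally writes a
    JSON-lines log and a checkpoint.  The encoder is trained from step one
    (never frozen).  The global seed in ``train_cfg`` drives data order and
    augmentation draws.
    """
    train_cfg = train_cfg or TrainConfig()
    loss_weights = loss_weights or LossWeights()
    k = model.config.num_classes
    out_hw = model._output_geometry(data[0][0].shape[0], data[0][0].shape[1])

    # fail fast on malformed pairs before any gradient step
    for img, inst, cls in data:
        if img.shape[:2] != inst.shape or inst.shape != cls.shape:
            raise ValueError("image/instance/class shapes disagree")
        validate_class_map(cls, inst)
        if cls.max(initial=0) > k:
            raise ValueError("class label exceeds configured num_classes")

    rng = np.random.default_rng(train_cfg.seed)
    optimizer = Adam(model.parameters(), lr=train_cfg.lr_initial)
    history: list[dict] = []
    log_file = open(log_path, "w") if log_path else None
    model.train()
    try:
        total_epochs = train_cfg.n_stages * train_cfg.epochs_per_stage
        for epoch in range(total_epochs):
            optimizer.lr = _learning_rate(
                train_cfg, epoch % train_cfg.epochs_per_stage
            )
            order = rng.permutation(len(data))
            term_sums: dict[str, float] = {}
            n_batches = 0
            for start in range(0, len(order), train_cfg.batch_size):
                idx = order[start : start + train_cfg.batch_size]
                xs, ts = [], []
                for i in idx:
                    img, inst, cls = data[i]
                    if use_augmentation:
                        img, t = augment(
                            img,
                            {"instances": inst, "classes": cls},
                            seed=int(rng.integers(2**31 - 1)),
                        )
                        inst, cls = t["instances"], t["classes"]
                    xs.append(_image_to_input(img))
                    ts.append(
                        build_targets(inst, cls, k, crop=out_hw)
                        if out_hw != img.shape[:2]
                        else build_targets(inst, cls, k)
                    )
                x = Tensor(np.stack(xs))
                targets = _stack_targets(ts)
                outputs = model(x)
                total, terms = branch_losses(outputs, targets, loss_weights)
                optimizer.zero_grad()
                total.backward()
                optimizer.step()
                n_batches += 1
                for name, value in terms.items():
                    v = value.item() if hasattr(value, "item") else float(value)
                    term_sums[name] = term_sums.get(name, 0.0) + v
                term_sums["total"] = term_sums.get("total", 0.0) + total.item()
            record = {
                "epoch": epoch,
                "lr": optimizer.lr,
                **{name: v / n_batches for name, v in term_sums.items()},
            }
            history.append(record)
            if log_file:
                log_file.write(json.dumps(record) + "\n")
                log_file.flush()
    finally:
        if log_file:
            log_file.close()
    if checkpoint_path:
        save_checkpoint(model, checkpoint_path)
    return history


def overfit_one_batch(
    model_seed: int,
    data_seed: int = 123,
    steps: int = 200,
    batch_size: int = 2,
    lr: float = 2e-3,
    n_patches: int = 4,
) -> tuple[float, float]:
    """Gradient-flow diagnostic: drive a width-reduced model into a tiny
    fixed patch set and report (initial, final) total loss.

    A healthy architecture overfits: the total loss should fall well below
    its starting value within a couple hundred Adam steps, which exercises
    gradients through the attention gates and the refinement residuals.
    """
    from .presets import toy_loss_weights, toy_model_config, toy_scene_spec

    model = AERNet(toy_model_config(seed=model_seed))
    data = synthetic_dataset(toy_scene_spec(), n_patches, seed=data_seed)
    xs = [_image_to_input(d[0]) for d in data]
    ts = [build_targets(d[1], d[2], model.config.num_classes) for d in data]
    optimizer = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(model_seed)
    initial = final = None
    model.train()
    for _ in range(steps):
        idx = rng.permutation(n_patches)[:batch_size]
        x = Tensor(np.stack([xs[i] for i in idx]))
        targets = _stack_targets([ts[i] for i in idx])
        total, _ = branch_losses(model(x), targets, toy_loss_weights())
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
        if initial is None:
            initial = total.item()
        final = total.item()
    return initial, final


def _predicted_maps(model: AERNet, img: np.ndarray):
    """Refined softmax probability, HV and class maps for one image."""
    x = Tensor(_image_to_input(img)[None])
    outputs: BranchOutputs = model(x)
    prob = softmax(outputs.prob_refined, axis=1).data[0, 1]
    hv = outputs.hv_refined.data[0].transpose(1, 2, 0)
    class_probs = softmax(outputs.class_refined, axis=1).data[0].transpose(1, 2, 0)
    return prob, hv, class_probs


def infer_arrays(
    model: AERNet,
    images: list[np.ndarray],
    postproc: PostprocConfig | None = None,
) -> list[tuple[np.ndarray, np.ndarray, dict[int, int]]]:
    """Forward + watershed + typing for in-memory images (eval mode)."""
    postproc = postproc or PostprocConfig()
    model.eval()
    results = []
    for img in images:
        prob, hv, class_probs = _predicted_maps(model, img)
        instances = watershed_instances(prob, hv, postproc)
        types, class_map = assign_types(instances, class_probs)
        results.append((instances, class_map, types))
    return results


def infer(
    checkpoint_path,
    image_dir,
    out_dir,
    postproc: PostprocConfig | None = None,
) -> list[dict]:
    """Run a checkpoint over a directory of images.

    Writes per-image 16-bit instance and class PNGs plus a JSON table of
    instance types; size-incompatible files are reported and skipped.
    """
    from .io import read_image, write_label_map

    model = load_checkpoint(checkpoint_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = []
    paths = sorted(
        p
        for p in Path(image_dir).iterdir()
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    for path in paths:
        entry = {"image": path.name}
        try:
            img = read_image(path)
            (instances, class_map, types), = infer_arrays(
                model, [img], postproc
            )
        except ValueError as exc:
            entry["error"] = str(exc)
            report.append(entry)
            continue
        write_label_map(instances, out_dir / f"{path.stem}_inst.png")
        write_label_map(class_map, out_dir / f"{path.stem}_class.png")
        entry["n_instances"] = int(instances.max(initial=0))
        entry["types"] = {str(k): v for k, v in types.items()}
        report.append(entry)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report
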
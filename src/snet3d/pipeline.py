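"""Patch-based training and stitched whole-volume inference.

Volumes are z-scored per case, randomly cropped into patches (offsets drawn
along the first axis; in-plane offsets are random only when the patch is
smaller than the volume in-plane), and fed to the network in batches.
Inference tiles the volume into patch-sized windows with 50% overlap along
every axis that exceeds the patch, averages the overlapping probabilities
with uniform weights (so every voxel is a convex combination of window
predictions) and thresholds at 0.5.

Everything is driven by a single seed: per-epoch seeds are derived from it
with ``SeedSequence``, so an interrupted run resumed from a checkpoint
replays the identical patch and dropout streams.
"""

from __future__ import annotations

import dataclasses
import time
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .losses import LossConfig, deep_supervision_loss
from .metrics import METRIC_COLUMNS, aggregate, evaluate_case
from .model import (NetworkConfig, SNet, build_network, load_checkpoint,
                    make_variant, save_checkpoint)
from .nn.autograd import Tensor
from .phantoms import load_nifti

__all__ = [
    "TrainConfig", "TrainingDiverged", "normalize_volume", "extract_patches",
    "split_manifest", "train", "predict_volume", "run_ablation",
    "evaluate_split",
]


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 60
    batch_size: int = 2
    learning_rate: float = 1e-4
    lr_schedule: str = "constant"  # or "cosine" (decays to lr/100 by the last epoch)
    optimizer: str = "adam"
    patch_shape: tuple[int, int, int] = (32, 32, 32)
    patches_per_volume: int = 1
    seed: int = 0
    checkpoint_every: int = 0  # 0: only best/last
    loss: LossConfig = LossConfig()

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["patch_shape"] = list(self.patch_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "patch_shape" in d:
            d["patch_shape"] = tuple(d["patch_shape"])
        if isinstance(d.get("loss"), dict):
            d["loss"] = LossConfig(**d["loss"])
        return cls(**d)


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Per-volume z-score (the network never sees raw intensities)."""
    v = np.asarray(volume, dtype=np.float32)
    sd = float(v.std())
    return (v - float(v.mean())) / (sd if sd > 0 else 1.0)


def _pad_to(volume: np.ndarray, shape, value=0.0) -> np.ndarray:
    pads = [(0, max(0, s - n)) for n, s in zip(volume.shape, shape)]
    if any(p[1] for p in pads):
        volume = np.pad(volume, pads, constant_values=value)
    return volume


def extract_patches(volume: np.ndarray, mask: np.ndarray, patch_shape,
                    n: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """``n`` seeded random crops of (volume, mask).

    Offsets are uniform along each axis where the volume exceeds the patch;
    smaller volumes are padded with background (warned).
    """
    patch_shape = tuple(int(s) for s in patch_shape)
    if any(s < 1 for s in patch_shape):
        raise ValueError(f"degenerate patch shape {patch_shape}")
    if any(v < p for v, p in zip(volume.shape, patch_shape)):
        warnings.warn(f"volume {volume.shape} smaller than patch {patch_shape}; "
                      "padding with background", stacklevel=2)
        volume = _pad_to(volume, patch_shape)
        mask = _pad_to(mask, patch_shape)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        off = [int(rng.integers(0, v - p + 1))
               for v, p in zip(volume.shape, patch_shape)]
        sl = tuple(slice(o, o + p) for o, p in zip(off, patch_shape))
        out.append((volume[sl], mask[sl]))
    return out


def split_manifest(manifest: dict, train_frac: float = 0.75,
                   seed: int = 0) -> dict:
    """Disjoint train/test case split (by case, seeded shuffle)."""
    names = [c["case"] for c in manifest["cases"]]
    order = np.random.default_rng(seed).permutation(len(names))
    n_train = max(1, int(round(train_frac * len(names))))
    if len(names) >= 2:
        n_train = min(n_train, len(names) - 1)
    train = sorted(names[i] for i in order[:n_train])
    test = sorted(names[i] for i in order[n_train:])
    return {"seed": int(seed), "train": train, "test": test}


def _load_cases(manifest: dict, subset: list[str] | None = None):
    root = Path(manifest["root"])
    wanted = set(subset) if subset is not None else None
    cases = []
    for case in manifest["cases"]:
        if wanted is not None and case["case"] not in wanted:
            continue
        vol, spacing = load_nifti(root / case["image"])
        msk, _ = load_nifti(root / case["mask"])
        cases.append((case["case"], normalize_volume(vol),
                      np.asarray(msk, dtype=np.uint8), spacing))
    if wanted is not None and len(cases) != len(wanted):
        missing = wanted - {c[0] for c in cases}
        raise FileNotFoundError(f"cases missing from manifest: {sorted(missing)}")
    return cases


def _epoch_seed(master: int, epoch: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master, epoch, stream]))


def train(net_cfg: NetworkConfig, train_cfg: TrainConfig, manifest: dict,
          out_dir, subset: list[str] | None = None,
          resume_from=None) -> tuple[Path, pd.DataFrame]:
    """Train on the manifest's cases; returns (best checkpoint path, log).

    Writes ``last``/``best`` checkpoints plus ``training_log.csv`` with the
    per-epoch mean loss. Dropout is active only here. A non-finite loss
    aborts with input statistics in the message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = _load_cases(manifest, subset)
    if not cases:
        raise ValueError("no training cases")
    if resume_from is not None:
        net, opt_state, extra = load_checkpoint(resume_from)
        start_epoch = int(extra["epoch"]) + 1
        optimizer = nn.Adam(net.parameters(), lr=train_cfg.learning_rate)
        if opt_state:
            optimizer.load_state_dict(opt_state)
        log_rows = extra.get("log", [])
    else:
        net = build_network(net_cfg, seed=train_cfg.seed)
        optimizer = nn.Adam(net.parameters(), lr=train_cfg.learning_rate)
        start_epoch, log_rows = 0, []
    best = min((r["mean_loss"] for r in log_rows), default=np.inf)
    n_heads = 1 if net.config.supervision == "single" else net.config.depth
    t0 = time.time()
    for epoch in range(start_epoch, train_cfg.epochs):
        if train_cfg.lr_schedule == "cosine" and train_cfg.epochs > 1:
            frac = epoch / (train_cfg.epochs - 1)
            optimizer.lr = train_cfg.learning_rate * (
                0.01 + 0.99 * 0.5 * (1 + np.cos(np.pi * frac)))
        patch_rng = _epoch_seed(train_cfg.seed, epoch, 0)
        drop_rng = _epoch_seed(train_cfg.seed, epoch, 1)
        pool = []
        for name, vol, msk, _ in cases:
            pool.extend(extract_patches(
                vol, msk, train_cfg.patch_shape, train_cfg.patches_per_volume,
                int(patch_rng.integers(2 ** 31))))
        order = patch_rng.permutation(len(pool))
        losses = []
        for lo in range(0, len(pool), train_cfg.batch_size):
            batch = [pool[i] for i in order[lo:lo + train_cfg.batch_size]]
            x = Tensor(np.stack([v for v, _ in batch])[..., None])
            g = np.stack([m for _, m in batch])[..., None].astype(np.float32)
            preds = net.forward(x, training=True, rng=drop_rng)
            loss = deep_supervision_loss(preds, g, train_cfg.loss)
            if not np.isfinite(loss.item()):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: lr={train_cfg.learning_rate}, "
                    f"input mean={x.data.mean():.3g} sd={x.data.std():.3g}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(loss.item() / n_heads)
        mean_loss = float(np.mean(losses)) if losses else np.nan
        log_rows.append({"epoch": epoch, "mean_loss": mean_loss,
                         "seconds": round(time.time() - t0, 2)})
        extra = {"epoch": epoch, "train_config": train_cfg.to_dict(),
                 "log": log_rows}
        save_checkpoint(out_dir / "last", net, optimizer=optimizer, extra=extra)
        if mean_loss < best:
            best = mean_loss
            save_checkpoint(out_dir / "best", net, optimizer=optimizer, extra=extra)
        if train_cfg.checkpoint_every and (epoch + 1) % train_cfg.checkpoint_every == 0:
            save_checkpoint(out_dir / f"epoch_{epoch:04d}", net,
                            optimizer=optimizer, extra=extra)
    if not (out_dir / "best.npz").exists():  # epochs == 0
        save_checkpoint(out_dir / "best", net, optimizer=optimizer,
                        extra={"epoch": -1, "train_config": train_cfg.to_dict(),
                               "log": log_rows})
    log = pd.DataFrame(log_rows)
    log.to_csv(out_dir / "training_log.csv", index=False)
    return out_dir / "best", log


def _axis_starts(size: int, patch: int, overlap: float) -> list[int]:
    if size <= patch:
        return [0]
    step = max(1, int(round(patch * (1.0 - overlap))))
    starts = list(range(0, size - patch + 1, step))
    if starts[-1] != size - patch:
        starts.append(size - patch)
    return starts


def predict_volume(net: SNet, volume: np.ndarray,
                   patch_shape=(32, 32, 32), overlap: float = 0.5,
                   normalized: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Stitched whole-volume inference.

    Returns ``(probability volume, binary mask)``. Windows of
    ``patch_shape`` tile each axis with the given overlap; overlapping
    probabilities are averaged with uniform weights. Volumes smaller than
    the patch are padded, predicted, and cropped back.
    """
    vol = volume if normalized else normalize_volume(volume)
    orig_shape = vol.shape
    patch_shape = tuple(int(s) for s in patch_shape)
    vol = _pad_to(vol, patch_shape)
    prob = np.zeros(vol.shape, dtype=np.float64)
    weight = np.zeros(vol.shape, dtype=np.float64)
    starts = [_axis_starts(v, p, overlap) for v, p in zip(vol.shape, patch_shape)]
    for i in starts[0]:
        for j in starts[1]:
            for k in starts[2]:
                sl = tuple(slice(o, o + p) for o, p in zip((i, j, k), patch_shape))
                prob[sl] += net.predict(vol[sl])
                weight[sl] += 1.0
    prob /= weight
    prob = prob[tuple(slice(0, n) for n in orig_shape)]
    mask = (prob >= net.config.binarize_threshold).astype(np.uint8)
    return prob.astype(np.float32), mask


def evaluate_split(net: SNet, manifest: dict, subset: list[str],
                   patch_shape=(32, 32, 32)) -> pd.DataFrame:
    """Per-case metrics (plus aggregate rows) on a list of held-out cases."""
    rows = []
    for name, vol, msk, spacing in _load_cases(manifest, subset):
        _, pred = predict_volume(net, vol, patch_shape, normalized=True)
        rec = evaluate_case(pred, msk, spacing)
        rows.append({"case": name, **rec.as_dict()})
    table = pd.DataFrame(rows)
    return pd.concat([table, aggregate(table)], ignore_index=True)


def run_ablation(manifest: dict, split: dict, base_cfg: NetworkConfig,
                 train_cfg: TrainConfig, out_dir,
                 variants=("BN+SL", "BN+ML", "SNet+SL", "SNet+ML"),
                 seeds=(0,)) -> pd.DataFrame:
    """Train and evaluate every variant identically; returns a table of
    mean and 95% CI per metric (rows: variant x seed plus per-variant
    pooled means). A failing variant is recorded and the others continue.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    out_dir = Path(out_dir)
    rows = []
    for variant in variants:
        cfg = make_variant(base_cfg, variant)
        for seed in seeds:
            tc = dataclasses.replace(train_cfg, seed=int(seed))
            run_dir = out_dir / f"{variant.replace('+', '_')}_s{seed}"
            try:
                ckpt, _ = train(cfg, tc, manifest, run_dir, subset=split["train"])
                net, _, _ = load_checkpoint(ckpt)
                table = evaluate_split(net, manifest, split["test"],
                                       tc.patch_shape)
                mean_row = table[table["case"] == "mean"].iloc[0]
                ci_row = table[table["case"] == "ci95_halfwidth"].iloc[0]
                row = {"variant": variant, "seed": seed, "error": ""}
                for m in METRIC_COLUMNS:
                    row[m] = float(mean_row[m])
                    row[f"{m}_ci95"] = float(ci_row[m])
                rows.append(row)
            except Exception as exc:  # record and continue with other variants
                rows.append({"variant": variant, "seed": seed,
                             "error": f"{type(exc).__name__}: {exc}"})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ablation.csv", index=False)
    return table
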
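"""Named experiment profiles and the two phantom benchmarks.

``PUBLISHED`` mirrors the training regimen the architecture was described
with (48x512x512 patches, batch 2, Adam at 1e-4, 1000 epochs, dropout 0.3,
full-resolution resampling branch). That regimen assumes data-center GPUs;
the ``DESK`` profile is the package's CPU-scale counterpart used by the
test-suite benchmarks: base width 8, 32^3 patches, 60 epochs, a
quarter-resolution resampling branch, and a cosine-decayed Adam step sized
for the short schedule (2e-3). Both are plain configs — nothing in the
library depends on which one you pass.

Two benchmarks exercise the whole pipeline end to end on seeded phantoms:

* :func:`shell_benchmark` — 20 ellipsoidal shells of wall thickness 2
  voxels at 64^3, 75/25 split, full S-Net; reports held-out Dice and HD95.
* :func:`tube_ablation_benchmark` — branching tube trees whose radii decay
  to about one voxel; trains the full model and the single-branch,
  single-supervision backbone identically and reports both Dice means,
  the architecture's headline comparison.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from .model import NetworkConfig, load_checkpoint
from .phantoms import load_manifest, make_dataset
from .pipeline import (TrainConfig, evaluate_split, run_ablation,
                       split_manifest, train)

__all__ = ["DESK_NET", "DESK_TRAIN", "PUBLISHED_NET", "PUBLISHED_TRAIN",
           "shell_benchmark", "tube_ablation_benchmark"]

PUBLISHED_NET = NetworkConfig(base_width=16, resample_scale=1.0)
PUBLISHED_TRAIN = TrainConfig(epochs=1000, batch_size=2, learning_rate=1e-4,
                              patch_shape=(48, 512, 512))

DESK_NET = NetworkConfig(base_width=8, resample_scale=0.25)
DESK_TRAIN = TrainConfig(epochs=60, batch_size=2, learning_rate=2e-3,
                         lr_schedule="cosine", patch_shape=(32, 32, 32),
                         patches_per_volume=1)

#: study conditions for the shell benchmark: thin wall, fixed thickness
SHELL_RANGES = {"wall_thickness": (2.0, 2.0)}


def shell_benchmark(seed: int, work_dir, n_cases: int = 20,
                    epochs: int | None = None) -> pd.DataFrame:
    """Generate, split, train and evaluate the shell phantom benchmark.

    Returns the held-out metrics table (per-case rows plus ``mean`` and
    ``ci95_halfwidth`` rows)."""
    work_dir = Path(work_dir)
    data_dir = work_dir / "data"
    make_dataset(n_cases, "shell", SHELL_RANGES, (64, 64, 64), seed, data_dir)
    manifest = load_manifest(data_dir)
    split = split_manifest(manifest, 0.75, seed)
    tc = dataclasses.replace(DESK_TRAIN, seed=seed,
                             epochs=epochs or DESK_TRAIN.epochs)
    ckpt, _ = train(DESK_NET, tc, manifest, work_dir / "run",
                    subset=split["train"])
    net, _, _ = load_checkpoint(ckpt)
    return evaluate_split(net, manifest, split["test"], tc.patch_shape)


def tube_ablation_benchmark(seeds, work_dir, n_cases: int = 10,
                            epochs: int = 30,
                            variants=("BN+SL", "SNet+ML")) -> pd.DataFrame:
    """Train selected ablation variants on tube-tree phantoms.

    Returns the ablation table (one row per variant x seed with the six
    held-out metric means)."""
    work_dir = Path(work_dir)
    data_dir = work_dir / "data"
    master = int(seeds[0])
    make_dataset(n_cases, "tube", None, (64, 64, 64), master, data_dir)
    manifest = load_manifest(data_dir)
    split = split_manifest(manifest, 0.75, master)
    tc = dataclasses.replace(DESK_TRAIN, epochs=epochs)
    return run_ablation(manifest, split, DESK_NET, tc, work_dir / "runs",
                        variants=variants, seeds=tuple(int(s) for s in seeds))
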
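"""Canned study harnesses: simulator phenomenology and the context-
identifiability experiment.

These functions are the reproducible entry points behind the package's
quantitative claims; the test suite and ``scripts/acceptance.py`` both
call them rather than re-scripting the protocols.

The context-identifiability experiment is the mechanism check for
context conditioning: one PA OmniNet is trained *jointly* on two
synthetic degradation tasks (a 16-element ring and a 32-element
multisegment acquisition, both against 128-element ground truth) and
then evaluated on each task's test split under three context sets —

``matched``     the task's own inference context (the first 16 training
                pairs, i.e. consecutive acquisitions of the first
                training subject),
``other_group`` the same task but a different training subject (the
                first 16 pairs of the second training group),
``mismatched``  the *other* task's inference context.

If the network actually reads the context, matched conditioning must
beat mismatched conditioning, and a same-task/different-subject context
must cost less than a mismatched-task one.  The experiment runs at
desk scale (32 x 32 images, reduced channel widths, a few minutes per
seed on one CPU core).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DatasetBundle, TaskSpec, build_dataset
from .geometry import make_geometry, subsample_elements
from .metrics import ssim
from .omninet import ModelConfig, OmniNet
from .phantom import random_scene, PhantomScene, Disk
from .acoustics import forward_project, das_reconstruct, render_ground_truth
from .report import paired_ttest, TTestResult
from .train import (OmniNetAdapter, TrainConfig, Trainer, group_context,
                    infer, sliding_context, static_context)

__all__ = [
    "simulator_quality_curve", "streak_periodicity",
    "ContextIdentifiabilityResult", "context_identifiability_experiment",
    "merge_bundles",
]


def simulator_quality_curve(
    seed: int = 0,
    n_scenes: int = 20,
    levels: tuple[int, ...] = (16, 32, 64, 128),
    n_dense: int = 256,
    grid_size: tuple[int, int] = (48, 48),
) -> pd.DataFrame:
    """Mean SSIM of sparse ring reconstructions vs dense ground truth.

    One row per sparsity level, averaged over ``n_scenes`` seeded random
    scenes; SSIM should be non-decreasing in the element count, the
    basic phenomenology of sparse-sampling artifacts.
    """
    rng = np.random.default_rng(seed)
    scene_seeds = rng.integers(0, 2**31 - 1, size=n_scenes)
    dense = make_geometry("ring", n_dense)
    rows = []
    for level in levels:
        sparse = subsample_elements(dense, level)
        vals = []
        for s in scene_seeds:
            scene = random_scene(int(s), grid_size)
            gt = render_ground_truth(scene, dense, grid_size)
            rec = das_reconstruct(forward_project(scene, sparse), sparse, grid_size)
            vals.append(ssim(rec, gt))
        rows.append({"n_elements": level, "mean_ssim": float(np.mean(vals)),
                     "n_scenes": n_scenes})
    return pd.DataFrame(rows)


def streak_periodicity(n_elements: int = 16, grid_size: tuple[int, int] = (64, 64),
                       radius_frac: float = 0.55) -> int:
    """Dominant angular harmonic of a sparse-ring point reconstruction.

    Reconstructing a centered point source with an N-element ring
    produces N radial streaks; the angular intensity profile at a fixed
    radius then has its strongest nonzero Fourier harmonic at a multiple
    of N.  Returns that dominant harmonic.
    """
    h, w = grid_size
    scene = PhantomScene(absorbers=(Disk(center=(0.0, 0.0), radius=0.03, amplitude=1.0),),
                         grid_size=grid_size)
    geo = make_geometry("ring", n_elements)
    img = das_reconstruct(forward_project(scene, geo), geo, grid_size)
    theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    r = radius_frac  # in fov units, inside the grid, away from the source
    xs = np.clip(((r * np.cos(theta) + 1) * w / 2 - 0.5).round().astype(int), 0, w - 1)
    ys = np.clip(((1 - r * np.sin(theta)) * h / 2 - 0.5).round().astype(int), 0, h - 1)
    profile = img[ys, xs]
    spec = np.abs(np.fft.rfft(profile - profile.mean()))
    return int(np.argmax(spec[1:]) + 1)


def merge_bundles(a: DatasetBundle, b: DatasetBundle, group_offset: int = 1000) -> DatasetBundle:
    """Concatenate two bundles, offsetting the second bundle's group ids."""
    from .dataset import ImagePair

    def shift(p: ImagePair) -> ImagePair:
        return ImagePair(sparse_input=p.sparse_input, ground_truth=p.ground_truth,
                         group_id=p.group_id + group_offset, geometry=p.geometry,
                         n_sparse=p.n_sparse, n_dense=p.n_dense, seed=p.seed)

    pairs = list(a.pairs) + [shift(p) for p in b.pairs]
    split_of_group = dict(a.split_of_group)
    split_of_group.update({g + group_offset: s for g, s in b.split_of_group.items()})
    return DatasetBundle(pairs=pairs, split_of_group=split_of_group,
                         config={"merged": [a.config, b.config]})


@dataclass
class ContextIdentifiabilityResult:
    per_image: pd.DataFrame = field(repr=False)  # seed, task, image, context, ssim
    mean_matched: float = 0.0
    mean_mismatched: float = 0.0
    mean_other_group: float = 0.0
    ttest: TTestResult | None = None            # matched vs mismatched, two-sided
    p_one_sided: float = 1.0                    # H1: matched > mismatched

    @property
    def matched_minus_mismatched(self) -> float:
        return self.mean_matched - self.mean_mismatched

    @property
    def drop_other_group(self) -> float:
        return self.mean_matched - self.mean_other_group

    @property
    def drop_mismatched(self) -> float:
        return self.mean_matched - self.mean_mismatched

    def summary(self) -> str:
        lines = [
            "Context-identifiability experiment",
            "=" * 42,
            f"mean test SSIM, matched context      {self.mean_matched:.4f}",
            f"mean test SSIM, other-group context  {self.mean_other_group:.4f}",
            f"mean test SSIM, mismatched context   {self.mean_mismatched:.4f}",
            f"paired t (matched vs mismatched)     t = {self.ttest.t:.3f}, "
            f"one-sided p = {self.p_one_sided:.2e}, n = {self.ttest.n}",
        ]
        return "\n".join(lines)


# study conditions for the desk-scale mechanism experiment
_TASK_A = TaskSpec(geometry="ring", n_sparse=16, n_dense=128, grid_size=(32, 32))
_TASK_B = TaskSpec(geometry="multisegment", n_sparse=32, n_dense=128, grid_size=(32, 32))


def _task_context_fn(window: int):
    """Sliding-window contexts restricted to the target's own task
    (tasks are distinguished by the pairs' geometry tag)."""

    def fn(pairs, index):
        geo = pairs[index].geometry
        seg_idx = [i for i, p in enumerate(pairs) if p.geometry == geo]
        seg = [pairs[i] for i in seg_idx]
        return sliding_context(seg, seg_idx.index(index), window)

    return fn


def context_identifiability_experiment(
    seed: int = 0,
    n_seeds: int = 3,
    n_items: int = 100,
    n_groups: int = 6,
    max_epochs: int = 15,
    base_channels: int = 8,
    context_size_test: int = 16,
    verbose: bool = False,
) -> ContextIdentifiabilityResult:
    """Run the two-task mechanism experiment (see module docstring)."""
    records = []
    for s in range(n_seeds):
        run_seed = (seed * 1000 + s) % (2**31)
        bundle_a = build_dataset(n_items, n_groups, _TASK_A, (0.5, 0.2, 0.3),
                                 seed=run_seed)
        bundle_b = build_dataset(n_items, n_groups, _TASK_B, (0.5, 0.2, 0.3),
                                 seed=run_seed + 1)
        joint = merge_bundles(bundle_a, bundle_b)

        model = OmniNet(ModelConfig(base_channels=base_channels,
                                    channel_multipliers=(1, 2, 2, 2),
                                    seed=run_seed))
        # MSE for the desk-scale runs: it converges in far fewer epochs than
        # the SSIM-bearing losses, and the experiment probes context
        # conditioning, not the loss choice
        cfg = TrainConfig(loss="mse", learning_rate=1e-3,
                          max_epochs=max_epochs, early_stop_patience=max_epochs,
                          batch_size=4, context_size_train=4, seed=run_seed)
        trainer = Trainer(OmniNetAdapter(model), joint, cfg,
                          context_fn=_task_context_fn(cfg.context_size_train))
        result = trainer.fit(verbose=verbose)

        def second_train_subject(bundle):
            order = list(dict.fromkeys(p.group_id for p in bundle.train))
            return group_context(bundle, order[1], context_size_test)

        contexts = {
            "A": {
                "matched": static_context(bundle_a.train, context_size_test),
                "other_group": second_train_subject(bundle_a),
                "mismatched": static_context(bundle_b.train, context_size_test),
            },
            "B": {
                "matched": static_context(bundle_b.train, context_size_test),
                "other_group": second_train_subject(bundle_b),
                "mismatched": static_context(bundle_a.train, context_size_test),
            },
        }
        for task, bundle in (("A", bundle_a), ("B", bundle_b)):
            test = bundle.test
            for ctx_name, ctx in contexts[task].items():
                preds = infer(result.adapter, [p.sparse_input for p in test], ctx)
                for j, (pred, p) in enumerate(zip(preds, test)):
                    records.append({"seed": s, "task": task, "image": j,
                                    "context": ctx_name,
                                    "ssim": ssim(pred, p.ground_truth)})

    df = pd.DataFrame(records)
    wide = df.pivot_table(index=["seed", "task", "image"], columns="context",
                          values="ssim")
    tt = paired_ttest(wide["matched"].to_numpy(), wide["mismatched"].to_numpy())
    p_one = tt.p / 2 if tt.t > 0 else 1 - tt.p / 2
    return ContextIdentifiabilityResult(
        per_image=df,
        mean_matched=float(wide["matched"].mean()),
        mean_mismatched=float(wide["mismatched"].mean()),
        mean_other_group=float(wide["other_group"].mean()),
        ttest=tt,
        p_one_sided=float(p_one),
    )
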
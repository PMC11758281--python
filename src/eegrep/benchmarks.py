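"""Reference simulation studies: null calibration and effect recovery.

These are the package's own validation experiments, run at desk scale:

* **Null calibration** — with every planted effect set to zero, epochs are
  exchangeable across stimulus kind, condition and attention, so every
  task x pipeline balanced accuracy must be statistically indistinguishable
  from chance.  Each repeat draws a fresh experiment, so the per-cell
  estimates are independent; the chance bands are normal approximations to
  the binomial at the actual test-set class counts, Bonferroni-adjusted for
  the number of simultaneous cells checked.

* **Planted-P300 recovery** — a Target-locked P3 amplitude boost must be
  recovered by the stimulus task (Target vs Distractor among score-0
  epochs) well above chance, while the Distractor score task, whose epochs
  carry no label-linked signal under this configuration, must stay at
  chance (negative control).

* **Boost monotonicity** — stimulus-task accuracy must be non-decreasing in
  the size of the planted P3 boost.

Problem sizes are deliberately small (a few participants, 12-16 channels):
the effects of interest are planted per-epoch, so recovering them does not
require the full 42-participant, 64-channel geometry.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import SplitSpec, TaskSpec, results_frame, run_task
from .scoring import apply_scores
from .synthetic_data import GeneratorConfig, generate_experiment

__all__ = [
    "null_config",
    "planted_config",
    "run_cells",
    "null_calibration",
    "chance_band",
    "planted_p300_study",
    "boost_monotonicity",
    "NULL_TASKS",
    "NULL_PIPELINES",
]

#: Task grid for the null calibration: one stratum per task family.
NULL_TASKS = (
    ("score", "Target"),
    ("score", "Distractor"),
    ("stimulus", "C1"),
    ("condition", "Target"),
)

#: Pipeline subset for the calibration grid (one per representation family).
NULL_PIPELINES = ("uts", "uts-tdf", "gfp", "fbn")


def null_config(seed: int) -> GeneratorConfig:
    """Scaled-down study with every planted effect removed.

    Attention remains imperfect (p_attend 0.7, intrusions 0.3) so that both
    score classes are populated for every participant, but nothing links the
    labels to the EEG."""
    return GeneratorConfig(
        n_participants=5, n_sequences=5, n_channels=16,
        p300_target_boost=0.0, p300_attention_scaling=0.0,
        p_attend_base=0.7, intrusion_rate=0.3, seed=seed,
    )


def planted_config(seed: int, boost: float = 5.0) -> GeneratorConfig:
    """Same study with a Target-locked P3 boost and no attention scaling.

    With the attention scaling at zero, Distractor epochs carry no
    label-linked signal, making the Distractor score task a negative
    control.  The recovery study uses more sequences per participant than
    the null grid: after the score-0 and per-condition filtering only a
    fraction of epochs feed each task, and the recovery test needs enough
    of them for a usefully narrow chance band."""
    return replace(null_config(seed), p300_target_boost=boost, n_sequences=15)


def run_cells(config: GeneratorConfig,
              tasks: Sequence[tuple[str, str]],
              pipelines: Sequence[str],
              split_spec: SplitSpec,
              top_channels: int | None = 10) -> pd.DataFrame:
    """Generate one experiment and evaluate every task x pipeline cell.

    Returns the tidy results table with one row per split, augmented with
    per-split test-set class counts (needed for exact chance bands)."""
    epochset, trials = generate_experiment(config)
    values = epochset.values_array()
    meta = apply_scores(epochset.metadata_frame(), trials)
    frames = []
    for task_name, stratum in tasks:
        task = TaskSpec(task_name, stratum, seed=config.seed)
        for pipeline in pipelines:
            results = run_task(values, meta, pipeline, task, split_spec,
                               top_channels=top_channels)
            frame = results_frame(results)
            counts = _test_class_counts(values, meta, task, split_spec)
            frame["test_class_counts"] = [counts[r.repeat_index] for r in results]
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def _test_class_counts(values, meta, task, split_spec):
    from .evaluation import build_task_dataset, make_splits

    rows, labels = build_task_dataset(meta.reset_index(drop=True), task)
    task_meta = meta.reset_index(drop=True).iloc[rows].reset_index(drop=True)
    counts = {}
    for split in make_splits(task_meta, split_spec, labels=labels):
        _, per_class = np.unique(labels[split.test_idx], return_counts=True)
        counts[split.repeat_index] = tuple(int(c) for c in per_class)
    return counts


def chance_band(class_counts: Sequence[Sequence[int]], z: float) -> tuple[float, float]:
    """Chance level and half-width of the band for the mean balanced
    accuracy over independent repeats.

    ``class_counts`` holds the test-set class counts of each repeat.  Under
    the null every per-class recall is Binomial(n_c, 1/K)/n_c, so the mean
    balanced accuracy over R repeats has variance
    (1/R^2) sum_r (1/K^2) sum_c p(1-p)/n_rc with p = 1/K."""
    n_classes = {len(c) for c in class_counts}
    if len(n_classes) != 1:
        raise ValueError("repeats disagree on the number of classes")
    k = n_classes.pop()
    p = 1.0 / k
    r = len(class_counts)
    variance = sum(
        sum(p * (1 - p) / n for n in counts) / k**2 for counts in class_counts
    ) / r**2
    return p, z * float(np.sqrt(variance))


def null_calibration(seed: int, n_repeats: int = 10,
                     tasks: Sequence[tuple[str, str]] = NULL_TASKS,
                     pipelines: Sequence[str] = NULL_PIPELINES) -> pd.DataFrame:
    """Run the null grid over ``n_repeats`` fresh experiments.

    Returns one row per (task, stratum, pipeline) with the mean balanced
    accuracy, the chance level, and the Bonferroni-adjusted 95% chance band
    half-width for the grid."""
    frames = []
    for rep in range(n_repeats):
        config = null_config(seed=int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31))
        split = SplitSpec(scenario="seen_participants", n_repeats=1, seed=config.seed)
        frame = run_cells(config, tasks, pipelines, split)
        frame["dataset_repeat"] = rep
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    n_cells = len(tasks) * len(pipelines)
    # two-sided family-wise 5% over the grid (Sidak-adjusted normal quantile)
    from scipy.stats import norm

    z = float(norm.ppf(1 - (1 - 0.95 ** (1 / n_cells)) / 2))
    rows = []
    for (task, stratum, pipeline), grp in table.groupby(["task", "stratum", "pipeline_tag"]):
        chance, band = chance_band(list(grp["test_class_counts"]), z=z)
        rows.append({
            "task": task, "stratum": stratum, "pipeline": pipeline,
            "mean_balanced_accuracy": grp["balanced_accuracy"].mean(),
            "chance": chance, "band": band, "n_repeats": len(grp),
            "n_test_total": int(sum(sum(c) for c in grp["test_class_counts"])),
        })
    return pd.DataFrame(rows)


def planted_p300_study(seed: int, boost: float = 5.0,
                       n_repeats: int = 3) -> pd.DataFrame:
    """Planted-boost recovery and its negative control.

    Evaluates the UTS pipeline on the stimulus task (should recover the
    boost) and on the Distractor score task (should stay at chance), over
    ``n_repeats`` fresh experiments."""
    tasks = (("stimulus", "C1"), ("score", "Distractor"))
    frames = []
    for rep in range(n_repeats):
        config = planted_config(
            seed=int(np.random.SeedSequence([seed, 17, rep]).generate_state(1)[0] % 2**31),
            boost=boost,
        )
        split = SplitSpec(scenario="seen_participants", n_repeats=1, seed=config.seed)
        frame = run_cells(config, tasks, ("uts",), split)
        frame["dataset_repeat"] = rep
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def boost_monotonicity(seed: int, boosts: Sequence[float] = (0.0, 2.0, 5.0, 10.0),
                       n_seeds: int = 5) -> pd.DataFrame:
    """Mean stimulus-task UTS accuracy as a function of the planted boost.

    Uses a single-condition design (C1 only) so every epoch is eligible for
    the one stimulus task; each (boost, seed) pair draws a fresh experiment."""
    rows = []
    for boost in boosts:
        accuracies = []
        for rep in range(n_seeds):
            child = int(np.random.SeedSequence([seed, 23, rep]).generate_state(1)[0] % 2**31)
            config = GeneratorConfig(
                n_participants=4, n_sequences=8, n_channels=12,
                conditions=("C1",),
                p300_target_boost=boost, p300_attention_scaling=0.0,
                p_attend_base=0.7, intrusion_rate=0.3, seed=child,
            )
            split = SplitSpec(scenario="seen_participants", n_repeats=1, seed=child)
            frame = run_cells(config, (("stimulus", "C1"),), ("uts",), split)
            accuracies.append(frame["balanced_accuracy"].mean())
        rows.append({"boost": boost,
                     "mean_balanced_accuracy": float(np.mean(accuracies)),
                     "n_seeds": n_seeds})
    return pd.DataFrame(rows)
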
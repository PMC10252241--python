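"""Training orchestration: adaptive two-level early stopping + gradual loss.

The loop trains the plan's model with plain SGD.  Every ``micro_check_every``
batches the loss on a fixed held-out validation mini-batch feeds the micro
patience controller, which may abort the current epoch; the epoch's logged
loss is then the gradual cross-entropy over the ``l`` consumed of the ``N``
allocated examples.  After every epoch the full-validation loss feeds the
macro controller, which may stop the run; the best-validation checkpoint is
restored on stop.

Any object exposing ``train_step / eval_loss / predict_proba / get_state /
set_state`` can stand in for the real network (scripted stubs in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import losses, netplan, patience
from .data import GradedImageSet, num_classes_for
from .metrics import confusion_matrix, metrics_report

__all__ = ["RunConfig", "TrainingTrace", "train_with_adaptive_stopping", "evaluate"]

TRACE_COLUMNS = [
    "epoch",
    "batch",
    "split",
    "monitored_value",
    "epsilon",
    "threshold",
    "stall_count",
    "decision",
]


@dataclass
class RunConfig:
    task: str = "five"
    max_epochs: int = 50
    batch_size: int = 32
    micro_check_every: int = 10
    macro_window: int = 3
    micro_window: int = 3
    min_epochs: int = 3
    learning_rate: float = 0.001
    seed: int = 0
    image_size: int = 64
    growth_rate: int = netplan.DEFAULT_GROWTH_RATE
    block_layers: tuple[int, ...] = netplan.DEFAULT_BLOCK_LAYERS
    micro_enabled: bool = True
    data_dir: str = ""
    out_dir: str = ""

    def __post_init__(self) -> None:
        if self.min_epochs < 1 or self.max_epochs < self.min_epochs:
            raise ValueError("need max_epochs >= min_epochs >= 1")
        if self.batch_size < 1 or self.micro_check_every < 1:
            raise ValueError("batch_size and micro_check_every must be >= 1")

    @property
    def num_classes(self) -> int:
        return num_classes_for(self.task)


@dataclass
class TrainingTrace:
    rows: list[dict] = field(default_factory=list)

    def append(self, **row: Any) -> None:
        self.rows.append({k: row.get(k) for k in TRACE_COLUMNS})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=TRACE_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def count(self, split: str) -> int:
        return sum(r["split"] == split for r in self.rows)


def _batched_eval_loss(model, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    total, n = 0.0, len(x)
    for i in range(0, n, batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        total += model.eval_loss(xb, yb) * len(xb)
    return total / n


def train_with_adaptive_stopping(
    config: RunConfig,
    dataset: GradedImageSet,
    model=None,
) -> tuple[TrainingTrace, Any, dict]:
    """Run the training loop; returns (trace, model-at-best-val, summary).

    ``dataset`` must already carry train/val split assignments; labels are
    regrouped for ``config.task`` here.
    """
    train_x, train_y = dataset.subset("train").arrays(config.task)
    val_x, val_y = dataset.subset("val").arrays(config.task)
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("train and val splits must both be non-empty")

    if model is None:
        plan = netplan.build_layer_plan(
            (config.image_size, config.image_size, 1),
            config.num_classes,
            growth_rate=config.growth_rate,
            block_layers=config.block_layers,
        )
        model = netplan.instantiate_network(plan, config.seed)

    rng = np.random.default_rng(config.seed)
    # fixed held-out mini-batch for the within-epoch (micro) checks
    micro_idx = rng.choice(len(val_x), size=min(config.batch_size, len(val_x)), replace=False)
    micro_x, micro_y = val_x[micro_idx], val_y[micro_idx]

    trace = TrainingTrace()
    macro_state = patience.init_patience()
    best_val = np.inf
    best_state = model.get_state()
    total_batches = 0
    stopped_epoch = None

    for epoch in range(1, config.max_epochs + 1):
        micro_state = patience.init_patience()
        perm = rng.permutation(len(train_x))
        epoch_alloc = len(train_x)  # N: examples allocated to this epoch
        consumed = 0  # l: examples processed before any abort
        ce_sum = 0.0
        micro_aborted = False

        for batch_i, start in enumerate(range(0, epoch_alloc, config.batch_size)):
            idx = perm[start : start + config.batch_size]
            loss = model.train_step(train_x[idx], train_y[idx], config.learning_rate)
            consumed += len(idx)
            total_batches += 1
            ce_sum += loss * len(idx)
            trace.append(
                epoch=epoch, batch=batch_i, split="train", monitored_value=loss
            )

            if config.micro_enabled and (batch_i + 1) % config.micro_check_every == 0:
                vloss = model.eval_loss(micro_x, micro_y)
                prev = micro_state.last_value
                micro_state = patience.observe(micro_state, vloss)
                decision = patience.should_stop_micro(micro_state, config.micro_window)
                trace.append(
                    epoch=epoch,
                    batch=batch_i,
                    split="val_micro",
                    monitored_value=vloss,
                    epsilon=vloss - prev if micro_state.step_index > 1 else None,
                    threshold=micro_state.patience_threshold,
                    stall_count=micro_state.stall_count,
                    decision=decision.level if decision.stop else "",
                )
                if decision.stop:
                    micro_aborted = True
                    break

        # epoch loss: gradual CE over the consumed portion (delta = N / l)
        delta = losses.delta_coefficient(epoch_alloc, consumed)
        epoch_loss = delta / epoch_alloc * ce_sum
        trace.append(
            epoch=epoch,
            split="train_epoch",
            monitored_value=epoch_loss,
            decision="micro" if micro_aborted else "",
        )

        val_loss = _batched_eval_loss(model, val_x, val_y, config.batch_size)
        prev = macro_state.last_value
        macro_state = patience.observe(macro_state, val_loss)
        decision = patience.should_stop_macro(
            macro_state, config.macro_window, config.min_epochs
        )
        trace.append(
            epoch=epoch,
            split="val",
            monitored_value=val_loss,
            epsilon=val_loss - prev if macro_state.step_index > 1 else None,
            threshold=macro_state.patience_threshold,
            stall_count=macro_state.stall_count,
            decision=decision.level if decision.stop else "",
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
        if decision.stop:
            stopped_epoch = epoch
            break

    model.set_state(best_state)  # restore best-validation checkpoint
    summary = {
        "epochs_run": epoch,
        "stopped_epoch": stopped_epoch,
        "total_batches": total_batches,
        "best_val_loss": float(best_val),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trace.to_csv(out / "trace.csv")
        if hasattr(model, "save_checkpoint"):
            model.save_checkpoint(out / "checkpoint.npz")
    return trace, model, summary


def evaluate(model, dataset: GradedImageSet, task: str, split: str = "test") -> dict:
    """Confusion matrix plus micro/macro metrics on one split."""
    x, y = dataset.subset(split).arrays(task)
    if len(x) == 0:
        raise ValueError(f"{split} split is empty")
    probs = model.predict_proba(x)
    if probs.shape[1] != num_classes_for(task):
        raise ValueError(
            f"model emits {probs.shape[1]} classes but task {task!r} has "
            f"{num_classes_for(task)}"
        )
    preds = probs.argmax(axis=1)
    cm = confusion_matrix(y, preds, num_classes_for(task))
    return {
        "confusion_matrix": cm,
        "metrics": metrics_report(cm, task, split),
        "accuracy": float((preds == y).mean()),
    }
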
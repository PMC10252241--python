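"""Adaptive-patience early stopping.

The monitored measure (validation loss) is observed as a sequence
``t_1, t_2, ...``.  Each new observation contributes a difference
``eps_i = t_i - t_{i-1}``; the patience threshold is the running average of
those differences, so the bar for "improvement" adapts to the trajectory
instead of being a fixed epoch count.

Two controllers share this state machine:

* the **macro** controller observes full-validation loss once per epoch and
  aborts the whole training run;
* the **micro** controller observes held-out-minibatch loss every few
  training batches and aborts only the current epoch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

__all__ = [
    "PatienceState",
    "StopDecision",
    "init_patience",
    "observe",
    "should_stop_macro",
    "should_stop_micro",
]

ThresholdMode = Literal["incremental", "literal"]


@dataclass(frozen=True)
class PatienceState:
    """Running statistics of the monitored measure and its differences.

    Attributes
    ----------
    step_index:
        Number of observations seen so far (``i``).
    last_value:
        Most recent observed measure (``t_i``); ``nan`` before the first
        observation.
    running_avg_diff:
        Running average of the successive differences ``eps``; ``nan``
        until two observations exist.
    patience_threshold:
        Current adaptive threshold.  Equal to ``running_avg_diff`` in the
        default mode; see :func:`observe` for the literal mode.
    stall_count:
        Consecutive observations whose difference failed to beat the
        threshold (no sufficient improvement).
    mode:
        Threshold update rule, ``"incremental"`` (default) or ``"literal"``.
    """

    step_index: int = 0
    last_value: float = math.nan
    running_avg_diff: float = math.nan
    patience_threshold: float = math.nan
    stall_count: int = 0
    mode: ThresholdMode = "incremental"

    @property
    def n_diffs(self) -> int:
        """Number of successive differences accumulated so far."""
        return max(self.step_index - 1, 0)


@dataclass(frozen=True)
class StopDecision:
    """Outcome of a stop query.  ``level == "none"`` iff ``stop`` is False."""

    stop: bool
    level: Literal["macro", "micro", "none"]
    reason: str

    def __post_init__(self) -> None:
        if self.stop == (self.level == "none"):
            raise ValueError("level must be 'none' exactly when stop is False")


def init_patience(mode: ThresholdMode = "incremental") -> PatienceState:
    """Return a fresh state; no stop is possible before two observations."""
    if mode not in ("incremental", "literal"):
        raise ValueError(f"unknown threshold mode: {mode!r}")
    return PatienceState(mode=mode)


def _effective_threshold(avg_diff: float) -> float:
    # Floor at zero: a genuinely decreasing loss (eps < 0) is always an
    # improvement, even when it decreases more slowly than the historical
    # average.  Without the floor a constant-rate descent would stall
    # (eps == avg), which is plainly wrong for an improvement monitor.
    return max(avg_diff, 0.0)


def observe(state: PatienceState, value: float) -> PatienceState:
    """Fold one monitored value into the state; pure, returns a new state.

    The difference ``eps = value - last_value`` is averaged into
    ``running_avg_diff``.  In the default ``incremental`` mode the patience
    threshold is that running mean.  In the ``literal`` mode it is
    ``(avg_prev + eps) / (i + 1)`` with ``i`` the observation index — kept
    for comparison even though it is not a self-consistent running mean.

    The observation stalls (``stall_count`` increments) when
    ``eps >= max(threshold, 0)``: the loss failed to improve beyond the
    adaptive bar.  Otherwise ``stall_count`` resets to 0.
    """
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"monitored value must be finite, got {value!r}")

    i = state.step_index + 1
    if state.step_index == 0:
        return replace(state, step_index=1, last_value=value)

    eps = value - state.last_value
    k = state.n_diffs + 1  # diffs including this one
    if k == 1:
        avg = eps
    else:
        avg = state.running_avg_diff + (eps - state.running_avg_diff) / k

    if state.mode == "literal":
        prev_avg = 0.0 if math.isnan(state.running_avg_diff) else state.running_avg_diff
        threshold = (prev_avg + eps) / (i + 1)
    else:
        threshold = avg

    stalled = eps >= _effective_threshold(threshold)
    return PatienceState(
        step_index=i,
        last_value=value,
        running_avg_diff=avg,
        patience_threshold=threshold,
        stall_count=state.stall_count + 1 if stalled else 0,
        mode=state.mode,
    )


def _check_window(window: int) -> None:
    if not isinstance(window, int) or isinstance(window, bool) or window < 1:
        raise ValueError(f"window must be an integer >= 1, got {window!r}")


def should_stop_macro(
    state: PatienceState, window: int, min_epochs: int = 3
) -> StopDecision:
    """Epoch-level stop: halt the whole run after ``window`` stalled epochs.

    No stop is permitted during the first ``min_epochs`` observations
    (warm-up guard against immature stopping).
    """
    _check_window(window)
    if state.step_index > min_epochs and state.stall_count >= window:
        return StopDecision(
            stop=True,
            level="macro",
            reason=(
                f"no improvement beyond adaptive threshold for "
                f"{state.stall_count} consecutive epochs (window={window})"
            ),
        )
    return StopDecision(stop=False, level="none", reason="")


def should_stop_micro(state: PatienceState, window: int) -> StopDecision:
    """Batch-level stop: abort only the current epoch; no warm-up guard."""
    _check_window(window)
    if state.stall_count >= window:
        return StopDecision(
            stop=True,
            level="micro",
            reason=(
                f"no improvement beyond adaptive threshold for "
                f"{state.stall_count} consecutive checks (window={window})"
            ),
        )
    return StopDecision(stop=False, level="none", reason="")
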
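"""Sliding-window episodic environment for activity-intensity inference.

An episode is one window of ``L`` consecutive seconds (default 300) of a
session.  At each second the environment emits a five-component state
``[weight, height, age, gender_flag, hr_t]``; the agent answers with an
index into the discrete coefficient grid ``a in {0, 0.1, ..., 20}`` and
is rewarded with the GT-normalized negative absolute error
``-|gt - pred| / (1 + gt)`` of the resulting prediction
``rmr_sec * (1 + a)``.

States are exposed raw; any standardization is owned by the agent.
Time is 0-based and windows are half-open ``[start, start + L)``.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np

from .formulas import ParticipantProfile, rmr_per_second
from .synth import SessionRecord

__all__ = [
    "STATE_DIM",
    "ActionGrid",
    "EnvironmentWindow",
    "make_windows",
    "state_at",
    "action_to_coefficient",
    "reward",
    "optimal_action",
]

#: Components of the state vector: weight, height, age, gender flag, HR.
STATE_DIM = 5


class ActionGrid:
    """The discrete activity-intensity coefficients: 201 values, 0 to 20
    at 0.1 spacing."""

    n_actions: int = 201
    spacing: float = 0.1

    def __init__(self) -> None:
        self.coefficients = np.round(np.arange(self.n_actions) * self.spacing, 1)

    def __len__(self) -> int:
        return self.n_actions

    def coefficient(self, index: int) -> float:
        return action_to_coefficient(index)


def action_to_coefficient(index: int) -> float:
    """Map a grid index to its coefficient ``a = index / 10``."""
    index = int(index)
    if not 0 <= index <= 200:
        raise ValueError(f"action index must be in [0, 200], got {index}")
    return round(index / 10.0, 1)


def reward(gt_ee: Union[float, np.ndarray], pred_ee: Union[float, np.ndarray]):
    """GT-normalized negative absolute error: ``-|gt - pred| / (1 + gt)``.

    Always <= 0, and 0 exactly when the prediction matches.  Works
    elementwise on arrays.
    """
    gt_ee = np.asarray(gt_ee, dtype=float)
    if np.any(gt_ee < 0):
        raise ValueError("gt_ee must be >= 0")
    out = -np.abs(gt_ee - np.asarray(pred_ee, dtype=float)) / (1.0 + gt_ee)
    return float(out) if out.ndim == 0 else out


def optimal_action(gt_ee: float, rmr_sec: float) -> int:
    """Best grid index by brute force over all 201 actions.

    Ties break toward the lowest index (first argmax).
    """
    if not rmr_sec > 0:
        raise ValueError(f"rmr_sec must be > 0, got {rmr_sec}")
    grid = ActionGrid()
    rewards = reward(np.full(grid.n_actions, float(gt_ee)), rmr_sec * (1.0 + grid.coefficients))
    return int(np.argmax(rewards))


def state_at(window: "EnvironmentWindow", t: int) -> np.ndarray:
    """Raw state vector at second ``t`` of the window (0-based)."""
    return window.state(t)


class EnvironmentWindow:
    """One episode: ``length`` contiguous seconds of a session.

    Follows the conventional episodic-control contract::

        state = env.reset()
        while True:
            next_state, r, done = env.step(action)
            if done:
                break
    """

    def __init__(self, session: SessionRecord, start: int, length: int):
        if start < 0 or start + length > len(session):
            raise ValueError(
                f"window [{start}, {start + length}) exceeds session of length {len(session)}"
            )
        self.profile: ParticipantProfile = session.profile
        self.start = int(start)
        self.length = int(length)
        self.hr = session.hr[start : start + length]
        gt = session.gt_ee
        self.gt_ee: Optional[np.ndarray] = None if gt is None else gt[start : start + length]
        labels = session.labels
        self.labels = None if labels is None else labels[start : start + length]
        self.rmr_sec = rmr_per_second(self.profile).value
        self._demo = np.array(
            [self.profile.weight, self.profile.height, self.profile.age, self.profile.gender_flag],
            dtype=float,
        )
        self.cursor = 0

    def __len__(self) -> int:
        return self.length

    @property
    def done(self) -> bool:
        return self.cursor >= self.length

    def state(self, t: int) -> np.ndarray:
        if not 0 <= t < self.length:
            raise IndexError(f"t={t} outside window of length {self.length}")
        return np.append(self._demo, self.hr[t])

    def states(self) -> np.ndarray:
        """All per-second states of the window as a (length, 5) array."""
        out = np.empty((self.length, STATE_DIM))
        out[:, :4] = self._demo
        out[:, 4] = self.hr
        return out

    def reset(self) -> np.ndarray:
        self.cursor = 0
        return self.state(0)

    def step(self, action_index: int) -> tuple[np.ndarray, float, bool]:
        """Apply an action at the current second; advance the cursor.

        Returns ``(next_state, reward, done)``; ``done`` is raised
        exactly after the last second has been stepped.  Requires the
        session to carry ground-truth EE.
        """
        if self.done:
            raise RuntimeError("step() called on a finished window; reset() first")
        if self.gt_ee is None:
            raise ValueError("cannot compute rewards: session has no ground-truth EE")
        a = action_to_coefficient(action_index)
        pred = self.rmr_sec * (1.0 + a)
        r = reward(self.gt_ee[self.cursor], pred)
        self.cursor += 1
        done = self.cursor >= self.length
        next_state = self.state(min(self.cursor, self.length - 1))
        return next_state, r, done


def make_windows(
    session: SessionRecord, length_s: int = 300, stride_s: int = 1
) -> list[EnvironmentWindow]:
    """All windows of ``length_s`` seconds at the given stride.

    Starts are ``0, stride, 2*stride, ...``; the count is
    ``floor((T - length) / stride) + 1``.  A session shorter than one
    window yields an empty list with a warning.
    """
    if stride_s < 1:
        raise ValueError(f"stride_s must be >= 1, got {stride_s}")
    T = len(session)
    if T < length_s:
        warnings.warn(
            f"session of {T} s is shorter than the window length {length_s} s; no windows",
            stacklevel=2,
        )
        return []
    starts = range(0, T - length_s + 1, stride_s)
    return [EnvironmentWindow(session, s, length_s) for s in starts]
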
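"""Synthetic per-second wearable sessions.

Emulates the structure of a 30-minute sit/stand/cycle/run protocol
sampled at 1 Hz: one participant profile plus a per-second series of
heart rate, oxygen uptake and activity label, so that every downstream
module (environment, agent, evaluation) is exercisable without any
external dataset.

Generation model
----------------
* target MET is piecewise constant per activity segment (sitting 1.0 and
  standing 1.2 fixed; cycling/running levels sampled within observed
  per-activity ranges);
* effective MET follows the target through a first-order lag with time
  constant ``tau`` (cardiorespiratory transition delay);
* VO2 = 3.5 * effective MET (mL/kg/min), the standard 1-MET identity;
* HR = hr_rest + hr_slope * (effective MET - 1) + AR(1) noise;
* ground-truth EE is indirect calorimetry on the effective VO2, per second.

All randomness flows from one explicit seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .formulas import ParticipantProfile

__all__ = [
    "SEGMENT_LABELS",
    "MET_LEVEL_RANGES",
    "ProtocolSegment",
    "ActivityProtocol",
    "NoiseParams",
    "SessionRecord",
    "generate_profile",
    "generate_met_trajectory",
    "generate_session",
]

#: Canonical segment labels, in protocol order.
SEGMENT_LABELS = ("Sitting", "Standing", "Cycle1", "Cycle2", "Run1", "Run2")

#: Observed MET ranges per segment across participants (min, max).
#: Sitting and standing are the same for everyone; exercise intensity varies.
MET_LEVEL_RANGES = {
    "Sitting": (1.0, 1.0),
    "Standing": (1.2, 1.2),
    "Cycle1": (4.0, 16.0),
    "Cycle2": (12.0, 16.0),
    "Run1": (4.5, 15.0),
    "Run2": (10.0, 20.0),
}

_CSV_COLUMNS = ["time_s", "hr_bpm", "vo2_ml_kg_min", "activity", "met_true"]


@dataclass(frozen=True)
class ProtocolSegment:
    label: str
    duration_s: int
    met_level: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.met_level < 1.0:
            raise ValueError(f"met_level must be >= 1, got {self.met_level}")


@dataclass(frozen=True)
class ActivityProtocol:
    """Ordered activity segments with target MET levels."""

    segments: tuple[ProtocolSegment, ...]

    @property
    def total_duration_s(self) -> int:
        return sum(s.duration_s for s in self.segments)

    @classmethod
    def default(
        cls,
        met_levels: Optional[dict[str, float]] = None,
        rng: Optional[np.random.Generator] = None,
        segment_duration_s: int = 300,
    ) -> "ActivityProtocol":
        """Six-segment protocol (five minutes each by default, 1800 s total).

        Exercise MET levels are taken from ``met_levels`` when given,
        otherwise sampled uniformly within :data:`MET_LEVEL_RANGES`
        using ``rng`` (required in that case).
        """
        met_levels = dict(met_levels or {})
        segments = []
        for label in SEGMENT_LABELS:
            lo, hi = MET_LEVEL_RANGES[label]
            if label in met_levels:
                level = float(met_levels[label])
            elif lo == hi:
                level = lo
            else:
                if rng is None:
                    raise ValueError(
                        f"no MET level supplied for {label!r} and no rng to sample one"
                    )
                level = float(rng.uniform(lo, hi))
            segments.append(ProtocolSegment(label, segment_duration_s, level))
        return cls(tuple(segments))


@dataclass(frozen=True)
class NoiseParams:
    """Heart-rate model parameters.

    ``noise_sd`` is the stationary standard deviation of the AR(1)
    heart-rate noise; ``tau`` the first-order VO2 lag in seconds
    (``tau = 0`` means instantaneous transitions).
    """

    hr_rest: float = 65.0
    hr_slope: float = 9.0
    noise_sd: float = 2.0
    ar_coef: float = 0.9
    tau: float = 30.0


@dataclass
class SessionRecord:
    """One participant's per-second session.

    ``samples`` holds columns ``time_s, hr_bpm, vo2_ml_kg_min, activity,
    met_true`` (the last two optional in imported data).  Ground-truth
    EE is derived from VO2 on demand, which makes the invariant
    ``gt_ee[t] == gt_ee_per_second(vo2[t], weight)`` hold by
    construction.
    """

    profile: ParticipantProfile
    samples: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ("time_s", "hr_bpm") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"samples missing required columns: {missing}")
        t = self.samples["time_s"].to_numpy()
        if len(t) and not np.array_equal(t, np.arange(t[0], t[0] + len(t))):
            raise ValueError("time_s must be consecutive at 1 s spacing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def hr(self) -> np.ndarray:
        return self.samples["hr_bpm"].to_numpy(dtype=float)

    @property
    def vo2(self) -> Optional[np.ndarray]:
        if "vo2_ml_kg_min" not in self.samples.columns:
            return None
        return self.samples["vo2_ml_kg_min"].to_numpy(dtype=float)

    @property
    def labels(self) -> Optional[np.ndarray]:
        if "activity" not in self.samples.columns:
            return None
        return self.samples["activity"].to_numpy()

    @property
    def met_true(self) -> Optional[np.ndarray]:
        if "met_true" not in self.samples.columns:
            return None
        return self.samples["met_true"].to_numpy(dtype=float)

    @property
    def gt_ee(self) -> Optional[np.ndarray]:
        """Per-second ground-truth EE in kcal/s, derived from VO2."""
        vo2 = self.vo2
        if vo2 is None:
            return None
        return vo2 * self.profile.weight * 5.0 / 1000.0 / 60.0

    def save(self, csv_path: Union[str, Path]) -> None:
        """Write the sample table as CSV plus a ``.json`` profile sidecar."""
        csv_path = Path(csv_path)
        cols = [c for c in _CSV_COLUMNS if c in self.samples.columns]
        self.samples[cols].to_csv(csv_path, index=False)
        sidecar = {"profile": asdict(self.profile), "meta": self.meta}
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, csv_path: Union[str, Path]) -> "SessionRecord":
        csv_path = Path(csv_path)
        samples = pd.read_csv(csv_path)
        sidecar = json.loads(csv_path.with_suffix(".json").read_text())
        profile = ParticipantProfile(**sidecar["profile"])
        return cls(profile=profile, samples=samples, meta=sidecar.get("meta", {}))


def _resolve_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_profile(rng_seed: Union[int, np.random.Generator, None]) -> ParticipantProfile:
    """Draw a participant: age U[23, 41] y, height U[160, 186] cm,
    weight U[53, 99] kg, gender Bernoulli(1/2)."""
    rng = _resolve_rng(rng_seed)
    return ParticipantProfile(
        weight=round(float(rng.uniform(53.0, 99.0)), 1),
        height=round(float(rng.uniform(160.0, 186.0)), 1),
        age=float(rng.integers(23, 42)),
        gender_flag=int(rng.integers(0, 2)),
    )


def generate_met_trajectory(protocol: ActivityProtocol) -> np.ndarray:
    """Per-second piecewise-constant target MET over the whole protocol."""
    parts = [np.full(seg.duration_s, seg.met_level, dtype=float) for seg in protocol.segments]
    return np.concatenate(parts) if parts else np.empty(0)


def _segment_labels(protocol: ActivityProtocol) -> np.ndarray:
    parts = [np.full(seg.duration_s, seg.label, dtype=object) for seg in protocol.segments]
    return np.concatenate(parts) if parts else np.empty(0, dtype=object)


def _first_order_lag(target: np.ndarray, tau: float) -> np.ndarray:
    """Discrete first-order response to ``target`` with time constant tau."""
    if tau <= 0:
        return target.astype(float).copy()
    alpha = 1.0 - np.exp(-1.0 / tau)
    out = np.empty_like(target, dtype=float)
    level = target[0]
    for t, tgt in enumerate(target):
        level = level + alpha * (tgt - level)
        out[t] = level
    return out


def generate_session(
    profile: ParticipantProfile,
    protocol: ActivityProtocol,
    noise_params: Optional[NoiseParams] = None,
    rng_seed: Union[int, np.random.Generator, None] = None,
) -> SessionRecord:
    """Simulate one session under the generation model (module docstring)."""
    noise = noise_params or NoiseParams()
    rng = _resolve_rng(rng_seed)

    met_target = generate_met_trajectory(protocol)
    met_eff = _first_order_lag(met_target, noise.tau)
    vo2 = 3.5 * met_eff

    hr_clean = noise.hr_rest + noise.hr_slope * (met_eff - 1.0)
    if noise.noise_sd > 0:
        n = len(met_eff)
        innov_sd = noise.noise_sd * np.sqrt(max(1.0 - noise.ar_coef**2, 0.0))
        z = rng.normal(0.0, 1.0, size=n)
        eps = np.empty(n)
        prev = noise.noise_sd * z[0] if n else 0.0
        for t in range(n):
            prev = noise.ar_coef * prev + innov_sd * z[t] if t else prev
            eps[t] = prev
        hr = hr_clean + eps
    else:
        hr = hr_clean.copy()
    hr = np.maximum(hr, 1.0)  # HR must stay physical

    samples = pd.DataFrame(
        {
            "time_s": np.arange(len(met_eff)),
            "hr_bpm": hr,
            "vo2_ml_kg_min": vo2,
            "activity": _segment_labels(protocol),
            "met_true": met_target,
        }
    )
    meta = {
        "noise_params": asdict(noise),
        "protocol": [asdict(seg) for seg in protocol.segments],
    }
    return SessionRecord(profile=profile, samples=samples, meta=meta)
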
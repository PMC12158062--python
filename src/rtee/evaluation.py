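"""Evaluation protocol: per-second baselines and MAE reporting.

Three per-second estimators are compared against VO2-derived ground
truth on the canonical kcal/s scale:

* ``ours`` — the trained agent's ``rmr_sec * (1 + a)`` series;
* ``keytel`` — the heart-rate regression, converted kJ/min -> kcal/s,
  with negatives clamped to 0 (clamping counted and reported);
* ``met`` — the per-segment MET product formula, kcal/min -> kcal/s.

Reports carry the overall MAE plus per-activity-segment MAEs in a
fixed six-segment layout and serialize losslessly to JSON (and to CSV
for spreadsheets).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agent import DQNAgent, TrainingConfig, train
from .formulas import KCAL_PER_KJ, ee_keytel, ee_met
from .synth import SEGMENT_LABELS, SessionRecord

__all__ = [
    "MetLookup",
    "MET_LOOKUP",
    "EvaluationReport",
    "fill_missing_hr",
    "keytel_series",
    "met_series",
    "mae",
    "segment_mae",
    "compare_methods",
    "split_sessions",
    "scenario_length_ablation",
]


class MetLookup:
    """Activity-description -> MET index table."""

    #: Representative MET index by activity type.
    DEFAULT_ENTRIES = {
        "resting": 1.0,
        "sitting quietly": 1.0,
        "office work": 1.5,
        "cycling 10 mph": 4.0,
        "food serving": 8.0,
        "firefighting": 13.0,
        "cycling over 20 mph": 16.0,
    }

    def __init__(self, entries: Optional[dict[str, float]] = None):
        self._table = {self._norm(k): v for k, v in (entries or self.DEFAULT_ENTRIES).items()}

    @staticmethod
    def _norm(key: str) -> str:
        # case/whitespace-insensitive; "cycling at 10 mph" == "cycling 10 mph"
        return " ".join(w for w in key.casefold().split() if w != "at")

    def __getitem__(self, activity: str) -> float:
        try:
            return self._table[self._norm(activity)]
        except KeyError:
            raise KeyError(f"no MET entry for activity {activity!r}") from None

    def __contains__(self, activity: str) -> bool:
        try:
            self[activity]
        except KeyError:
            return False
        return True

    def __len__(self) -> int:
        return len(self._table)


MET_LOOKUP = MetLookup()


def fill_missing_hr(hr: np.ndarray) -> tuple[np.ndarray, int]:
    """Forward-fill NaN heart-rate seconds (back-fill a leading gap).

    Returns the filled series and the number of filled samples.
    """
    s = pd.Series(np.asarray(hr, dtype=float))
    n_missing = int(s.isna().sum())
    if n_missing:
        s = s.ffill().bfill()
        if s.isna().any():
            raise ValueError("heart-rate series is entirely missing")
    return s.to_numpy(), n_missing


def keytel_series(
    session: SessionRecord, clamp_negative: bool = True, fill_missing: bool = True
) -> np.ndarray:
    """Per-second Keytel EE in kcal/s (formula-only; ignores GT and agent)."""
    hr = session.hr
    if fill_missing:
        hr, _ = fill_missing_hr(hr)
    elif np.isnan(hr).any():
        raise ValueError("heart-rate series has missing seconds; enable fill_missing")
    p = session.profile
    # vectorized form of the per-second ee_keytel call, kJ/min -> kcal/s
    c0, c_hr, c_w, c_a = (
        (-55.0969, 0.6309, 0.1988, 0.2017)
        if p.gender_flag == 1
        else (-20.4022, 0.4472, -0.1263, 0.074)
    )
    kj_min = c0 + c_hr * hr + c_w * p.weight + c_a * p.age
    out = kj_min * KCAL_PER_KJ / 60.0
    if clamp_negative:
        out = np.maximum(out, 0.0)
    return out


def met_series(
    session: SessionRecord, met_per_segment: Optional[dict[str, float]] = None
) -> np.ndarray:
    """Per-second MET-formula EE in kcal/s.

    Uses the session's true per-second MET labels unless
    ``met_per_segment`` maps each activity label to a MET index (the
    tabulated-MET use case, including deliberate mis-specification).
    Every second must be resolvable to a MET value.
    """
    w = session.profile.weight
    if met_per_segment is not None:
        labels = session.labels
        if labels is None:
            raise ValueError("session has no activity labels")
        unknown = sorted(set(labels) - set(met_per_segment))
        if unknown:
            raise ValueError(f"no MET value for segments: {unknown}")
        mets = np.array([met_per_segment[lab] for lab in labels], dtype=float)
    else:
        mets = session.met_true
        if mets is None or np.isnan(mets).any():
            raise ValueError("session lacks per-second MET labels; pass met_per_segment")
    return mets * w * 3.5 / 200.0 / 60.0


def mae(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean absolute error between two equal-length per-second series."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {gt.shape}")
    return float(np.mean(np.abs(pred - gt)))


def segment_mae(pred: np.ndarray, gt: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """MAE within each activity label class."""
    pred = np.asarray(pred, dtype=float)
    gt = np.asarray(gt, dtype=float)
    labels = np.asarray(labels)
    if not (pred.shape == gt.shape == labels.shape):
        raise ValueError("pred, gt and labels must have equal lengths")
    return {
        str(lab): float(np.mean(np.abs(pred[labels == lab] - gt[labels == lab])))
        for lab in pd.unique(labels)
    }


@dataclass
class EvaluationReport:
    """Overall and per-segment MAE (kcal/s) for each estimator."""

    maes: dict[str, dict[str, float]]  # estimator -> {"Total", segment...}
    n_seconds: int
    segment_counts: dict[str, int] = field(default_factory=dict)
    keytel_clamped: int = 0
    hr_filled: int = 0
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        cols = ["Total", *SEGMENT_LABELS]
        rows = {
            est: [vals.get(c, np.nan) for c in cols] for est, vals in self.maes.items()
        }
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    def to_json(self) -> str:
        payload = {
            "maes": self.maes,
            "n_seconds": self.n_seconds,
            "segment_counts": self.segment_counts,
            "keytel_clamped": self.keytel_clamped,
            "hr_filled": self.hr_filled,
            "meta": self.meta,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        return cls(**json.loads(text))

    def save(self, json_path: Union[str, Path], csv_path: Union[str, Path, None] = None) -> None:
        Path(json_path).write_text(self.to_json())
        if csv_path is not None:
            self.to_frame().to_csv(csv_path, index_label="method")


def compare_methods(
    agent: Optional[DQNAgent],
    sessions: Sequence[SessionRecord],
    met_per_segment: Optional[dict[str, float]] = None,
    clamp_keytel: bool = True,
    collect_traces: bool = False,
) -> EvaluationReport:
    """Three-estimator MAE report over labeled ground-truthed sessions.

    ``met_per_segment`` optionally overrides the per-second true MET
    with tabulated per-segment values.  With ``agent=None`` the report
    contains only the two formula baselines.
    """
    preds: dict[str, list[np.ndarray]] = {"keytel": [], "met": []}
    if agent is not None:
        preds["ours"] = []
    gts, labels_all, traces = [], [], []
    keytel_clamped = 0
    hr_filled = 0
    for session in sessions:
        gt = session.gt_ee
        if gt is None:
            raise ValueError("evaluation sessions must carry ground-truth EE")
        labels = session.labels
        if labels is None:
            raise ValueError("evaluation sessions must carry activity labels")
        hr_filled += fill_missing_hr(session.hr)[1]
        raw_keytel = keytel_series(session, clamp_negative=False)
        keytel_clamped += int(np.sum(raw_keytel < 0))
        preds["keytel"].append(np.maximum(raw_keytel, 0.0) if clamp_keytel else raw_keytel)
        preds["met"].append(met_series(session, met_per_segment))
        if agent is not None:
            preds["ours"].append(agent.predict_ee_series(session))
        gts.append(gt)
        labels_all.append(labels)
    gt_cat = np.concatenate(gts)
    labels_cat = np.concatenate(labels_all)

    maes: dict[str, dict[str, float]] = {}
    for est, series_list in preds.items():
        series = np.concatenate(series_list)
        maes[est] = {"Total": mae(series, gt_cat), **segment_mae(series, gt_cat, labels_cat)}
        if collect_traces:
            traces.append(
                pd.DataFrame(
                    {"method": est, "abs_error": np.abs(series - gt_cat), "activity": labels_cat}
                )
            )
    counts = {str(k): int(v) for k, v in zip(*np.unique(labels_cat, return_counts=True))}
    report = EvaluationReport(
        maes=maes,
        n_seconds=int(len(gt_cat)),
        segment_counts=counts,
        keytel_clamped=keytel_clamped,
        hr_filled=hr_filled,
    )
    if collect_traces:
        report.meta["traces"] = pd.concat(traces, ignore_index=True)
    return report


def split_sessions(
    sessions: Sequence[SessionRecord], rng: np.random.Generator
) -> tuple[list[SessionRecord], list[SessionRecord]]:
    """Leave-participants-out split holding out one male and one female.

    Falls back to holding out two arbitrary sessions when one gender is
    absent.  Requires at least three sessions.
    """
    if len(sessions) < 3:
        raise ValueError("need at least 3 sessions to split")
    males = [i for i, s in enumerate(sessions) if s.profile.gender_flag == 1]
    females = [i for i, s in enumerate(sessions) if s.profile.gender_flag == 0]
    if males and females:
        held = {int(rng.choice(males)), int(rng.choice(females))}
    else:
        held = set(rng.choice(len(sessions), size=2, replace=False).tolist())
    test = [s for i, s in enumerate(sessions) if i in held]
    train_set = [s for i, s in enumerate(sessions) if i not in held]
    return train_set, test


def scenario_length_ablation(
    sessions: Sequence[SessionRecord],
    config: Optional[TrainingConfig] = None,
    lengths: dict[str, int] = {"5Min": 300, "1Min": 60},
) -> dict[str, float]:
    """Train one agent per scenario length and report each overall MAE.

    Agents differ only in window length; the split, seeds and all other
    hyperparameters are shared.  The comparison direction is reported,
    not asserted.
    """
    from dataclasses import replace

    config = config or TrainingConfig()
    rng = np.random.default_rng(config.seed)
    train_set, test_set = split_sessions(sessions, rng)
    results: dict[str, float] = {}
    for name, length in lengths.items():
        cfg = replace(config, window_length_s=length)
        agent, _ = train(train_set, cfg)
        report = compare_methods(agent, test_set)
        results[name] = report.maes["ours"]["Total"]
    return results
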
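"""Dataset files and run configuration.

Trials travel as plain CSV with one row per trial:

    participant_id, experiment, trial_index, target_deg,
    bet1_deg .. bet6_deg, undo_bet_index, undo_original_deg

Angles are degrees in [0, 360), serialized to 3 decimals (so a
read-write-read cycle is an exact fixed point); the undo columns are
empty except in experiment-2 rows with an undo event, where
``undo_bet_index`` is the 1-based index of the erased bet.  A leading
``#``-comment line carries provenance (seed, generator version) as JSON
and is ignored by readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .observers import Dataset, Trial, UndoEvent, N_BETS

__all__ = [
    "DATASET_COLUMNS",
    "RunConfig",
    "read_dataset",
    "write_dataset",
    "dataset_from_frame",
    "frame_from_dataset",
]

BET_COLUMNS = [f"bet{k}_deg" for k in range(1, N_BETS + 1)]
DATASET_COLUMNS = (
    ["participant_id", "experiment", "trial_index", "target_deg"]
    + BET_COLUMNS
    + ["undo_bet_index", "undo_original_deg"]
)
ANGLE_COLUMNS = ["target_deg"] + BET_COLUMNS


@dataclass
class RunConfig:
    """Flat configuration mirroring the study's defaults.

    Defaults reproduce the original setup: Gaussian sd 4 degrees, penalty
    exponent 0.4, 6 bets with the first twice as tall, cohorts of 40
    participants x 150 trials.
    """

    penalty_exponent: float = 0.4
    gaussian_sd: float = 4.0
    standard_peak_mode: str = "fixed"  # "fixed" (0.1) | "calibrated"
    n_bets: int = 6
    first_bet_multiplier: float = 2.0
    observer_kind: str = "sampling"
    encoding_sd: float = 12.0
    internal_sd_mean: float = 10.0
    internal_sd_spread: float = 3.0
    bet_noise_growth: float = 2.0
    skew: float = 0.0
    confidence_coupling: float = 0.0
    lapse_rate: float = 0.005
    undo_enabled: bool = False
    n_participants: int = 40
    n_trials: int = 150
    seed: int = 0
    flip_axis: str = "target"
    ks_variant: str = "pseudo_sample"
    spread_measure: str = "adjacent"

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def penalty_params(self):
        from .profile_engine import PenaltyParams, calibrate_standard_peak

        peak = (
            calibrate_standard_peak(
                exponent=self.penalty_exponent,
                n_bets=self.n_bets,
                first_bet_multiplier=self.first_bet_multiplier,
            )
            if self.standard_peak_mode == "calibrated"
            else 0.1
        )
        return PenaltyParams(self.penalty_exponent, peak, self.gaussian_sd)

    def observer_params(self):
        from .observers import ObserverParams

        return ObserverParams(
            kind=self.observer_kind,
            encoding_sd=self.encoding_sd,
            internal_sd_mean=self.internal_sd_mean,
            internal_sd_spread=self.internal_sd_spread,
            bet_noise_growth=self.bet_noise_growth,
            skew=self.skew,
            confidence_coupling=self.confidence_coupling,
            lapse_rate=self.lapse_rate,
            undo_enabled=self.undo_enabled,
        )


def frame_from_dataset(dataset: Dataset) -> pd.DataFrame:
    """Tidy one-row-per-trial table with 3-decimal angles."""
    rows = []
    for t in dataset.trials:
        row = {
            "participant_id": t.participant_id,
            "experiment": t.experiment,
            "trial_index": t.trial_index,
            "target_deg": _q(t.target),
        }
        for k, b in enumerate(t.bets, start=1):
            row[f"bet{k}_deg"] = _q(b)
        if t.undo_event is not None:
            row["undo_bet_index"] = t.undo_event.bet_index + 1
            row["undo_original_deg"] = _q(t.undo_event.original_deg)
        else:
            row["undo_bet_index"] = pd.NA
            row["undo_original_deg"] = pd.NA
        rows.append(row)
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)


def _q(angle: float) -> float:
    """Quantize an angle to 3 decimals, keeping it inside [0, 360)."""
    return float(np.round(float(angle), 3) % 360.0)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as CSV with a provenance comment line.

    Deterministic column order and 3-decimal formatting, so the same
    dataset always produces byte-identical files.
    """
    path = Path(path)
    df = frame_from_dataset(dataset)
    prov = json.dumps(dataset.provenance, sort_keys=True) if dataset.provenance else "{}"
    with open(path, "w", newline="") as fh:
        fh.write(f"# betwheel dataset provenance: {prov}\n")
        df.to_csv(fh, index=False, float_format="%.3f")


def dataset_from_frame(df: pd.DataFrame, source: str = "<frame>") -> Dataset:
    """Validate a trial table and build a Dataset.

    Malformed rows are reported with their (1-based data) line numbers.
    """
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    problems = []
    trials = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        errs = []
        angles = [getattr(row, c) for c in ANGLE_COLUMNS]
        for c, a in zip(ANGLE_COLUMNS, angles):
            if not np.isfinite(a) or not (0.0 <= a < 360.0):
                errs.append(f"{c}={a!r} outside [0, 360)")
        exp = int(row.experiment)
        undo = None
        if not pd.isna(row.undo_bet_index):
            if exp != 2:
                errs.append("undo columns set but experiment != 2")
            idx = int(row.undo_bet_index)
            orig = float(row.undo_original_deg) if not pd.isna(row.undo_original_deg) else np.nan
            if not 1 <= idx <= N_BETS:
                errs.append(f"undo_bet_index={idx} outside 1..{N_BETS}")
            elif not np.isfinite(orig) or not (0.0 <= orig < 360.0):
                errs.append(f"undo_original_deg={orig!r} outside [0, 360)")
            else:
                undo = UndoEvent(bet_index=idx - 1, original_deg=orig)
        if errs:
            problems.append(f"line {i}: " + "; ".join(errs))
            continue
        trials.append(
            Trial(
                participant_id=int(row.participant_id),
                trial_index=int(row.trial_index),
                target=float(row.target_deg),
                bets=tuple(float(a) for a in angles[1:]),
                experiment=exp,
                undo_event=undo,
            )
        )
    if problems:
        raise ValueError(f"{source}: malformed rows:\n" + "\n".join(problems))
    return Dataset(trials)


def read_dataset(path) -> Dataset:
    """Read and validate a dataset CSV; provenance comment is restored."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    prov = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        marker = "provenance:"
        if marker in first:
            try:
                prov = json.loads(first.split(marker, 1)[1])
            except json.JSONDecodeError:
                prov = {}
    df = pd.read_csv(path, comment="#")
    ds = dataset_from_frame(df, source=str(path))
    ds.provenance = prov
    return ds
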
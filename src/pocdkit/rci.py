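"""Reliable-change-index (RCI) classification of postoperative cognitive
dysfunction (POCD).

The definition implemented here: for each test, a *change score* is the
follow-up score minus the baseline score, oriented so that negative
means deterioration.  The expected change over time (practice effect)
and its variability are estimated from a non-surgical control group
tested at matching intervals.  A patient's test is "positive" when the
patient's change score lies at least ``z_threshold`` (default 1.96)
control SDs below the control mean change, i.e.

    z = (delta - mean_ctrl) / sd_ctrl  <=  -1.96

and the patient has POCD when at least ``min_positive`` (default 2) of
the six tests are positive.  Both thresholds are inclusive.

Missing data policy: a patient with any missing test is unclassifiable
by default, mirroring the exclusion of subjects unable to complete the
full battery.  A permissive mode (classify when at least
``battery size - 1`` tests are present) is available behind the
``max_missing`` argument and is never the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .battery import BatteryDef, INTERVALS
from .errors import CalibrationError, DataError


def change_score(pre: float, post: float, orientation: int) -> float:
    """Deficit-oriented change ``orientation * (post - pre)``.

    Negative always means deterioration; missing input yields NaN.
    """
    if pre is None or post is None:
        return math.nan
    pre = float(pre)
    post = float(post)
    if math.isnan(pre) or math.isnan(post):
        return math.nan
    return orientation * (post - pre)


@dataclass(frozen=True)
class ControlChangeStats:
    """Control-group calibration: per test x interval mean and SD of the
    deficit-oriented change score, with the control counts used."""

    table: pd.DataFrame  # columns: test, interval, mean_change, sd_change, n
    battery: BatteryDef

    def get(self, test: str, interval: str) -> tuple[float, float]:
        sub = self.table[
            (self.table["test"] == test) & (self.table["interval"] == interval)
        ]
        if sub.empty:
            raise CalibrationError(f"no calibration for {test} at {interval}")
        row = sub.iloc[0]
        return float(row["mean_change"]), float(row["sd_change"])

    @property
    def n_controls(self) -> int:
        return int(self.table["n"].min())


def _control_changes(
    controls: pd.DataFrame, battery: BatteryDef, test: str, interval: str
) -> np.ndarray:
    o = battery.orientation_of(test)
    pre = controls[battery.score_column(test, "baseline")].to_numpy(float)
    post = controls[battery.score_column(test, interval)].to_numpy(float)
    delta = o * (post - pre)
    return delta[~np.isnan(delta)]


def fit_control_stats(
    controls: pd.DataFrame,
    battery: BatteryDef | None = None,
    intervals: tuple[str, ...] = INTERVALS,
) -> ControlChangeStats:
    """Estimate mean and sample SD (n-1 denominator) of control change
    scores per test x interval.

    Raises :class:`CalibrationError` when fewer than 2 complete controls
    are available for any cell or when any cell's SD is zero (the RCI is
    then undefined).
    """
    bat = battery or BatteryDef.default()
    if len(controls) == 0:
        raise CalibrationError("no controls supplied")
    rows = []
    for interval in intervals:
        for test in bat.tests:
            delta = _control_changes(controls, bat, test, interval)
            if len(delta) < 2:
                raise CalibrationError(
                    f"fewer than 2 complete controls for {test} at {interval}"
                )
            sd = float(np.std(delta, ddof=1))
            if sd <= 0.0:
                raise CalibrationError(
                    f"zero change-score SD for {test} at {interval}; "
                    "RCI undefined"
                )
            rows.append(
                {
                    "test": test,
                    "interval": interval,
                    "mean_change": float(np.mean(delta)),
                    "sd_change": sd,
                    "n": len(delta),
                }
            )
    return ControlChangeStats(table=pd.DataFrame(rows), battery=bat)


def rci_z(delta: float, ctrl: tuple[float, float]) -> float:
    """Z-score of a change score against the control calibration.

    ``ctrl`` is ``(mean_change, sd_change)``; ``sd_change`` must be > 0.
    """
    mean, sd = ctrl
    if sd <= 0:
        raise CalibrationError("sd_change must be positive")
    if delta is None or math.isnan(delta):
        return math.nan
    return (delta - mean) / sd


@dataclass(frozen=True)
class RCIOutcome:
    """Classification of one subject at one interval."""

    subject_id: str
    interval: str
    z: tuple[float, ...]
    n_positive: int
    pocd: bool
    classifiable: bool


def classify_subject(
    z,
    z_threshold: float = 1.96,
    min_positive: int = 2,
    max_missing: int = 0,
    subject_id: str = "",
    interval: str = "",
) -> RCIOutcome:
    """Apply the threshold rule to a vector of per-test z-scores.

    A test is positive when ``z <= -z_threshold`` (inclusive, matching
    "at least 1.96 SD lower").  Subjects with more than ``max_missing``
    missing tests are flagged unclassifiable (``pocd`` is then False and
    must not be counted in any denominator).
    """
    z = np.asarray(z, dtype=float)
    missing = int(np.isnan(z).sum())
    if missing > max_missing:
        return RCIOutcome(subject_id, interval, tuple(z), 0, False, False)
    n_pos = int(np.sum(z[~np.isnan(z)] <= -z_threshold))
    return RCIOutcome(subject_id, interval, tuple(z), n_pos, n_pos >= min_positive, True)


@dataclass(frozen=True)
class Incidence:
    """POCD incidence with explicit numerator and denominator."""

    n_pocd: int
    n_classifiable: int
    interval: str

    @property
    def proportion(self) -> float:
        if self.n_classifiable == 0:
            return math.nan
        return self.n_pocd / self.n_classifiable

    @property
    def percent(self) -> str:
        """Percentage to one decimal place, as reported (29/99 -> '29.3')."""
        return format_incidence(self.n_pocd, self.n_classifiable)

    def __str__(self) -> str:
        return (
            f"{self.n_pocd}/{self.n_classifiable} ({self.percent}%) "
            f"at {self.interval}"
        )


def format_incidence(k: int, n: int) -> str:
    """Format ``k/n`` as a percentage with one decimal place."""
    if n == 0:
        return "0.0" if k == 0 else "nan"
    return f"{100.0 * k / n:.1f}"


def classify_cohort(
    patients: pd.DataFrame,
    controls: pd.DataFrame,
    battery: BatteryDef | None = None,
    interval: str = "day7",
    z_threshold: float = 1.96,
    min_positive: int = 2,
    max_missing: int = 0,
    ctrl_stats: ControlChangeStats | None = None,
) -> tuple[pd.DataFrame, Incidence]:
    """Classify every patient at one interval against control calibration.

    Returns a per-subject outcome frame (id, interval, z per test,
    n_positive, pocd, classifiable) and the incidence among classifiable
    patients.  Calibration errors propagate.
    """
    bat = battery or BatteryDef.default()
    if interval not in INTERVALS:
        raise DataError(f"unknown interval {interval!r}")
    stats = ctrl_stats or fit_control_stats(controls, bat, intervals=(interval,))

    # Vectorized over patients: one (n, n_tests) z-matrix.
    z_cols = {}
    for test in bat.tests:
        o = bat.orientation_of(test)
        pre = patients[bat.score_column(test, "baseline")].to_numpy(float)
        post = patients[bat.score_column(test, interval)].to_numpy(float)
        mean, sd = stats.get(test, interval)
        z_cols[test] = (o * (post - pre) - mean) / sd
    zmat = np.column_stack([z_cols[t] for t in bat.tests])

    n_missing = np.isnan(zmat).sum(axis=1)
    classifiable = n_missing <= max_missing
    n_positive = np.nansum(zmat <= -z_threshold, axis=1).astype(int)
    n_positive[~classifiable] = 0
    pocd = classifiable & (n_positive >= min_positive)

    outcomes = pd.DataFrame({"id": patients["id"].astype(str).to_numpy(),
                             "interval": interval})
    for t in bat.tests:
        outcomes[f"z_{t}"] = z_cols[t]
    outcomes["n_positive"] = n_positive
    outcomes["pocd"] = pocd
    outcomes["classifiable"] = classifiable
    return outcomes, Incidence(int(pocd.sum()), int(classifiable.sum()), interval)


def write_outcomes_tsv(outcomes: pd.DataFrame, path) -> None:
    outcomes.to_csv(path, sep="\t", index=False)


def read_outcomes_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except FileNotFoundError:
        raise DataError(f"outcomes file not found: {path}") from None
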
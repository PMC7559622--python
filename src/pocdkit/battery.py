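"""Neuropsychological test battery definition.

The cognitive outcome is measured with a battery of six tests
(visual verbal learning, concept shifting, Stroop color-word, memory
scanning, letter-digit coding, reaction time).  Each test has an
*orientation*: +1 when a higher score means better performance (e.g.
words recalled), -1 when a higher score means worse performance (e.g.
completion time in seconds).  All change scores downstream are
multiplied by the orientation so that negative always means
deterioration.
"""

from __future__ import annotations

from dataclasses import dataclass

import yaml

from .errors import DataError

#: Canonical test slugs, in battery order.
DEFAULT_TESTS = (
    "visual_verbal_learning",
    "concept_shifting",
    "stroop",
    "memory_scanning",
    "letter_digit",
    "reaction_time",
)

# Time/latency-based tests score higher when performance is worse.  The
# orientation of each instrument is an explicit configuration choice, not
# something inferable from the data.
DEFAULT_ORIENTATION = (1, -1, -1, -1, -1, -1)

#: Assessment timepoints and the two follow-up intervals.
TIMEPOINTS = ("baseline", "day7", "month3")
INTERVALS = ("day7", "month3")


@dataclass(frozen=True)
class BatteryDef:
    """An ordered battery of cognitive tests with per-test orientation.

    Parameters
    ----------
    tests:
        Ordered test names; used as CSV column stems ``score_<test>_<tp>``.
    orientation:
        Per-test +1 (higher = better) or -1 (higher = worse).
    """

    tests: tuple[str, ...] = DEFAULT_TESTS
    orientation: tuple[int, ...] = DEFAULT_ORIENTATION

    def __post_init__(self) -> None:
        if len(self.tests) != len(self.orientation):
            raise DataError("tests and orientation must have equal length")
        if len(self.tests) == 0:
            raise DataError("battery must contain at least one test")
        if len(set(self.tests)) != len(self.tests):
            raise DataError("duplicate test names in battery")
        if any(o not in (-1, 1) for o in self.orientation):
            raise DataError("orientation entries must be +1 or -1")

    @property
    def n_tests(self) -> int:
        return len(self.tests)

    def orientation_of(self, test: str) -> int:
        try:
            return self.orientation[self.tests.index(test)]
        except ValueError:
            raise DataError(f"unknown test {test!r}") from None

    def score_column(self, test: str, timepoint: str) -> str:
        if timepoint not in TIMEPOINTS:
            raise DataError(f"unknown timepoint {timepoint!r}")
        return f"score_{test}_{timepoint}"

    @classmethod
    def default(cls) -> "BatteryDef":
        return cls()

    @classmethod
    def from_yaml(cls, path) -> "BatteryDef":
        """Load a battery from a YAML file of ``{tests: [{name, orientation}]}``."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        try:
            entries = raw["tests"]
            names = tuple(e["name"] for e in entries)
            orient = tuple(int(e["orientation"]) for e in entries)
        except (KeyError, TypeError) as exc:
            raise DataError(f"malformed battery file {path}: {exc}") from exc
        return cls(tests=names, orientation=orient)

    def to_yaml(self, path) -> None:
        payload = {
            "tests": [
                {"name": t, "orientation": o}
                for t, o in zip(self.tests, self.orientation)
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)
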
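"""Long-format study table with a raw/log scale registry."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import DesignError

REQUIRED_COLUMNS = ["subject", "group", "timepoint", "outcome", "value"]
GROUPS = ("hypoxia", "normoxia")
TIMEPOINTS = ("Pre", "Post-0", "Post-1", "Post-2")
POST_TIMEPOINTS = ("Post-0", "Post-1", "Post-2")


@dataclass
class StudyDataset:
    """Rows of (subject, group, timepoint, outcome, value) plus outcome scales.

    The scale registry maps each outcome to ``"raw"`` (additive effects) or
    ``"log"`` (multiplicative effects, strictly positive values).
    """

    frame: pd.DataFrame
    scales: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DesignError(f"study table is missing columns: {missing}")
        bad_scale = {s for s in self.scales.values() if s not in ("raw", "log")}
        if bad_scale:
            raise DesignError(f"unknown scale labels: {sorted(bad_scale)}")

    def validate(self) -> "StudyDataset":
        g = self.frame.groupby("subject")["group"].nunique()
        multi = g[g > 1]
        if len(multi):
            raise DesignError(f"subjects in more than one group: {list(multi.index)}")
        unknown_groups = set(self.frame["group"]) - set(GROUPS)
        if unknown_groups:
            raise DesignError(f"unknown group labels: {sorted(unknown_groups)}")
        for outcome, scale in self.scales.items():
            if scale == "log":
                vals = self.frame.loc[self.frame["outcome"] == outcome, "value"]
                if (vals <= 0).any():
                    raise DesignError(f"log-scale outcome {outcome!r} has non-positive values")
        return self

    @property
    def outcomes(self) -> list[str]:
        return sorted(self.frame["outcome"].unique())

    def scale_of(self, outcome: str) -> str:
        return self.scales.get(outcome, "raw")

    def subset(self, outcome: str) -> pd.DataFrame:
        sub = self.frame[self.frame["outcome"] == outcome]
        if sub.empty:
            raise KeyError(f"outcome {outcome!r} not present in the study table")
        return sub.copy()

    def to_csv(self, path, scales_path=None) -> None:
        self.frame.to_csv(path, index=False, float_format="%.10g")
        if scales_path is not None:
            Path(scales_path).write_text(json.dumps(self.scales, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path, scales=None, scales_path=None) -> "StudyDataset":
        frame = pd.read_csv(path)
        if scales is None and scales_path is not None:
            scales = json.loads(Path(scales_path).read_text())
        return cls(frame=frame, scales=dict(scales or {}))
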
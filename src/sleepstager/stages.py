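"""Vigilance-stage labels shared across the package."""

from __future__ import annotations

import enum


class Stage(enum.Enum):
    """Rodent vigilance stage of one epoch.

    NREM: high-amplitude delta (0.5-4 Hz) EEG with low muscle tone.
    REM: low-amplitude theta (6-10 Hz) EEG with atonia (very low EMG).
    WAKE: mixed EEG with high, varying EMG.
    DIRTY: epoch excluded from staging (artifact / out-of-range power).
    """

    NREM = "N"
    REM = "R"
    WAKE = "W"
    DIRTY = "D"

    @classmethod
    def from_code(cls, code: str) -> "Stage":
        code = code.strip().upper()
        for stage in cls:
            if code in (stage.value, stage.name):
                return stage
        raise ValueError(f"unknown stage code: {code!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


SCOREABLE_STAGES = (Stage.NREM, Stage.REM, Stage.WAKE)
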
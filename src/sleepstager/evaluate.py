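"""Agreement metrics between an automated and a reference hypnogram.

Accuracy is the fraction of co-scored epochs on which the two hypnograms
agree.  Per-stage sensitivity of stage X is the fraction of reference-X
epochs the automated staging also calls X; specificity of X is the fraction
of reference-non-X epochs the automated staging also calls non-X.  Epochs
that either side marks DIRTY are excluded from all metrics and reported as a
separate count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import Hypnogram
from .stages import SCOREABLE_STAGES, Stage


class EvaluationError(Exception):
    pass


@dataclass
class StageMetrics:
    accuracy: float
    sensitivity: dict[Stage, float]   # NaN when the reference lacks the stage
    specificity: dict[Stage, float]
    confusion: pd.DataFrame           # reference rows x automated columns
    n_scored: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": {s.name: v for s, v in self.sensitivity.items()},
            "specificity": {s.name: v for s, v in self.specificity.items()},
            "n_scored": self.n_scored,
            "n_excluded": self.n_excluded,
            "confusion": {
                ref: {auto: int(c) for auto, c in row.items()}
                for ref, row in self.confusion.to_dict(orient="index").items()
            },
        }

    def summary(self) -> str:
        lines = [
            f"epochs scored: {self.n_scored} (excluded: {self.n_excluded})",
            f"accuracy: {self.accuracy:.4f}",
        ]
        for s in SCOREABLE_STAGES:
            sens, spec = self.sensitivity[s], self.specificity[s]
            sens_s = "NA" if np.isnan(sens) else f"{sens:.4f}"
            spec_s = "NA" if np.isnan(spec) else f"{spec:.4f}"
            lines.append(f"{s.name:5s} sensitivity {sens_s}  specificity {spec_s}")
        return "\n".join(lines)


def score(auto: Hypnogram, reference: Hypnogram) -> StageMetrics:
    """Score an automated hypnogram against a reference of equal length."""
    if len(auto) != len(reference):
        raise EvaluationError(
            f"hypnogram lengths differ: {len(auto)} vs {len(reference)}"
        )
    pairs = [
        (r, a)
        for a, r in zip(auto.stages, reference.stages)
        if a is not Stage.DIRTY and r is not Stage.DIRTY
    ]
    n_excluded = len(auto) - len(pairs)
    if not pairs:
        raise EvaluationError("no co-scored epochs (all dirty/unscored)")

    names = [s.name for s in SCOREABLE_STAGES]
    confusion = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for ref, aut in pairs:
        confusion.loc[ref.name, aut.name] += 1

    total = confusion.to_numpy().sum()
    accuracy = float(np.trace(confusion.to_numpy())) / total
    sensitivity: dict[Stage, float] = {}
    specificity: dict[Stage, float] = {}
    for s in SCOREABLE_STAGES:
        ref_x = confusion.loc[s.name].sum()
        sensitivity[s] = (
            float(confusion.loc[s.name, s.name]) / ref_x if ref_x else float("nan")
        )
        ref_nonx = total - ref_x
        auto_nonx_correct = (
            confusion.drop(index=s.name).to_numpy().sum()
            - confusion.drop(index=s.name)[s.name].sum()
        )
        specificity[s] = (
            float(auto_nonx_correct) / ref_nonx if ref_nonx else float("nan")
        )
    return StageMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        confusion=confusion,
        n_scored=int(total),
        n_excluded=n_excluded,
    )
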
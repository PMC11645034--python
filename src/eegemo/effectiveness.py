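"""Learning-effectiveness scoring from valence–arousal–dominance estimates.

The aggregate score is the weighted sum 0.3·V + 0.4·A + 0.3·D on the 0–9
rating scale: arousal — attention and mental activation — carries the
largest weight (0.4), while valence (interest/engagement) and dominance
(self-regulation) each carry 0.3.  Scores map onto four learning states:

=========  ============
score      state
=========  ============
[0, 3)     Ineffective
[3, 4)     Moderate
[4, 6)     Good
[6, 9]     Excellent
=========  ============

Shared interval endpoints are assigned upward (3 → Moderate, 4 → Good,
6 → Excellent) so the mapping is total and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .types import ConfigurationError, ValidationError, VADScoreRecord

WEIGHTS = {"V": 0.3, "A": 0.4, "D": 0.3}
STATES = ("Ineffective", "Moderate", "Good", "Excellent")
_BOUNDS = (3.0, 4.0, 6.0)


def score(V: float, A: float, D: float) -> float:
    """Weighted learning-effectiveness score; linear in each argument."""
    for name, v in (("V", V), ("A", A), ("D", D)):
        if not 0 <= v <= 9:
            raise ValidationError(f"{name}={v} outside the 0–9 rating range")
    return WEIGHTS["V"] * V + WEIGHTS["A"] * A + WEIGHTS["D"] * D


def classify_state(s: float) -> str:
    """Map a score in [0, 9] to its learning state (boundaries go upward)."""
    if not 0 <= s <= 9:
        raise ValidationError(f"score {s} outside [0, 9]")
    for bound, state in zip(_BOUNDS, STATES):
        if s < bound:
            return state
    return STATES[3]


@dataclass
class StreamReport:
    records: list[VADScoreRecord]
    mean_score: float | None
    fraction_above_5: float | None
    state_dwell: dict[str, int] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"window": r.window, "V": r.V, "A": r.A, "D": r.D, "score": r.score, "state": r.state}
                for r in self.records
            ]
        )

    def summary_json(self) -> str:
        return json.dumps(
            {
                "n_windows": len(self.records),
                "mean_score": self.mean_score,
                "fraction_above_5": self.fraction_above_5,
                "state_dwell": self.state_dwell,
            },
            sort_keys=True,
        )


def stream_scores(vad_sequence) -> StreamReport:
    """Score a (n, 3) VAD sequence window by window.

    Returns one record per window in order plus summary statistics (mean
    score, fraction of windows above 5, per-state dwell counts).  An empty
    input yields an empty report (a warning is the caller's concern).
    """
    vad = np.asarray(vad_sequence, dtype=np.float64)
    if vad.size == 0:
        return StreamReport(records=[], mean_score=None, fraction_above_5=None)
    if vad.ndim != 2 or vad.shape[1] != 3:
        raise ValidationError(f"VAD sequence must be (n, 3); got {vad.shape}")
    records = []
    dwell = {s: 0 for s in STATES}
    for i, (v, a, d) in enumerate(vad):
        s = score(v, a, d)
        st = classify_state(s)
        dwell[st] += 1
        records.append(VADScoreRecord(window=i, V=float(v), A=float(a), D=float(d), score=s, state=st))
    scores = np.array([r.score for r in records])
    return StreamReport(
        records=records,
        mean_score=float(scores.mean()),
        fraction_above_5=float(np.mean(scores > 5)),
        state_dwell=dwell,
    )


def predict_vad(models: dict, sequences: np.ndarray) -> np.ndarray:
    """Per-sequence VAD estimates from three binary classifiers.

    ``models`` maps dimension name ("V", "A", "D") to a trained binary
    model; the positive-class probability is mapped linearly to the 0–9
    rating scale (p × 9).  Deterministic in evaluation mode.
    """
    for dim in ("V", "A", "D"):
        if dim not in models:
            raise ConfigurationError(f"missing model for dimension {dim!r}")
    cols = []
    for dim in ("V", "A", "D"):
        proba = models[dim].predict_proba(sequences)
        if proba.shape[1] != 2:
            raise ConfigurationError(f"model for {dim!r} is not binary (got {proba.shape[1]} classes)")
        cols.append(proba[:, 1] * 9.0)
    return np.column_stack(cols)
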
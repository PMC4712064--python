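"""Region-of-interest extraction: baseline and evoked windows per block.

Seven window conditions are supported, named ``<baseline s>-<evoked s>`` with
an ``-f``/``-l`` suffix selecting the first or last part of a 20 s block for
the 10 s evoked windows.  Baseline windows are cut from the start of the
rest pause that precedes each block (the only unstimulated epoch in the
protocol), so every stimulus block contributes one evoked and one baseline
segment per channel.

Windows are half-open ``[t0, t0 + len)`` in seconds and converted to 0-based
sample indices by flooring ``t * fs``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BASELINE, BlockSchedule, EmgRecording

__all__ = [
    "WindowCondition",
    "WINDOW_CONDITIONS",
    "CONDITION_LABELS",
    "LabeledSegment",
    "extract_segments",
    "segment_manifest",
]


@dataclass(frozen=True)
class WindowCondition:
    """Baseline/evoked window lengths and evoked alignment for one condition."""

    label: str
    baseline_len: float
    evoked_len: float
    evoked_align: str  # "first" | "last"

    def __post_init__(self) -> None:
        if self.evoked_align not in ("first", "last"):
            raise ValueError("evoked_align must be 'first' or 'last'")


WINDOW_CONDITIONS: dict[str, WindowCondition] = {
    c.label: c
    for c in (
        WindowCondition("1-1", 1.0, 1.0, "first"),
        WindowCondition("1-2", 1.0, 2.0, "first"),
        WindowCondition("1-10-f", 1.0, 10.0, "first"),
        WindowCondition("1-10-l", 1.0, 10.0, "last"),
        WindowCondition("2-2", 2.0, 2.0, "first"),
        WindowCondition("2-10-f", 2.0, 10.0, "first"),
        WindowCondition("2-10-l", 2.0, 10.0, "last"),
    )
}

CONDITION_LABELS = tuple(WINDOW_CONDITIONS)


@dataclass
class LabeledSegment:
    """One windowed channel trace with its class label and provenance."""

    subject: str
    channel: str
    label: str  # affect category or BASELINE
    samples: np.ndarray
    block_index: int
    start_s: float
    end_s: float
    condition: str


def _cut(x: np.ndarray, t0: float, length: float, fs: float) -> tuple[np.ndarray, float, float]:
    i0 = int(np.floor(t0 * fs))
    i1 = i0 + int(round(length * fs))
    if i0 < 0 or i1 > len(x):
        raise ValueError(
            f"window [{t0:.3f}, {t0 + length:.3f}) s exceeds recording bounds"
        )
    return x[i0:i1], t0, t0 + length


def extract_segments(
    rec: EmgRecording,
    schedule: BlockSchedule,
    cond: WindowCondition,
    subject: str = "S000",
) -> list[LabeledSegment]:
    """One evoked + one baseline segment per block per channel.

    Evoked windows take the first ``evoked_len`` seconds of each block
    (``align='first'``) or the last (``align='last'``); baseline windows take
    the first ``baseline_len`` seconds of the pause preceding each block.
    """
    fs = rec.sampling_rate
    if schedule.total_duration > rec.duration + 1e-9:
        raise ValueError("schedule extends beyond the recording")
    segments: list[LabeledSegment] = []
    pauses = schedule.pause_epochs()
    for k, block in enumerate(schedule.blocks):
        if cond.evoked_align == "first":
            t0 = block.onset
        else:
            t0 = block.end - cond.evoked_len
        for ch, x in rec.channels.items():
            cut, s0, s1 = _cut(x, t0, cond.evoked_len, fs)
            segments.append(
                LabeledSegment(subject, ch, block.category, cut, k, s0, s1, cond.label)
            )
        p0, _ = pauses[k]
        for ch, x in rec.channels.items():
            cut, s0, s1 = _cut(x, p0, cond.baseline_len, fs)
            segments.append(
                LabeledSegment(subject, ch, BASELINE, cut, k, s0, s1, cond.label)
            )
    return segments


def segment_manifest(segments: list[LabeledSegment]) -> pd.DataFrame:
    """Tabular manifest (no samples) suitable for CSV export."""
    return pd.DataFrame(
        {
            "subject": [s.subject for s in segments],
            "channel": [s.channel for s in segments],
            "class": [s.label for s in segments],
            "condition": [s.condition for s in segments],
            "start_s": [s.start_s for s in segments],
            "end_s": [s.end_s for s in segments],
            "block_index": [s.block_index for s in segments],
        }
    )
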
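"""Beat-level preprocessing: RR filtering, windowing, rhythm labeling, SQI gate.

The workflow mirrors how annotated Holter data are prepared for
segment-level AF classification: rhythm-pure RR episodes are extracted
from the beat annotations, intervals longer than 2 s (missed beats,
pauses) are removed, each episode is cut into non-overlapping
fixed-length windows (30 or 12 beats), and windows overlapping ECG
stretches judged noisy by the 2-of-5 signal-quality rule are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import InvalidInputError, RRSegment

__all__ = [
    "SqiRecord",
    "SqiThresholds",
    "RhythmEpisode",
    "FilterResult",
    "filter_rr",
    "segment_rr",
    "label_segments",
    "extract_and_segment",
    "is_noisy",
    "apply_sqi_gate",
]

EPISODE_RHYTHMS = ("AF", "N", "AFL", "J")
SQI_WINDOW_S = 10.0


@dataclass(frozen=True)
class SqiRecord:
    """Five per-10-s ECG signal-quality indices.

    bsqi: agreement of two QRS detectors (0..1); tsqi: beat-morphology
    consistency (0 allowed); isqi: RR-interval abnormality index (0
    allowed); psqi: 5-25 Hz / 5-50 Hz power ratio (0..1); ksqi: signal
    kurtosis.  ``t_start_s`` anchors the 10-s window in recording time.
    """

    bsqi: float
    tsqi: float
    isqi: float
    psqi: float
    ksqi: float
    t_start_s: float = 0.0

    def __post_init__(self) -> None:
        for name in ("bsqi", "tsqi", "isqi", "psqi", "ksqi", "t_start_s"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidInputError(f"{name} must be finite")


@dataclass(frozen=True)
class SqiThresholds:
    """Cut-offs of the five noise predicates (defaults as published)."""

    bsqi_lt: float = 0.5
    tsqi_eq: float = 0.0
    isqi_eq: float = 0.0
    psqi_lt: float = 0.8
    ksqi_lt: float = 3.0
    min_criteria: int = 2


@dataclass(frozen=True)
class RhythmEpisode:
    """A run of beats sharing one manually annotated rhythm."""

    start_beat: int
    end_beat: int  # exclusive
    rhythm: str

    def __post_init__(self) -> None:
        if self.start_beat >= self.end_beat:
            raise InvalidInputError(
                f"episode must satisfy start_beat < end_beat, got [{self.start_beat}, {self.end_beat})"
            )
        if self.rhythm not in EPISODE_RHYTHMS:
            raise InvalidInputError(
                f"unknown rhythm code {self.rhythm!r}; expected one of {EPISODE_RHYTHMS}"
            )

    @property
    def n_beats(self) -> int:
        return self.end_beat - self.start_beat


@dataclass
class FilterResult:
    intervals: np.ndarray
    n_removed: int
    kept_mask: np.ndarray  # over the input positions


def filter_rr(intervals, max_rr: float = 2.0) -> FilterResult:
    """Drop implausibly long RR intervals (missed beats), keeping ``<= max_rr``.

    An empty result is returned as such (flagged by ``intervals.size == 0``),
    never raised.
    """
    if max_rr <= 0:
        raise InvalidInputError(f"max_rr must be > 0, got {max_rr}")
    x = np.asarray(intervals, float)
    keep = x <= max_rr
    return FilterResult(intervals=x[keep], n_removed=int((~keep).sum()), kept_mask=keep)


def segment_rr(
    intervals, window: int, start_beat: int = 0, label: str = "UNKNOWN"
) -> tuple[list[RRSegment], int]:
    """Cut a series into non-overlapping ``window``-beat segments.

    Returns the segments and the count of trailing intervals dropped.
    Beat bookkeeping: ``window * n_segments + n_dropped == len(intervals)``.
    """
    if window < 4:
        raise InvalidInputError(f"window must be >= 4 beats, got {window}")
    x = np.asarray(intervals, float)
    n_full = x.size // window
    segments = [
        RRSegment(x[k * window : (k + 1) * window], label=label,
                  start_beat=start_beat + k * window)
        for k in range(n_full)
    ]
    return segments, int(x.size - n_full * window)


def label_segments(
    segments: Sequence[RRSegment],
    episodes: Sequence[RhythmEpisode],
    task: str = "AF_vs_nonAF",
) -> list[RRSegment]:
    """Attach task labels to segments from the episode annotation.

    Each segment must lie wholly inside one episode (segmentation is done
    per episode, so windows never straddle a rhythm change).  Under
    ``AF_vs_N`` the AFL and J segments are excluded; under
    ``AF_vs_nonAF`` the N, AFL and J rhythms are merged into NONAF.
    """
    if task not in ("AF_vs_N", "AF_vs_nonAF"):
        raise InvalidInputError(f"unknown task {task!r}")
    eps = sorted(episodes, key=lambda e: e.start_beat)
    for a, b in zip(eps, eps[1:]):
        if a.end_beat > b.start_beat:
            raise InvalidInputError(
                f"episodes overlap: [{a.start_beat},{a.end_beat}) and [{b.start_beat},{b.end_beat})"
            )
    out: list[RRSegment] = []
    for seg in segments:
        lo, hi = seg.start_beat, seg.start_beat + seg.n_beats
        home = [e for e in eps if e.start_beat <= lo and hi <= e.end_beat]
        if not home:
            raise InvalidInputError(
                f"segment at beats [{lo},{hi}) is not contained in a single episode"
            )
        rhythm = home[0].rhythm
        if rhythm == "AF":
            label = "AF"
        elif task == "AF_vs_N":
            if rhythm != "N":
                continue  # AFL/J excluded from this task
            label = "N"
        else:
            label = "NONAF"
        out.append(RRSegment(seg.intervals, label=label, start_beat=seg.start_beat,
                             quality_flag=seg.quality_flag))
    return out


def extract_and_segment(
    intervals,
    episodes: Sequence[RhythmEpisode],
    window: int,
    task: str = "AF_vs_nonAF",
    max_rr: float = 2.0,
) -> tuple[list[RRSegment], dict[str, int]]:
    """Episode-wise filter + window + label pipeline.

    Within each episode the ``<= max_rr`` filter is applied first; a
    removed interval breaks template continuity, so windowing restarts
    after each gap rather than splicing across it.  Returns labeled
    segments and a bookkeeping dict (removed intervals, dropped
    remainders).
    """
    x = np.asarray(intervals, float)
    n_removed = 0
    n_dropped = 0
    labeled: list[RRSegment] = []
    for ep in episodes:
        if ep.end_beat > x.size:
            raise InvalidInputError(
                f"episode [{ep.start_beat},{ep.end_beat}) exceeds series length {x.size}"
            )
        chunk = x[ep.start_beat : ep.end_beat]
        keep = chunk <= max_rr
        n_removed += int((~keep).sum())
        # contiguous runs of kept intervals; a gap restarts the window
        boundaries = np.flatnonzero(~keep)
        run_edges = np.concatenate([[-1], boundaries, [chunk.size]])
        segs: list[RRSegment] = []
        for lo, hi in zip(run_edges[:-1] + 1, run_edges[1:]):
            if hi - lo < window:
                n_dropped += max(hi - lo, 0)
                continue
            run_segs, dropped = segment_rr(
                chunk[lo:hi], window, start_beat=ep.start_beat + lo
            )
            n_dropped += dropped
            segs.extend(run_segs)
        labeled.extend(label_segments(segs, [ep], task=task))
    return labeled, {"n_removed": n_removed, "n_dropped": n_dropped}


def is_noisy(sqi: SqiRecord, thresholds: SqiThresholds | None = None) -> bool:
    """2-of-5 noise rule on one 10-s window.

    The window is noisy iff at least ``min_criteria`` of: bSQI < 0.5,
    tSQI = 0, iSQI = 0, pSQI < 0.8, kSQI < 3.
    """
    t = thresholds or SqiThresholds()
    hits = (
        int(sqi.bsqi < t.bsqi_lt)
        + int(sqi.tsqi == t.tsqi_eq)
        + int(sqi.isqi == t.isqi_eq)
        + int(sqi.psqi < t.psqi_lt)
        + int(sqi.ksqi < t.ksqi_lt)
    )
    return hits >= t.min_criteria


def apply_sqi_gate(
    segments: Sequence[RRSegment],
    beat_times_s,
    sqi_records: Sequence[SqiRecord],
    thresholds: SqiThresholds | None = None,
    mode: str = "any",
) -> list[RRSegment]:
    """Flag segments overlapping noisy 10-s windows.

    ``beat_times_s[k]`` is the onset time of beat ``k`` in the source
    series (the RR series is beat-indexed, the SQI windows time-indexed).
    ``mode='any'`` flags a segment if any overlapping window is noisy
    (conservative default); ``mode='majority'`` if more than half are.
    """
    if mode not in ("any", "majority"):
        raise InvalidInputError(f"unknown gate mode {mode!r}")
    t = np.asarray(beat_times_s, float)
    noisy = [
        (rec.t_start_s, rec.t_start_s + SQI_WINDOW_S, is_noisy(rec, thresholds))
        for rec in sqi_records
    ]
    out: list[RRSegment] = []
    for seg in segments:
        lo_i = seg.start_beat
        hi_i = seg.start_beat + seg.n_beats
        if hi_i >= t.size:
            raise InvalidInputError("beat_times_s shorter than the segmented series")
        t_lo, t_hi = t[lo_i], t[hi_i]
        overlapping = [bad for (w_lo, w_hi, bad) in noisy if w_lo < t_hi and w_hi > t_lo]
        if not overlapping:
            flagged = False
        elif mode == "any":
            flagged = any(overlapping)
        else:
            flagged = sum(overlapping) * 2 > len(overlapping)
        out.append(RRSegment(seg.intervals, label=seg.label,
                             start_beat=seg.start_beat, quality_flag=flagged))
    return out
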
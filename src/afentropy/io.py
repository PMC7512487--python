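"""File I/O, run configuration and the end-to-end pipeline.

One canonical RR CSV dialect is used throughout: a header row, a
``rr_s`` column of interval lengths in seconds, and an optional
``label`` column.  Beat-annotation exports (sample index + beat code at
a stated sampling frequency) can be converted to RR series.  Per-segment
results are written as CSV with one row per window.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, evaluate, synth
from .core import EntropyParams, InvalidInputError, RRSegment
from .preprocess import RhythmEpisode, SqiRecord, segment_rr

__all__ = [
    "RunConfig",
    "read_rr_csv",
    "write_rr_csv",
    "read_beat_annotations",
    "read_episodes",
    "read_sqi",
    "grid_search_w",
    "compute_segment_table",
    "segment_table_from_intervals",
    "evaluate_scores",
    "run_pipeline",
    "time_measures",
]

log = logging.getLogger("afentropy")

RESULT_COLUMNS = [
    "segment_id", "start_beat", "n_beats", "rrmean_s",
    "sampen", "fuzzymen", "cosen", "entropy_af",
    "r_used_af", "r_used_cosen", "quality_flag", "label",
]


@dataclass
class RunConfig:
    """Everything a full synth -> compute -> evaluate run needs.

    Round-trips losslessly through YAML (:meth:`to_file` /
    :meth:`from_file`); every field has a default, and the resolved
    values are logged when the pipeline runs.
    """

    input: str | None = None
    out: str = "afentropy_results.csv"
    window: int = 30
    measures: tuple[str, ...] = core.MEASURES
    m_af: int = 2
    m_cosen: int = 1
    m_comparator: int = 2
    n: float = 2.0
    w: float = 1.0
    r_init: float = 0.05
    r_step: float = 0.05
    min_avg_matches: float = 5.0
    epsilon: float = 1e-10
    task: str = "AF_vs_nonAF"
    operating: str = "youden"
    n_af: int = 500
    n_nsr: int = 500
    seed: int = 0
    log_level: str = "INFO"

    def af_params(self) -> EntropyParams:
        return EntropyParams(m=self.m_af, n=self.n, r_init=self.r_init,
                             r_step=self.r_step, min_avg_matches=self.min_avg_matches,
                             w=self.w, epsilon=self.epsilon)

    def comparator_params(self) -> EntropyParams:
        return EntropyParams(m=self.m_comparator, n=self.n, r_init=self.r_init,
                             r_step=self.r_step, min_avg_matches=self.min_avg_matches,
                             w=self.w, epsilon=self.epsilon)

    def cosen_params(self) -> EntropyParams:
        return EntropyParams(m=self.m_cosen, n=self.n, r_init=self.r_init,
                             r_step=self.r_step, min_avg_matches=self.min_avg_matches,
                             w=self.w, epsilon=self.epsilon)

    def to_file(self, path) -> None:
        d = dataclasses.asdict(self)
        d["measures"] = list(self.measures)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _detect_sep(path: Path) -> str:
    """Tab- or comma-separated, decided from the header line.

    (Automatic sniffing misfires on single-column files.)
    """
    try:
        with open(path) as fh:
            header = fh.readline()
    except FileNotFoundError:
        raise InvalidInputError(f"no such file: {path}") from None
    return "\t" if "\t" in header else ","


def read_rr_csv(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read the canonical RR CSV/TSV (column ``rr_s``, optional ``label``).

    Malformed numeric rows are rejected with their line numbers (header
    is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_detect_sep(path))
    except FileNotFoundError:
        raise InvalidInputError(f"no such file: {path}") from None
    except pd.errors.ParserError as exc:
        raise InvalidInputError(f"{path}: unparseable CSV ({exc})") from None
    if "rr_s" not in df.columns:
        raise InvalidInputError(f"{path}: missing required column 'rr_s' (found {list(df.columns)})")
    rr = pd.to_numeric(df["rr_s"], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(rr))
    if bad.size:
        lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise InvalidInputError(f"{path}: non-numeric rr_s value(s) at line(s) {lines}")
    labels = df["label"].astype(str).to_numpy() if "label" in df.columns else None
    return rr, labels


def write_rr_csv(path, intervals, labels=None) -> None:
    df = pd.DataFrame({"rr_s": np.asarray(intervals, float)})
    if labels is not None:
        df["label"] = labels
    df.to_csv(path, index=False)


def read_beat_annotations(path, fs: float) -> np.ndarray:
    """RR series (seconds) from a beat-annotation export.

    Accepts either a headed CSV with a ``sample_index`` column or the
    whitespace-separated annotation-dump dialect ``time  sample  code ...``
    (sample index in the second field).  ``fs`` is the ECG sampling
    frequency in Hz; ``RR_k = (sample_{k+1} - sample_k) / fs``.
    """
    if fs <= 0:
        raise InvalidInputError(f"sampling frequency must be > 0, got {fs}")
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such file: {path}")
    text = path.read_text().strip()
    if not text:
        return np.array([])
    first = text.splitlines()[0]
    if "sample_index" in first:
        df = pd.read_csv(path, sep=_detect_sep(path))
        samples = pd.to_numeric(df["sample_index"], errors="coerce").to_numpy(float)
    else:
        rows = [ln.split() for ln in text.splitlines() if ln.strip()]
        try:
            samples = np.array([float(r[1]) for r in rows])
        except (IndexError, ValueError) as exc:
            raise InvalidInputError(f"{path}: unrecognised annotation format ({exc})") from None
    if np.any(~np.isfinite(samples)):
        raise InvalidInputError(f"{path}: non-numeric sample index")
    if samples.size < 2:
        return np.array([])
    if np.any(np.diff(samples) <= 0):
        raise InvalidInputError(f"{path}: sample indices must be strictly increasing")
    return np.diff(samples) / fs


def read_episodes(path) -> list[RhythmEpisode]:
    """Rhythm-episode file: CSV with columns start_beat, end_beat, rhythm."""
    df = pd.read_csv(Path(path), sep=_detect_sep(Path(path)))
    missing = {"start_beat", "end_beat", "rhythm"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")
    return [RhythmEpisode(int(r.start_beat), int(r.end_beat), str(r.rhythm))
            for r in df.itertuples()]


def read_sqi(path) -> list[SqiRecord]:
    """Per-10-s SQI file: CSV with columns t_start_s, bsqi, tsqi, isqi, psqi, ksqi."""
    df = pd.read_csv(Path(path), sep=_detect_sep(Path(path)))
    cols = {"t_start_s", "bsqi", "tsqi", "isqi", "psqi", "ksqi"}
    missing = cols - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing column(s) {sorted(missing)}")
    return [SqiRecord(bsqi=r.bsqi, tsqi=r.tsqi, isqi=r.isqi, psqi=r.psqi,
                      ksqi=r.ksqi, t_start_s=r.t_start_s) for r in df.itertuples()]


def grid_search_w(segments: list[RRSegment], w_grid=None,
                  params: EntropyParams | None = None) -> tuple[float, dict[float, float]]:
    """Training-AUC grid search for the heart-rate weight ``w``.

    The conditional part of the AF entropy does not depend on ``w``, so
    it is computed once per segment and the ``- w * ln(mean RR)`` term
    swept over the grid (default 0 to 2 in steps of 0.1).  Returns the
    AUC-maximizing ``w`` (ties toward the smaller value) and the AUC per
    grid point.  The tuned value is a training-set quantity; apply it
    unchanged to held-out data.
    """
    if w_grid is None:
        w_grid = np.round(np.arange(0.0, 2.0 + 1e-9, 0.1), 10)
    base = params or EntropyParams(m=2)
    p0 = replace(base, w=0.0) if base.w != 0.0 else base
    labels = np.array([s.label for s in segments])
    core_part = np.array([core.entropy_af(s, p0).value for s in segments])
    log_rrm = np.log([s.mean_rr for s in segments])
    aucs = {float(w): evaluate.roc(core_part - w * log_rrm, labels).auc for w in w_grid}
    best = max(aucs, key=lambda w: (aucs[w], -w))
    return best, aucs


# ---------------------------------------------------------------------------
# Segment-table computation
# ---------------------------------------------------------------------------


def compute_segment_table(segments: list[RRSegment], config: RunConfig | None = None) -> pd.DataFrame:
    """Per-segment entropy table (one row per window, all measures)."""
    config = config or RunConfig()
    af_p = config.af_params()
    cmp_p = config.comparator_params()
    cos_p = config.cosen_params()
    rows = []
    for k, seg in enumerate(segments):
        res = core.compute_all(seg, af_p, cmp_p, cos_p, measures=config.measures)
        row = {
            "segment_id": k,
            "start_beat": seg.start_beat,
            "n_beats": seg.n_beats,
            "rrmean_s": seg.mean_rr,
            "sampen": np.nan, "fuzzymen": np.nan, "cosen": np.nan, "entropy_af": np.nan,
            "r_used_af": np.nan, "r_used_cosen": np.nan,
            "quality_flag": seg.quality_flag,
            "label": seg.label,
        }
        for name, r in res.items():
            row[name] = r.value
        if "entropy_af" in res:
            row["r_used_af"] = res["entropy_af"].r_used
        if "cosen" in res:
            row["r_used_cosen"] = res["cosen"].r_used
        rows.append(row)
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def segment_table_from_intervals(rr, config: RunConfig, labels=None) -> pd.DataFrame:
    """Window a raw RR series and compute the entropy table.

    If per-beat ``labels`` are given, each window takes the label of its
    beats when they agree and is dropped otherwise (windows are expected
    to be rhythm-pure).
    """
    segments, n_dropped = segment_rr(rr, config.window)
    if labels is not None:
        labels = np.asarray(labels)
        kept = []
        for seg in segments:
            lab = labels[seg.start_beat : seg.start_beat + seg.n_beats]
            uniq = set(lab.tolist())
            if len(uniq) == 1:
                kept.append(RRSegment(seg.intervals, label=uniq.pop(),
                                      start_beat=seg.start_beat))
        segments = kept
    log.info("windowed %d segments of %d beats (%d trailing intervals dropped)",
             len(segments), config.window, n_dropped)
    return compute_segment_table(segments, config)


def evaluate_scores(table: pd.DataFrame, config: RunConfig,
                    thresholds_in: dict[str, float] | None = None) -> pd.DataFrame:
    """Per-measure ROC/operating-point report from a segment table.

    Rows mirror the standard report layout: cut-point c, J, Se, Sp, Acc,
    PPV, NPV, Err (percentages), plus AUC and the dropped-segment count.
    With ``thresholds_in``, saved cut-points are applied unchanged
    (transfer protocol) instead of being re-derived.
    """
    rows = []
    usable = table[~table["quality_flag"].astype(bool)]
    labels = usable["label"].to_numpy()
    for measure in config.measures:
        scores = usable[measure].to_numpy(float)
        curve = evaluate.roc(scores, labels)
        if thresholds_in and measure in thresholds_in:
            c = float(thresholds_in[measure])
            j = float("nan")
        elif config.operating == "youden":
            c, j = evaluate.youden_optimal(curve)
        elif config.operating in ("se99", "sp99"):
            cp = evaluate.cutpoint_at(curve, "Se" if config.operating == "se99" else "Sp", 0.99)
            c, j = cp.threshold, cp.se + cp.sp - 1.0
        else:
            raise InvalidInputError(f"unknown operating mode {config.operating!r}")
        finite = np.isfinite(scores)
        counts = evaluate.confusion_at(scores[finite], labels[finite], c, curve.orientation)
        mets = evaluate.metrics(counts)
        if thresholds_in and measure in thresholds_in:
            j = mets["Se"] + mets["Sp"] - 1.0
        rows.append({
            "measure": measure,
            "auc_pct": 100.0 * curve.auc,
            "c": c,
            "J_pct": 100.0 * j,
            **{f"{k}_pct": 100.0 * v for k, v in mets.items()},
            "orientation": curve.orientation,
            "n_dropped_nonfinite": curve.n_dropped,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Full workflow: load or synthesise RR data, compute, evaluate.

    Returns a summary dict with the segment table, the evaluation report
    and the resolved configuration; writes the per-segment CSV to
    ``config.out`` and the report next to it.  Deterministic for a fixed
    seed.
    """
    logging.basicConfig(level=config.log_level)
    log.info("run configuration: %s", dataclasses.asdict(config))
    if config.input is None:
        segments = synth.gen_labeled_dataset(
            config.n_af, config.n_nsr, window=config.window, seed=config.seed)
        table = compute_segment_table(segments, config)
    else:
        rr, labels = read_rr_csv(config.input)
        table = segment_table_from_intervals(rr, config, labels)
    report = evaluate_scores(table, config)
    out = Path(config.out)
    table.to_csv(out, index=False)
    report_path = out.with_name(out.stem + "_report.csv")
    report.to_csv(report_path, index=False)
    log.info("wrote %s and %s", out, report_path)
    return {"table": table, "report": report, "config": config,
            "out": str(out), "report_out": str(report_path)}


def time_measures(segments: list[RRSegment], config: RunConfig | None = None) -> dict[str, float]:
    """Mean per-segment wall time (ms) of each measure; informational only."""
    config = config or RunConfig()
    af_p, cmp_p, cos_p = config.af_params(), config.comparator_params(), config.cosen_params()
    out = {}
    for name in config.measures:
        t0 = time.perf_counter()
        for seg in segments:
            core.compute_all(seg, af_p, cmp_p, cos_p, measures=[name])
        out[name] = 1e3 * (time.perf_counter() - t0) / max(len(segments), 1)
    return out
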
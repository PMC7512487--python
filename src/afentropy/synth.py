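"""Synthetic RR-interval generators for AF-like and sinus-rhythm-like series.

These generators provide controlled ground truth for testing the entropy
measures and the evaluation pipeline without any recorded data:

* AF-like series: short mean RR (fast ventricular response) with large,
  serially uncorrelated beat-to-beat variability -- modelled as i.i.d.
  log-normal intervals with a requested mean and coefficient of
  variation.  This captures the near-random irregularity of AF without
  modelling AV-node physiology.
* NSR-like series: longer mean RR with small variability plus a slow
  sinusoidal (respiratory sinus arrhythmia) modulation, so the null
  class is regular-but-not-constant.

Generated intervals are clipped to the physiologically plausible band
(0.25 s, 2.0 s); the upper bound mirrors the 2-s preprocessing filter.
Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import InvalidInputError, RRSegment

__all__ = [
    "SynthConfig",
    "SynthResult",
    "AF_DEFAULTS",
    "NSR_DEFAULTS",
    "gen_af_rr",
    "gen_nsr_rr",
    "gen_shuffled_nsr_rr",
    "gen_labeled_dataset",
]

CLIP_LO_S = 0.25
CLIP_HI_S = 2.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic RR series.

    ``dispersion`` is the coefficient of variation for the AF model and
    the Gaussian SD in seconds for the NSR model.  ``resp_freq`` /
    ``resp_depth`` shape the respiratory modulation (NSR only).
    """

    n_beats: int = 30
    mean_rr: float = 0.85
    dispersion: float = 0.03
    resp_freq: float = 0.25
    resp_depth: float = 0.04
    seed: int | None = None
    class_label: str = "NONAF"

    def __post_init__(self) -> None:
        if self.n_beats < 12:
            raise InvalidInputError(f"n_beats must be >= 12, got {self.n_beats}")
        if self.mean_rr <= 0:
            raise InvalidInputError(f"mean_rr must be > 0, got {self.mean_rr}")
        if self.dispersion < 0 or self.resp_depth < 0 or self.resp_freq < 0:
            raise InvalidInputError("dispersion, resp_freq and resp_depth must be >= 0")
        if self.class_label not in ("AF", "NONAF"):
            raise InvalidInputError(f"class_label must be AF or NONAF, got {self.class_label!r}")


# Study conditions: a fast, highly irregular AF ventricular response
# (mean RR 0.6 s ~ 100 bpm, CV 25%) against a resting sinus rhythm
# (mean RR 0.85 s ~ 70 bpm, SD 30 ms, respiratory modulation at 0.25 Hz
# with 40 ms depth).
AF_DEFAULTS = SynthConfig(n_beats=30, mean_rr=0.6, dispersion=0.25, class_label="AF")
NSR_DEFAULTS = SynthConfig(n_beats=30, mean_rr=0.85, dispersion=0.03,
                           resp_freq=0.25, resp_depth=0.04, class_label="NONAF")


@dataclass(frozen=True)
class SynthResult:
    intervals: np.ndarray
    n_clipped: int
    config: SynthConfig


def _rng(config: SynthConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def _clip(raw: np.ndarray, config: SynthConfig) -> SynthResult:
    clipped = np.clip(raw, CLIP_LO_S, CLIP_HI_S)
    return SynthResult(clipped, int((clipped != raw).sum()), config)


def gen_af_rr(config: SynthConfig | None = None,
              rng: np.random.Generator | None = None) -> SynthResult:
    """I.i.d. log-normal RR series with the configured mean and CV.

    Log-normal moment matching: ``sigma^2 = ln(1 + CV^2)``,
    ``mu = ln(mean) - sigma^2 / 2``.  ``CV = 0`` gives a constant series.
    Lag-1 autocorrelation is zero by construction.
    """
    config = config or AF_DEFAULTS
    g = _rng(config, rng)
    cv = config.dispersion
    if cv == 0:
        raw = np.full(config.n_beats, config.mean_rr)
    else:
        sigma2 = np.log1p(cv * cv)
        mu = np.log(config.mean_rr) - sigma2 / 2.0
        raw = g.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=config.n_beats)
    return _clip(raw, config)


def gen_nsr_rr(config: SynthConfig | None = None,
               rng: np.random.Generator | None = None) -> SynthResult:
    """Sinus-rhythm-like RR series: mean + respiratory sinusoid + noise.

    ``rr_k = mean_rr + resp_depth * sin(2 pi resp_freq t_k) + N(0, SD)``
    with ``t_k`` the cumulative beat time, so the modulation is periodic
    in real time, not in beat index.
    """
    config = config or NSR_DEFAULTS
    g = _rng(config, rng)
    noise = g.normal(0.0, config.dispersion, size=config.n_beats) if config.dispersion > 0 \
        else np.zeros(config.n_beats)
    raw = np.empty(config.n_beats)
    t = 0.0
    for k in range(config.n_beats):
        raw[k] = config.mean_rr + config.resp_depth * np.sin(
            2.0 * np.pi * config.resp_freq * t) + noise[k]
        t += raw[k]
    return _clip(raw, config)


def gen_shuffled_nsr_rr(config: SynthConfig | None = None,
                        rng: np.random.Generator | None = None) -> SynthResult:
    """Second null model: an NSR series with its serial order destroyed.

    Same marginal distribution as :func:`gen_nsr_rr` but shuffled, which
    removes the respiratory autocorrelation while keeping mean and SD.
    """
    config = config or NSR_DEFAULTS
    g = _rng(config, rng)
    res = gen_nsr_rr(config, g)
    return SynthResult(g.permutation(res.intervals), res.n_clipped, config)


def gen_labeled_dataset(
    n_af: int,
    n_nsr: int,
    window: int = 30,
    seed: int = 0,
    af_config: SynthConfig | None = None,
    nsr_config: SynthConfig | None = None,
) -> list[RRSegment]:
    """Independent labeled segments: ``n_af`` AF-like + ``n_nsr`` NSR-like.

    Each segment is drawn from its own independent random stream spawned
    from ``seed``, so the dataset is reproducible and segments are
    exchangeable within class.
    """
    if n_af < 1 or n_nsr < 1:
        raise InvalidInputError("n_af and n_nsr must be >= 1")
    af_config = replace(af_config or AF_DEFAULTS, n_beats=window)
    nsr_config = replace(nsr_config or NSR_DEFAULTS, n_beats=window)
    streams = np.random.SeedSequence(seed).spawn(n_af + n_nsr)
    segments: list[RRSegment] = []
    for k in range(n_af):
        res = gen_af_rr(af_config, np.random.default_rng(streams[k]))
        segments.append(RRSegment(res.intervals, label="AF", start_beat=k * window))
    for k in range(n_nsr):
        res = gen_nsr_rr(nsr_config, np.random.default_rng(streams[n_af + k]))
        segments.append(RRSegment(res.intervals, label="NONAF",
                                  start_beat=(n_af + k) * window))
    return segments
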
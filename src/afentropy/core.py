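"""Entropy measures for short RR-interval segments.

This module implements four irregularity measures used to discriminate
atrial fibrillation (AF) from organised rhythms on short (12--30 beat)
RR-interval windows:

* :func:`sampen` -- sample entropy, the negative log of the conditional
  probability that templates matching at embedding dimension ``m``
  (Chebyshev distance, hard 0/1 matching, self-matches excluded) still
  match at dimension ``m + 1``.
* :func:`fuzzymen` -- fuzzy measure entropy, which replaces the hard
  match decision with a graded exponential membership function and sums
  a local (per-template mean removed) and a global (series mean removed)
  conditional term.
* :func:`cosen` -- coefficient of sample entropy: SampEn with a
  data-driven tolerance found by a match-quota search, converted to a
  density estimate by adding ``ln(2r)``, and adjusted for heart rate by
  subtracting ``ln(mean RR)``.
* :func:`entropy_af` -- the AF-targeted measure combining a *ranged*
  (normalised, amplitude-independent) vector distance, fuzzy similarity,
  density-based estimation, the flexible tolerance search, and a
  weighted heart-rate adjustment.

Conventions
-----------
Formulas in the HRV literature are written 1-based; arrays here are
0-based, so template ``i`` (1-based) is row ``i - 1``.  At both
embedding dimensions the first ``N - m`` template vectors are used, so
the dimension-``m`` and dimension-``m + 1`` averages run over the same
number of templates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "InvalidInputError",
    "RRSegment",
    "EntropyParams",
    "EntropyResult",
    "RSearchResult",
    "embed",
    "ranged_distance",
    "chebyshev_distance",
    "fuzzy_similarity",
    "mean_similarity",
    "flexible_r_search",
    "entropy_af",
    "sampen",
    "fuzzymen",
    "cosen",
    "compute_all",
]

RHYTHM_CLASSES = ("AF", "N", "AFL", "J", "NONAF", "UNKNOWN")

DistanceKind = Literal["ranged", "chebyshev"]
SimilarityKind = Literal["fuzzy", "heaviside"]


class InvalidInputError(ValueError):
    """Raised when a segment or parameter set violates a precondition."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RRSegment:
    """One fixed-length window of RR intervals (seconds).

    Parameters
    ----------
    intervals
        Ordered RR intervals in seconds; all strictly positive, length >= 4.
    label
        Rhythm class, one of ``AF, N, AFL, J, NONAF, UNKNOWN``.
    start_beat
        Index of the first beat of this window in the source series
        (bookkeeping for segmentation / quality gating).
    quality_flag
        ``True`` if the window overlaps signal judged noisy.
    """

    intervals: np.ndarray
    label: str = "UNKNOWN"
    start_beat: int = 0
    quality_flag: bool = False

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise InvalidInputError("intervals must be one-dimensional")
        if self.intervals.size < 4:
            raise InvalidInputError(
                f"segment needs at least 4 intervals, got {self.intervals.size}"
            )
        if not np.all(np.isfinite(self.intervals)):
            raise InvalidInputError("intervals must be finite")
        if np.any(self.intervals <= 0):
            raise InvalidInputError("RR intervals must be strictly positive")
        if self.label not in RHYTHM_CLASSES:
            raise InvalidInputError(
                f"unknown rhythm label {self.label!r}; expected one of {RHYTHM_CLASSES}"
            )

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size)

    @property
    def mean_rr(self) -> float:
        return float(self.intervals.mean())


@dataclass(frozen=True)
class EntropyParams:
    """Tuning parameters shared by the entropy measures.

    Attributes
    ----------
    m
        Embedding dimension (template length, beats).  Default 1, the
        short-window convention for the AF-targeted measures; the hard-
        threshold comparators conventionally use 2 (see their defaults).
    n
        Fuzzy similarity weight (exponent on the distance).
    r_init, r_step, r_max
        Grid for the flexible tolerance search.  For the ranged distance
        the tolerance is unitless and the grid is ``0.05, 0.10, ... 1.0``;
        for Chebyshev distance the search steps by ``0.01 * SD(segment)``
        seconds up to the largest pairwise distance.
    min_avg_matches
        Average per-template similarity mass (or match count) at
        dimension ``m + 1`` that terminates the tolerance search.
    w
        Weight on the heart-rate adjustment term ``-w * ln(mean RR)``.
    epsilon
        Small positive guard added to the ranged-distance denominator.
    """

    m: int = 1
    n: float = 2.0
    r_init: float = 0.05
    r_step: float = 0.05
    r_max: float = 1.0
    min_avg_matches: float = 5.0
    w: float = 1.0
    epsilon: float = 1e-10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise InvalidInputError(f"m must be >= 1, got {self.m}")
        for name in ("n", "r_init", "r_step", "min_avg_matches", "epsilon"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.w < 0:
            raise InvalidInputError(f"w must be >= 0, got {self.w}")
        if self.r_max < self.r_init:
            raise InvalidInputError("r_max must be >= r_init")


@dataclass(frozen=True)
class EntropyResult:
    """Outcome of one entropy computation on one segment.

    ``value`` is in nats.  ``b_m`` / ``a_m1`` are the mean similarity
    degrees (or conditional match probabilities) at dimensions ``m`` and
    ``m + 1``.  A non-finite ``value`` is never silently replaced: the
    ``error`` field distinguishes a vanished numerator (``"A_ZERO"``)
    from a vanished denominator (``"B_ZERO"``).
    """

    value: float
    measure: str
    r_used: float = float("nan")
    b_m: float = float("nan")
    a_m1: float = float("nan")
    error: str | None = None
    quota_met: bool = True

    @property
    def is_finite(self) -> bool:
        return bool(np.isfinite(self.value))


@dataclass(frozen=True)
class RSearchResult:
    """Tolerance returned by :func:`flexible_r_search`."""

    r: float
    quota_met: bool
    avg_matches: float


# ---------------------------------------------------------------------------
# Template embedding and distances
# ---------------------------------------------------------------------------


def _as_intervals(segment: RRSegment | Sequence[float] | np.ndarray) -> np.ndarray:
    x = segment.intervals if isinstance(segment, RRSegment) else np.asarray(segment, float)
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("intervals must be finite")
    return x


def embed(segment: RRSegment | Sequence[float], m: int) -> np.ndarray:
    """Form the ``N - m`` template vectors of ``m`` consecutive intervals.

    Template ``i`` (0-based) is ``(x[i], ..., x[i + m - 1])``.  Note that
    although ``N - m + 1`` windows of length ``m`` exist, only the first
    ``N - m`` are used, so that the template count is the same at
    dimensions ``m`` and ``m + 1``.
    """
    x = _as_intervals(segment)
    N = x.size
    if N <= m:
        raise InvalidInputError(f"need more intervals than the embedding dimension: N={N}, m={m}")
    return sliding_window_view(x, m)[: N - m]


def _check_pair(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape or u.ndim != 1 or u.size < 1:
        raise InvalidInputError(f"vectors must be 1-d and of equal length, got {u.shape} vs {v.shape}")
    return u, v


def ranged_distance(u, v, epsilon: float = 1e-10) -> float:
    """Normalised (ranged) distance between two template vectors.

    ``(max|u_k - v_k| - min|u_k - v_k|) / (max|u_k - v_k| + min|u_k - v_k| + eps)``,
    bounded in ``[0, 1)`` and invariant to a common gain or offset applied
    to both vectors (up to the ``epsilon`` perturbation).  For ``m = 1``
    the max and min coincide and the distance is identically 0; this
    degeneracy is deliberate and documented rather than patched.
    """
    u, v = _check_pair(u, v)
    if epsilon <= 0:
        raise InvalidInputError("epsilon must be > 0")
    ad = np.abs(u - v)
    mx, mn = ad.max(), ad.min()
    return float((mx - mn) / (mx + mn + epsilon))


def chebyshev_distance(u, v) -> float:
    """Element-maximum (Chebyshev) distance, in seconds."""
    u, v = _check_pair(u, v)
    return float(np.abs(u - v).max())


def fuzzy_similarity(d, n: float, r: float):
    """Graded similarity ``exp(-d**n / r)`` of a distance ``d``.

    Equals 1 iff ``d == 0`` and decreases strictly with ``d``; larger
    ``n`` sharpens the decision boundary toward a hard threshold.
    """
    if r <= 0:
        raise InvalidInputError(f"tolerance r must be > 0, got {r}")
    if n <= 0:
        raise InvalidInputError(f"similarity weight n must be > 0, got {n}")
    d = np.asarray(d, float)
    out = np.exp(-(d**n) / r)
    return float(out) if out.ndim == 0 else out


def _pairwise_distances(templates: np.ndarray, kind: DistanceKind, epsilon: float) -> np.ndarray:
    diff = np.abs(templates[:, None, :] - templates[None, :, :])
    if kind == "chebyshev":
        return diff.max(axis=-1)
    if kind == "ranged":
        return (diff.max(axis=-1) - diff.min(axis=-1)) / (
            diff.max(axis=-1) + diff.min(axis=-1) + epsilon
        )
    raise InvalidInputError(f"unknown distance kind {kind!r}")


def _similarity_from_distance(d: np.ndarray, kind: SimilarityKind, n: float, r: float) -> np.ndarray:
    if kind == "fuzzy":
        return np.exp(-(d**n) / r)
    if kind == "heaviside":
        return (d <= r).astype(float)
    raise InvalidInputError(f"unknown similarity kind {kind!r}")


def _template_matrix(
    x: np.ndarray, dim: int, n_templates: int
) -> np.ndarray:
    if x.size < dim + 1:
        raise InvalidInputError(f"segment too short for dimension {dim}: N={x.size}")
    W = sliding_window_view(x, dim)
    if n_templates > W.shape[0]:
        raise InvalidInputError(
            f"requested {n_templates} templates but only {W.shape[0]} exist at dimension {dim}"
        )
    return W[:n_templates]


def mean_similarity(
    segment,
    dim: int,
    n: float,
    r: float,
    distance_kind: DistanceKind = "ranged",
    similarity_kind: SimilarityKind = "fuzzy",
    *,
    include_self: bool = True,
    n_templates: int | None = None,
    epsilon: float = 1e-10,
) -> float:
    """Mean pairwise similarity degree of the template vectors at ``dim``.

    With ``include_self=True`` the double average runs over *all* ordered
    pairs ``(i, j)`` including ``i == j`` (the convention of the
    AF-targeted measure); with ``include_self=False`` the diagonal is
    excluded (the SampEn/COSEn convention).  ``n_templates`` fixes the
    number of templates so both embedding dimensions can share the count
    ``N - m``; by default all ``N - dim`` templates are used.
    """
    x = _as_intervals(segment)
    if n_templates is None:
        n_templates = x.size - dim
    min_t = 1 if include_self else 2
    if n_templates < min_t:
        raise InvalidInputError(
            f"segment too short: {n_templates} templates at dimension {dim}"
        )
    T = _template_matrix(x, dim, n_templates)
    D = _similarity_from_distance(
        _pairwise_distances(T, distance_kind, epsilon), similarity_kind, n, r
    )
    if include_self:
        return float(D.mean())
    np.fill_diagonal(D, 0.0)
    t = D.shape[0]
    return float(D.sum() / (t * (t - 1)))


# ---------------------------------------------------------------------------
# Flexible tolerance search
# ---------------------------------------------------------------------------


def _match_mass_per_template(
    x: np.ndarray,
    params: EntropyParams,
    distance_kind: DistanceKind,
    similarity_kind: SimilarityKind,
) -> "tuple[np.ndarray, bool]":
    """Pairwise distance matrix at dimension m+1 and the self-match rule."""
    m = params.m
    n_templates = x.size - m
    T = _template_matrix(x, m + 1, n_templates)
    D = _pairwise_distances(T, distance_kind, params.epsilon)
    include_self = similarity_kind == "fuzzy"
    return D, include_self


def _avg_matches_at(
    D: np.ndarray, include_self: bool, params: EntropyParams, similarity_kind: SimilarityKind, r: float
) -> float:
    S = _similarity_from_distance(D, similarity_kind, params.n, r)
    if not include_self:
        S = S.copy()
        np.fill_diagonal(S, 0.0)
    return float(S.sum(axis=1).mean())


def _r_grid(
    x: np.ndarray, params: EntropyParams, distance_kind: DistanceKind, D: np.ndarray
) -> np.ndarray:
    if distance_kind == "ranged":
        step, r_max = params.r_step, params.r_max
    else:
        # Chebyshev tolerances live on the scale of the data (seconds):
        # step by 1% of the segment SD, stop at the largest observed
        # pairwise distance (beyond which nothing changes).
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
        step = max(0.01 * sd, 1e-6)
        r_max = max(float(D.max()), params.r_init)
    n_steps = int(np.ceil((r_max - params.r_init) / step)) + 1
    return params.r_init + step * np.arange(max(n_steps, 1))


def flexible_r_search(
    segment,
    params: EntropyParams | None = None,
    distance_kind: DistanceKind = "ranged",
    similarity_kind: SimilarityKind = "fuzzy",
) -> RSearchResult:
    """Smallest grid tolerance meeting the average-match quota.

    Starting from ``r_init`` and stepping upward, returns the first
    tolerance at which the average number of matches per template at
    dimension ``m + 1`` reaches ``min_avg_matches``.  For the fuzzy
    (graded) similarity the match count is the sum of similarity
    degrees including the self-pair; for hard (Heaviside) matching
    self-pairs are excluded.  If the quota is never met the grid cap is
    returned with ``quota_met=False`` and a warning.
    """
    if params is None:
        params = EntropyParams()
    x = _as_intervals(segment)
    D, include_self = _match_mass_per_template(x, params, distance_kind, similarity_kind)
    grid = _r_grid(x, params, distance_kind, D)
    avg = float("nan")
    for r in grid:
        avg = _avg_matches_at(D, include_self, params, similarity_kind, float(r))
        if avg >= params.min_avg_matches:
            return RSearchResult(float(r), True, avg)
    warnings.warn(
        f"match quota {params.min_avg_matches} not reached at r_max={grid[-1]:.4g} "
        f"(avg matches {avg:.3g}); using r_max",
        RuntimeWarning,
        stacklevel=2,
    )
    return RSearchResult(float(grid[-1]), False, avg)


# ---------------------------------------------------------------------------
# The four measures
# ---------------------------------------------------------------------------


def _conditional_log_ratio(a: float, b: float) -> tuple[float, str | None]:
    if b <= 0.0:
        return float("nan"), "B_ZERO"
    if a <= 0.0:
        return float("inf"), "A_ZERO"
    return float(-np.log(a / b)), None


def entropy_af(segment, params: EntropyParams | None = None) -> EntropyResult:
    """AF-targeted entropy of one RR segment.

    ``-ln(A / B) + ln(2 r) - w * ln(mean RR)`` where ``B`` and ``A`` are
    the mean fuzzy similarity degrees of the ranged-distance template
    pairs at dimensions ``m`` and ``m + 1`` (both over ``N - m``
    templates, self-pairs included), and ``r`` comes from the flexible
    match-quota search.  The ``ln(2r)`` term converts the probability
    ratio into a density ratio; the last term corrects for heart rate
    (AF typically shortens the mean RR interval).

    Default ``m = 2``: with the ranged distance, ``m = 1`` is degenerate
    (a single element-wise difference makes max = min, so every
    dimension-1 distance is 0 and ``B`` is identically 1, reducing the
    measure to an unconditional density).  ``m = 2`` is the smallest
    embedding at which the conditional structure survives; ``m = 1``
    remains available and its degeneracy is documented rather than
    patched.
    """
    if params is None:
        params = EntropyParams(m=2)
    x = _as_intervals(segment)
    m = params.m
    if x.size < m + 2:
        raise InvalidInputError(f"need N > m + 1, got N={x.size}, m={m}")
    # The ranged distance is normalised, so it is invariant to a common
    # gain only up to the fixed epsilon guard.  Scaling the segment to
    # unit mean first perturbs each distance by O(epsilon) -- far below
    # any physiological or statistical resolution -- and makes gain
    # invariance exact (the heart-rate term uses the raw mean).
    xn = x / x.mean()
    search = flexible_r_search(xn, params, "ranged", "fuzzy")
    r = search.r
    n_templates = x.size - m
    b = mean_similarity(
        xn, m, params.n, r, "ranged", "fuzzy",
        include_self=True, n_templates=n_templates, epsilon=params.epsilon,
    )
    a = mean_similarity(
        xn, m + 1, params.n, r, "ranged", "fuzzy",
        include_self=True, n_templates=n_templates, epsilon=params.epsilon,
    )
    core, err = _conditional_log_ratio(a, b)
    value = core + np.log(2.0 * r) - params.w * np.log(float(x.mean()))
    return EntropyResult(
        value=float(value) if err is None else float("nan") if err == "B_ZERO" else float("inf"),
        measure="ENTROPY_AF", r_used=r, b_m=b, a_m1=a, error=err, quota_met=search.quota_met,
    )


def sampen(segment, m: int = 2, r: float | None = None) -> EntropyResult:
    """Sample entropy of one RR segment (tolerance ``r`` in seconds).

    Hard Chebyshev matching with self-matches excluded; ``B`` counts
    template pairs within ``r`` at length ``m`` and ``A`` at length
    ``m + 1``, both over the first ``N - m`` templates.  ``r`` defaults
    to ``0.2 * SD(segment)``, the common HRV convention.  Zero matches
    at either length give a flagged non-finite result.
    """
    x = _as_intervals(segment)
    if x.size < m + 2:
        raise InvalidInputError(f"need N > m + 1, got N={x.size}, m={m}")
    if r is None:
        r = 0.2 * float(np.std(x, ddof=1))
    if r <= 0:
        raise InvalidInputError(f"tolerance r must be > 0, got {r}")
    n_templates = x.size - m
    b = mean_similarity(x, m, 1.0, r, "chebyshev", "heaviside",
                        include_self=False, n_templates=n_templates)
    a = mean_similarity(x, m + 1, 1.0, r, "chebyshev", "heaviside",
                        include_self=False, n_templates=n_templates)
    value, err = _conditional_log_ratio(a, b)
    return EntropyResult(value=value, measure="SAMPEN", r_used=float(r), b_m=b, a_m1=a, error=err)


def _fuzzy_conditional(
    V: np.ndarray, n: float, r: float
) -> float:
    """Mean off-diagonal fuzzy similarity (Chebyshev distance) of rows of V."""
    d = np.abs(V[:, None, :] - V[None, :, :]).max(axis=-1)
    S = np.exp(-(d**n) / r)
    np.fill_diagonal(S, 0.0)
    t = V.shape[0]
    return float(S.sum() / (t * (t - 1)))


def fuzzymen(segment, params: EntropyParams | None = None, r: float | None = None) -> EntropyResult:
    """Fuzzy measure entropy: local + global fuzzy conditional terms.

    The local term removes each template's own mean (shape information),
    the global term removes the series mean (level information); each is
    ``-ln(A / B)`` with Chebyshev distance, graded similarity
    ``exp(-d**n / r)``, self-matches excluded.  Default ``m = 2`` and
    ``r = 0.2 * SD(segment)``.
    """
    if params is None:
        params = EntropyParams(m=2)
    x = _as_intervals(segment)
    m, n = params.m, params.n
    if x.size < m + 2:
        raise InvalidInputError(f"need N > m + 1, got N={x.size}, m={m}")
    if r is None:
        r = 0.2 * float(np.std(x, ddof=1))
    if r <= 0:
        raise InvalidInputError(f"tolerance r must be > 0, got {r}")
    n_templates = x.size - m
    mu = float(x.mean())
    value = 0.0
    err: str | None = None
    b_loc = a_loc = float("nan")
    for centering in ("local", "global"):
        Tm = _template_matrix(x, m, n_templates).astype(float)
        Tm1 = _template_matrix(x, m + 1, n_templates).astype(float)
        if centering == "local":
            Tm = Tm - Tm.mean(axis=1, keepdims=True)
            Tm1 = Tm1 - Tm1.mean(axis=1, keepdims=True)
        else:
            Tm = Tm - mu
            Tm1 = Tm1 - mu
        b = _fuzzy_conditional(Tm, n, r)
        a = _fuzzy_conditional(Tm1, n, r)
        if centering == "local":
            b_loc, a_loc = b, a
        term, term_err = _conditional_log_ratio(a, b)
        if term_err is not None:
            err = term_err
            value = float("nan") if term_err == "B_ZERO" else float("inf")
            break
        value += term
    return EntropyResult(value=value, measure="FUZZYMEN", r_used=float(r),
                         b_m=b_loc, a_m1=a_loc, error=err)


def cosen(segment, params: EntropyParams | None = None) -> EntropyResult:
    """Coefficient of sample entropy.

    ``SampEn(m, r*) + ln(2 r*) - ln(mean RR)`` with the tolerance ``r*``
    chosen by the flexible match-quota search under Chebyshev distance
    and hard matching.  Default ``m = 1``, the short-window convention
    for Chebyshev-distance measures.
    """
    if params is None:
        params = EntropyParams(m=1)
    x = _as_intervals(segment)
    if x.size < params.m + 2:
        raise InvalidInputError(f"need N > m + 1, got N={x.size}, m={params.m}")
    search = flexible_r_search(segment, params, "chebyshev", "heaviside")
    base = sampen(x, m=params.m, r=search.r)
    value = base.value + np.log(2.0 * search.r) - np.log(float(x.mean()))
    return EntropyResult(
        value=float(value), measure="COSEN", r_used=search.r,
        b_m=base.b_m, a_m1=base.a_m1, error=base.error, quota_met=search.quota_met,
    )


MEASURES = ("sampen", "fuzzymen", "cosen", "entropy_af")


def compute_all(
    segment,
    af_params: EntropyParams | None = None,
    comparator_params: EntropyParams | None = None,
    cosen_params: EntropyParams | None = None,
    measures: Sequence[str] = MEASURES,
) -> dict[str, EntropyResult]:
    """Compute the requested measures on one segment.

    ``af_params`` drives ``entropy_af`` (default ``m=2``);
    ``cosen_params`` drives ``cosen`` (default ``m=1``);
    ``comparator_params`` drives ``sampen`` and ``fuzzymen``
    (default ``m=2``, ``r = 0.2 * SD``).
    """
    if af_params is None:
        af_params = EntropyParams(m=2)
    if comparator_params is None:
        comparator_params = EntropyParams(m=2)
    if cosen_params is None:
        cosen_params = EntropyParams(m=1)
    out: dict[str, EntropyResult] = {}
    for name in measures:
        if name == "sampen":
            out[name] = sampen(segment, m=comparator_params.m)
        elif name == "fuzzymen":
            out[name] = fuzzymen(segment, comparator_params)
        elif name == "cosen":
            out[name] = cosen(segment, cosen_params)
        elif name == "entropy_af":
            out[name] = entropy_af(segment, af_params)
        else:
            raise InvalidInputError(f"unknown measure {name!r}; expected one of {MEASURES}")
    return out
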
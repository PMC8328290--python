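"""Psychometric analysis and a model-based observer for the three tasks.

Analysis side: maximum-likelihood 2AFC psychometric fitting with a 75%
threshold read-out, continuous piecewise-linear (hinge) breakpoint
regression over a candidate grid, and signal-detection d' with the 1/(2N)
correction for perfect rates.

Simulation side: an observer that perceives stimuli only through their
constant-curvature encodings.  It judges a two-arc contour "more complex"
than a single arc when its encoding carries more segments, matches contours
by representation distance, and calls a shape pair "different" when their
representations differ by more than a criterion.  Its noise parameters
(memory curvature jitter, segment confusion, decision noise) are modeling
additions with no empirical commitment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

from .contour import Contour
from .model import (
    CCRepresentation,
    ModelParams,
    encode,
    merge_adjacent,
    reconstruct,
    representation_distance,
    segment_count_difference,
)
from .stimuli import (
    ShapePair,
    SplineShapeSpec,
    StimulusError,
    gen_two_arc,
    gen_cc_arc,
    ArcSpec,
    gen_spline_shape,
    take_fragment,
)

__all__ = [
    "TrialBlock",
    "PsychometricFit",
    "PiecewiseFit",
    "SDTResult",
    "ObserverNoise",
    "UnidentifiableFitError",
    "fit_psychometric",
    "fit_piecewise_linear",
    "dprime",
    "simulate_2afc_blocks",
    "simulate_exp1",
    "simulate_exp2",
    "simulate_exp3",
]


class UnidentifiableFitError(RuntimeError):
    """The data carry no information about the psychometric slope/threshold."""


@dataclass(frozen=True)
class TrialBlock:
    """Aggregated trials at one stimulus level.

    ``condition_value`` is the level (curvature ratio, window size in
    degrees, or segment-count difference); forced-choice blocks carry
    ``n_trials``/``n_correct``, same-different blocks carry
    hits/misses/fas/crs.
    """

    condition_value: float
    n_trials: int = 0
    n_correct: int = 0
    hits: int = 0
    misses: int = 0
    fas: int = 0
    crs: int = 0

    def __post_init__(self):
        if not (0 <= self.n_correct <= self.n_trials) or min(
                self.hits, self.misses, self.fas, self.crs) < 0:
            raise ValueError("inconsistent trial counts")

    @property
    def p_correct(self) -> float:
        return self.n_correct / self.n_trials


@dataclass(frozen=True)
class PsychometricFit:
    """MLE fit of a 2AFC psychometric function on a log stimulus axis.

    p(x) = gamma + (1 - gamma - lambda) * F(beta * (log x - alpha)),
    F logistic or cumulative normal.  ``threshold_at_p75`` is the stimulus
    level at which the fitted probability crosses 0.75 (None when absent).
    """

    family: str
    alpha: float
    beta: float
    gamma: float
    lam: float
    log_likelihood: float
    threshold_at_p75: float | None

    def predict(self, level) -> np.ndarray:
        x = np.log(np.asarray(level, float))
        F = expit if self.family == "logistic" else norm.cdf
        return self.gamma + (1.0 - self.gamma - self.lam) * F(
            self.beta * (x - self.alpha))


@dataclass(frozen=True)
class PiecewiseFit:
    """Continuous hinge regression: slope_pre up to the breakpoint, then
    slope_post, sharing the value at the break."""

    breakpoint: float
    slope_pre: float
    slope_post: float
    intercept: float
    r_squared: float

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        return (self.intercept + self.slope_pre * x
                + (self.slope_post - self.slope_pre)
                * np.maximum(0.0, x - self.breakpoint))


@dataclass(frozen=True)
class SDTResult:
    """Corrected hit / false-alarm rates and d' = Z(hit) - Z(fa)."""

    hit_rate: float
    fa_rate: float
    d_prime: float


def _nll(params, x, n, c, gamma, lam, family):
    alpha, beta = params
    F = expit if family == "logistic" else norm.cdf
    p = gamma + (1.0 - gamma - lam) * F(beta * (x - alpha))
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return -np.sum(c * np.log(p) + (n - c) * np.log1p(-p))


def fit_psychometric(blocks, family: str = "logistic", guess: float = 0.5,
                     lapse: float = 0.0) -> PsychometricFit:
    """Maximum-likelihood psychometric fit over trial blocks.

    The stimulus axis is log-transformed (levels must be positive); the
    guess rate is fixed (0.5 for 2AFC) and the lapse rate fixed at
    ``lapse``.  Raises :class:`UnidentifiableFitError` when the data are
    indistinguishable from chance at every level (flat likelihood).
    """
    if family not in ("logistic", "cumulative-normal"):
        raise ValueError(f"unknown family {family!r}")
    blocks = list(blocks)
    levels = np.array([b.condition_value for b in blocks], float)
    if len(set(levels)) < 3:
        raise ValueError("need at least 3 distinct stimulus levels")
    if np.any(levels <= 0):
        raise ValueError("levels must be positive (log stimulus axis)")
    x = np.log(levels)
    n = np.array([b.n_trials for b in blocks], float)
    c = np.array([b.n_correct for b in blocks], float)

    # chance model: every response a guess (p = gamma at all levels)
    nll_chance = -np.sum(c * np.log(guess) + (n - c) * np.log1p(-guess))

    best = None
    span = x.max() - x.min()
    for a0 in np.linspace(x.min(), x.max(), 5):
        for b0 in (1.0 / max(span, 1e-6), 4.0 / max(span, 1e-6), 20.0 / max(span, 1e-6)):
            res = minimize(_nll, np.array([a0, b0]),
                           args=(x, n, c, guess, lapse, family),
                           method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10,
                                    "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
    alpha, beta = best.x
    if beta <= 0 or nll_chance - best.fun < 1e-6:
        raise UnidentifiableFitError(
            "likelihood is flat: performance indistinguishable from chance"
        )
    # level where the fitted probability reaches 0.75
    target = (0.75 - guess) / (1.0 - guess - lapse)
    if 0.0 < target < 1.0:
        q = logit(target) if family == "logistic" else norm.ppf(target)
        threshold = float(np.exp(alpha + q / beta))
    else:
        threshold = None
    return PsychometricFit(family=family, alpha=float(alpha), beta=float(beta),
                           gamma=guess, lam=lapse,
                           log_likelihood=-float(best.fun),
                           threshold_at_p75=threshold)


def fit_piecewise_linear(x, y, candidate_breakpoints) -> PiecewiseFit:
    """Least-squares continuous hinge fit over a breakpoint candidate grid.

    For each candidate c the model y = b0 + b1*x + b2*max(0, x - c) is fit
    by ordinary least squares; the candidate maximizing R^2 wins, with ties
    broken toward the larger breakpoint (the more economical window).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 4:
        raise ValueError("need at least 4 points for a hinge fit")
    candidates = np.asarray(candidate_breakpoints, float)
    if np.any(candidates < x.min()) or np.any(candidates > x.max()):
        raise ValueError("candidate breakpoints must lie within the x range")
    sst = float(np.sum((y - y.mean()) ** 2))
    best = None
    for cbp in np.sort(candidates):
        X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - cbp)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        ssr = float(np.sum((y - X @ coef) ** 2))
        r2 = 1.0 if sst == 0.0 else 1.0 - ssr / sst
        key = round(r2, 9)
        # ascending candidates: >= keeps the larger breakpoint among ties
        if best is None or key >= best[0]:
            best = (key, cbp, coef, r2)
    _, cbp, coef, r2 = best
    return PiecewiseFit(breakpoint=float(cbp), slope_pre=float(coef[1]),
                        slope_post=float(coef[1] + coef[2]),
                        intercept=float(coef[0]), r_squared=float(r2))


def dprime(hits: int, misses: int, fas: int, crs: int) -> SDTResult:
    """Signal-detection sensitivity d' = Z(hit rate) - Z(fa rate).

    Perfect rates (0 or 1) are corrected to 1/(2N) resp. 1 - 1/(2N), where
    N is the number of trials in that class, so d' stays finite.
    """
    if min(hits, misses, fas, crs) < 0:
        raise ValueError("counts must be nonnegative")
    n_signal = hits + misses
    n_noise = fas + crs
    if n_signal == 0 or n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")

    def corrected(k, n):
        rate = k / n
        if rate == 0.0:
            return 1.0 / (2 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate

    h = corrected(hits, n_signal)
    f = corrected(fas, n_noise)
    return SDTResult(hit_rate=h, fa_rate=f,
                     d_prime=float(norm.ppf(h) - norm.ppf(f)))


# ---------------------------------------------------------------------------
# model-based observer


@dataclass(frozen=True)
class ObserverNoise:
    """Noise model of the simulated observer.

    curvature_sd : multiplicative jitter applied to each remembered
        segment's curvature (fraction of its value);
    confusion_rate : probability that the remembered representation gains a
        spurious segment split;
    decision_sd : Gaussian noise on the same/different decision variable.
    """

    curvature_sd: float = 0.0
    confusion_rate: float = 0.0
    decision_sd: float = 0.0


def _remembered(rep: CCRepresentation, noise: ObserverNoise, rng,
                params: ModelParams) -> CCRepresentation:
    """Noisy memory trace of a representation (re-merged after jitter)."""
    if noise.curvature_sd == 0.0 and noise.confusion_rate == 0.0:
        return rep
    segs = list(rep.segments)
    if noise.curvature_sd > 0.0:
        segs = [replace(s, curvature=s.curvature
                        * (1.0 + noise.curvature_sd * rng.standard_normal()))
                for s in segs]
    if noise.confusion_rate > 0.0 and rng.random() < noise.confusion_rate:
        i = int(rng.integers(0, len(segs)))
        s = segs[i]
        half = replace(s, arclength=s.arclength / 2.0)
        jitter = 1.0 + 2.0 * max(noise.curvature_sd, 0.05)
        segs[i:i + 1] = [replace(half, curvature=half.curvature * jitter),
                         replace(half, curvature=half.curvature / jitter)]
    noisy = replace(rep, segments=tuple(segs))
    return merge_adjacent(noisy, params)


def _draw_two_arc_trial(ratio, rng):
    """Matched single-arc / two-arc stimulus pair for one trial."""
    for _ in range(100):
        l1, l2 = rng.uniform(120.0, 250.0, 2)
        k1 = rng.uniform(0.0059, 0.02)
        order = "high_second" if rng.random() < 0.5 else "high_first"
        k_hi = k1 * ratio
        if max(l1, l2) * k_hi >= 2.0 * np.pi:
            continue
        if l1 * (k1 if order == "high_second" else k_hi) \
                + l2 * (k_hi if order == "high_second" else k1) >= 2.0 * np.pi:
            continue
        two, _ = gen_two_arc(ratio, l1, l2, k1, order=order)
        # single-arc foil with length drawn from the same total-length range
        ls = rng.uniform(240.0, 500.0)
        ks = rng.uniform(0.0059, 0.02)
        if ls * ks >= 2.0 * np.pi:
            continue
        single = gen_cc_arc(ArcSpec(arclength=ls, curvature=ks))
        return single, two
    raise StimulusError("could not draw a valid trial within the constraints")


def simulate_exp1(ratios, n_trials: int, params: ModelParams = ModelParams(),
                  rng=None, noise: ObserverNoise = ObserverNoise()
                  ) -> list[TrialBlock]:
    """Complexity-judgment task: single arc vs. two joined arcs.

    The observer encodes both open contours and picks the one with more
    constant-curvature segments as "more complex", guessing on ties.
    Returns one TrialBlock per curvature ratio.
    """
    rng = np.random.default_rng(rng)
    blocks = []
    for ratio in ratios:
        correct = 0
        for _ in range(n_trials):
            single, two = _draw_two_arc_trial(ratio, rng)
            n_single = _remembered(encode(single, params), noise, rng,
                                   params).n_segments
            n_two = _remembered(encode(two, params), noise, rng,
                                params).n_segments
            if n_two > n_single:
                correct += 1
            elif n_two == n_single and rng.random() < 0.5:
                correct += 1
        blocks.append(TrialBlock(condition_value=float(ratio),
                                 n_trials=n_trials, n_correct=correct))
    return blocks


def simulate_exp2(window_lengths, n_trials: int,
                  params: ModelParams = ModelParams(), rng=None,
                  noise: ObserverNoise = ObserverNoise(curvature_sd=0.10,
                                                       decision_sd=2.0),
                  spec: SplineShapeSpec = SplineShapeSpec(),
                  fraction: float = 0.4) -> list[TrialBlock]:
    """Fragment-matching task: original fragment vs. its CC rendering.

    Per trial a random 40% fragment is encoded into memory (with noise); the
    observer then compares the memory trace with the encodings of the
    original fragment and of a constant-curvature rendering produced with an
    absolute integration window of the given arclength (contour units), and
    picks the closer one.  Accuracy is the rate of choosing the original.
    """
    rng = np.random.default_rng(rng)
    blocks = []
    for w in window_lengths:
        correct = 0
        for _ in range(n_trials):
            seed = int(rng.integers(0, 2**31 - 1))
            shape = gen_spline_shape(replace(spec, seed=seed))
            frag = take_fragment(shape, fraction, rng)
            rep_orig = encode(frag, params)
            cc_render = reconstruct(
                encode(frag, replace(params, window_arclength=float(w))),
                points_per_segment=64)
            rep_cc = encode(cc_render, params)
            memory = _remembered(rep_orig, noise, rng, params)
            d_orig = (representation_distance(memory, rep_orig)
                      + noise.decision_sd * rng.standard_normal())
            d_cc = (representation_distance(memory, rep_cc)
                    + noise.decision_sd * rng.standard_normal())
            if d_orig < d_cc or (d_orig == d_cc and rng.random() < 0.5):
                correct += 1
        blocks.append(TrialBlock(condition_value=float(w), n_trials=n_trials,
                                 n_correct=correct))
    return blocks


def simulate_exp3(pairs_by_condition: dict[int, list[ShapePair]],
                  n_trials_per_condition: int, n_same_trials: int,
                  params: ModelParams = ModelParams(), rng=None,
                  noise: ObserverNoise = ObserverNoise(curvature_sd=0.10,
                                                       decision_sd=1.0),
                  criterion: float = 2.0,
                  metric_weight: float = 0.2) -> list[TrialBlock]:
    """Same/different task over a similarity-matched pair corpus.

    On "different" trials the observer encodes the first shape into a noisy
    memory trace, encodes the second shape, and responds "different" when
    their representation distance (plus decision noise) exceeds the
    criterion; "same" trials show one shape twice and feed the shared
    false-alarm rate.  Returns one TrialBlock per segment-difference
    condition, each carrying the common fas/crs counts.
    """
    rng = np.random.default_rng(rng)
    enc_cache: dict[int, CCRepresentation] = {}

    def enc(contour):
        key = id(contour)
        if key not in enc_cache:
            enc_cache[key] = encode(contour, params)
        return enc_cache[key]

    def says_different(rep1, rep2):
        memory = _remembered(rep1, noise, rng, params)
        d = representation_distance(memory, rep2, metric_weight=metric_weight)
        return d + noise.decision_sd * rng.standard_normal() > criterion

    all_pairs = [p for pool in pairs_by_condition.values() for p in pool]
    fas = crs = 0
    for _ in range(n_same_trials):
        pair = all_pairs[int(rng.integers(0, len(all_pairs)))]
        shape = pair.shape_a if rng.random() < 0.5 else pair.shape_b
        if says_different(enc(shape), enc(shape)):
            fas += 1
        else:
            crs += 1

    blocks = []
    for cond in sorted(pairs_by_condition):
        pool = pairs_by_condition[cond]
        hits = 0
        for _ in range(n_trials_per_condition):
            pair = pool[int(rng.integers(0, len(pool)))]
            first_a = rng.random() < 0.5
            r1 = enc(pair.shape_a if first_a else pair.shape_b)
            r2 = enc(pair.shape_b if first_a else pair.shape_a)
            if says_different(r1, r2):
                hits += 1
        blocks.append(TrialBlock(condition_value=float(cond),
                                 hits=hits,
                                 misses=n_trials_per_condition - hits,
                                 fas=fas, crs=crs))
    return blocks


def simulate_2afc_blocks(levels, threshold: float, slope: float,
                         n_trials: int, rng=None, guess: float = 0.5,
                         family: str = "logistic") -> list[TrialBlock]:
    """Synthetic 2AFC data from an observer with a known psychometric
    function (75% point at ``threshold`` on the raw level axis)."""
    rng = np.random.default_rng(rng)
    F = expit if family == "logistic" else norm.cdf
    target = (0.75 - guess) / (1.0 - guess)
    q = logit(target) if family == "logistic" else norm.ppf(target)
    alpha = np.log(threshold) - q / slope
    blocks = []
    for lvl in levels:
        p = guess + (1.0 - guess) * F(slope * (np.log(lvl) - alpha))
        k = int(rng.binomial(n_trials, p))
        blocks.append(TrialBlock(condition_value=float(lvl),
                                 n_trials=n_trials, n_correct=k))
    return blocks
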
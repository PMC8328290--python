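"""Generators for the psychophysical stimulus families.

Four families of vector stimuli, plus the physical shape-similarity metric
used to equate them:

* single constant-curvature arcs (open contours, 240-500 px long, curvature
  0.0059-0.02 px^-1, angular extent under 360 deg);
* two smoothly joined constant-curvature arcs with a prescribed curvature
  ratio, tangent-continuous at the junction;
* closed random shapes built by radially displacing 12 control points on a
  circle and interpolating them with a periodic cubic spline;
* 40% fragments of those shapes, and deformed shape pairs with matched
  contour length, binned by how many constant-curvature segments the two
  members differ by under the parameterized encoder.

All generators are deterministic given a seed / Generator instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq
from shapely.geometry import LineString, Polygon

from .contour import Contour, InvalidContourError, resample_uniform
from .model import (
    CCRepresentation,
    ModelParams,
    encode,
    segment_count_difference,
)

__all__ = [
    "ArcSpec",
    "SplineShapeSpec",
    "ShapePair",
    "StimulusError",
    "MatchingError",
    "gen_cc_arc",
    "gen_two_arc",
    "gen_spline_shape",
    "spline_from_controls",
    "take_fragment",
    "shape_similarity",
    "deform_pair",
    "deform_pair_in_band",
    "build_matched_pairs",
]


class StimulusError(ValueError):
    """A stimulus specification violates its construction constraints."""


class MatchingError(RuntimeError):
    """Similarity matching across condition bins could not be achieved."""


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ArcSpec:
    """A single constant-curvature arc: length and |curvature| in pixels,
    initial tangent ``orientation`` (radians), turning direction ``sign``."""

    arclength: float
    curvature: float
    orientation: float = 0.0
    sign: int = 1

    def __post_init__(self):
        if self.arclength <= 0 or self.curvature < 0:
            raise StimulusError("arclength must be positive, curvature >= 0")
        if self.sign not in (-1, 1):
            raise StimulusError("sign must be +1 or -1")
        if self.arclength * self.curvature >= 2.0 * np.pi:
            raise StimulusError(
                f"angular extent {self.arclength * self.curvature:.3f} rad "
                "violates the under-360-degree constraint"
            )


@dataclass(frozen=True)
class SplineShapeSpec:
    """Random closed shape: 12 control points at 30-degree spacing, radii
    uniform in [displacement_low, displacement_high] * base_radius, joined
    by a periodic cubic spline."""

    n_control: int = 12
    base_radius: float = 200.0
    displacement_low: float = 0.7
    displacement_high: float = 1.3
    n_points: int = 1024
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.displacement_low < self.displacement_high):
            raise StimulusError("need 0 < displacement_low < displacement_high")
        if self.n_control < 4 or self.n_points < 64:
            raise StimulusError("too few control points or samples")


@dataclass(frozen=True)
class ShapePair:
    """Two closed contours with their physical similarity and (optionally)
    the difference in constant-curvature segment count between them."""

    shape_a: Contour
    shape_b: Contour
    similarity: float
    segment_diff: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.similarity <= 1.0):
            raise ValueError("similarity must lie in [0, 1]")


def _arc_coords(length, k_signed, orientation, n):
    u = np.linspace(0.0, length, n)
    if abs(k_signed * length) < 1e-12:
        return np.column_stack([u * np.cos(orientation),
                                u * np.sin(orientation)])
    phi = orientation + k_signed * u
    x = (np.sin(phi) - np.sin(orientation)) / k_signed
    y = -(np.cos(phi) - np.cos(orientation)) / k_signed
    return np.column_stack([x, y])


def gen_cc_arc(spec: ArcSpec, n_points: int | None = None) -> Contour:
    """Sample a single constant-curvature arc as an open contour.

    Exact to machine precision up to the polyline sampling (default spacing
    about one pixel).
    """
    n = n_points if n_points is not None else max(8, round(spec.arclength) + 1)
    pts = _arc_coords(spec.arclength, spec.sign * spec.curvature,
                      spec.orientation, n)
    return Contour(points=pts, closed=False)


def gen_two_arc(ratio: float, l1: float, l2: float, k1: float,
                order: str = "high_second", orientation: float = 0.0,
                sign: int = 1, n_points: int | None = None):
    """Two smoothly joined constant-curvature arcs with curvature ratio
    ``ratio``.

    The second arc starts at the first arc's endpoint with the first arc's
    end tangent, so the junction is tangent-continuous by construction.
    ``order`` selects which side carries the higher curvature
    ("high_first" or "high_second"); both arcs turn in the same direction.

    Returns
    -------
    contour : Contour
        Open contour sampled uniformly in arclength over both arcs.
    junction_index : int
        Index of the junction point in the contour (ground truth).
    """
    if ratio <= 1.0:
        raise StimulusError("ratio must exceed 1")
    if not (120.0 <= l1 <= 250.0 and 120.0 <= l2 <= 250.0):
        raise StimulusError("arc lengths must lie in [120, 250] px")
    if not (0.0059 <= k1 <= 0.02):
        raise StimulusError("k1 must lie in [0.0059, 0.02] px^-1")
    if order not in ("high_first", "high_second"):
        raise StimulusError(f"unknown order {order!r}")
    ka = k1 if order == "high_second" else k1 * ratio
    kb = k1 * ratio if order == "high_second" else k1
    for length, k in ((l1, ka), (l2, kb)):
        if length * k >= 2.0 * np.pi:
            raise StimulusError(
                "an arc's angular extent violates the under-360-degree constraint"
            )
    total = l1 + l2
    n = n_points if n_points is not None else max(16, round(total) + 1)
    j = round(l1 / total * (n - 1))
    a1 = _arc_coords(l1, sign * ka, orientation, j + 1)
    end_tan = orientation + sign * ka * l1
    a2 = _arc_coords(l2, sign * kb, end_tan, n - j)
    pts = np.vstack([a1, a2[1:] + a1[-1]])
    return Contour(points=pts, closed=False), j


def spline_from_controls(control_points: np.ndarray,
                         n_points: int = 1024) -> Contour:
    """Closed contour through control points via a periodic cubic spline
    (chord-length parameterization)."""
    cp = np.asarray(control_points, float)
    wrapped = np.vstack([cp, cp[:1]])
    chords = np.hypot(*np.diff(wrapped, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(chords)])
    spline = CubicSpline(t, wrapped, bc_type="periodic")
    u = np.linspace(0.0, t[-1], n_points, endpoint=False)
    return Contour(points=spline(u), closed=True)


def _control_points(spec: SplineShapeSpec, rng) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(spec.n_control) / spec.n_control
    radii = spec.base_radius * rng.uniform(spec.displacement_low,
                                           spec.displacement_high,
                                           spec.n_control)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def _is_simple(contour: Contour) -> bool:
    ring = np.vstack([contour.points, contour.points[:1]])
    return LineString(ring).is_simple


def gen_spline_shape(spec: SplineShapeSpec, return_controls: bool = False,
                     max_retries: int = 50):
    """Generate a random closed spline shape (deterministic per spec.seed).

    Control-point radii are redrawn (from the same seeded stream) if the
    resulting contour self-intersects; generated contours are always simple.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(max_retries):
        cp = _control_points(spec, rng)
        contour = spline_from_controls(cp, spec.n_points)
        if _is_simple(contour):
            return (contour, cp) if return_controls else contour
    raise StimulusError(
        f"no simple contour after {max_retries} retries (seed {spec.seed})"
    )


def take_fragment(contour: Contour, fraction: float = 0.4,
                  rng=None) -> Contour:
    """Open fragment covering ``fraction`` of a closed contour's length,
    starting at a uniformly random point along it."""
    if not contour.closed:
        raise InvalidContourError("take_fragment needs a closed contour")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    rng = _as_rng(rng)
    n = contour.n_points
    count = max(8, round(fraction * n) + 1)
    start = int(rng.integers(0, n))
    idx = (start + np.arange(count)) % n
    return Contour(points=contour.points[idx], closed=False)


def _polygon(contour: Contour) -> Polygon:
    poly = Polygon(contour.points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def shape_similarity(a: Contour, b: Contour, align: str = "centroid") -> float:
    """Physical similarity of two closed shapes by interior overlap.

    With the shapes superposed at a common centroid (``align="centroid"``,
    default) or left in place (``align="none"``), returns the mean of
    |A & B| / |A| and |A & B| / |B| — 1 for identical shapes, 0 for
    disjoint ones.
    """
    if not (a.closed and b.closed):
        raise InvalidContourError("shape_similarity needs closed contours")
    pa, pb = _polygon(a), _polygon(b)
    if align == "centroid":
        from shapely.affinity import translate
        ca, cb = pa.centroid, pb.centroid
        pb = translate(pb, xoff=ca.x - cb.x, yoff=ca.y - cb.y)
    elif align != "none":
        raise ValueError(f"unknown alignment {align!r}")
    inter = pa.intersection(pb).area
    return 0.5 * (inter / pa.area + inter / pb.area)


def deform_pair(shape: Contour, control_points: np.ndarray, magnitude: float,
                rng=None, n_points: int = 1024, length_tol: float = 0.005,
                max_retries: int = 40) -> ShapePair:
    """Deform a spline shape by displacing two adjacent control points,
    preserving total contour length.

    The first of the two control points moves by ``magnitude`` in a random
    direction; the second moves in another random direction by an amount
    solved (1D root finding) so that the deformed contour's length matches
    the original within ``length_tol``.  Directions are redrawn if no such
    amount exists.
    """
    if not shape.closed:
        raise InvalidContourError("deform_pair needs a closed shape")
    rng = _as_rng(rng)
    cp = np.asarray(control_points, float)
    m = cp.shape[0]
    L0 = shape.length

    for _ in range(max_retries):
        j = int(rng.integers(0, m))
        j2 = (j + 1) % m
        th1, th2 = rng.uniform(0.0, 2.0 * np.pi, 2)
        d1 = magnitude * np.array([np.cos(th1), np.sin(th1)])
        d2dir = np.array([np.cos(th2), np.sin(th2)])

        def length_err(amount):
            new = cp.copy()
            new[j] += d1
            new[j2] += amount * d2dir
            return spline_from_controls(new, n_points).length - L0

        lo, hi = 0.0, 3.0 * magnitude
        flo = length_err(lo)
        fhi = length_err(hi)
        if flo == 0.0:
            amount = 0.0
        elif flo * fhi < 0:
            amount = brentq(length_err, lo, hi, xtol=1e-6 * max(magnitude, 1.0))
        else:
            continue
        new = cp.copy()
        new[j] += d1
        new[j2] += amount * d2dir
        shape_b = spline_from_controls(new, n_points)
        if not _is_simple(shape_b):
            continue
        if abs(shape_b.length - L0) > length_tol * L0:
            continue
        sim = shape_similarity(shape, shape_b)
        return ShapePair(shape_a=shape, shape_b=shape_b, similarity=sim)
    raise StimulusError(
        "could not deform while preserving contour length "
        f"after {max_retries} attempts"
    )


def deform_pair_in_band(shape: Contour, control_points: np.ndarray,
                        similarity_band=(0.97, 0.98), rng=None,
                        n_points: int = 1024, max_retries: int = 20
                        ) -> ShapePair | None:
    """Length-preserving deformation tuned to land in a similarity band.

    Same construction as :func:`deform_pair`, but the leading displacement
    magnitude is bisected until the pair's similarity hits a target drawn
    uniformly from ``similarity_band`` (similarity decreases with magnitude
    for fixed directions).  Returns None when no admissible deformation is
    found, so callers can redraw the base shape.
    """
    if not shape.closed:
        raise InvalidContourError("deform_pair_in_band needs a closed shape")
    rng = _as_rng(rng)
    cp = np.asarray(control_points, float)
    m = cp.shape[0]
    L0 = shape.length

    for _ in range(max_retries):
        j = int(rng.integers(0, m))
        j2 = (j + 1) % m
        th1, th2 = rng.uniform(0.0, 2.0 * np.pi, 2)
        u1 = np.array([np.cos(th1), np.sin(th1)])
        u2 = np.array([np.cos(th2), np.sin(th2)])

        def build(mag):
            def err(amount):
                new = cp.copy()
                new[j] += mag * u1
                new[j2] += amount * u2
                return spline_from_controls(new, n_points).length - L0

            flo, fhi = err(0.0), err(3.0 * mag)
            if flo == 0.0:
                amount = 0.0
            elif flo * fhi < 0:
                amount = brentq(err, 0.0, 3.0 * mag, xtol=1e-6 * max(mag, 1.0))
            else:
                return None
            new = cp.copy()
            new[j] += mag * u1
            new[j2] += amount * u2
            return spline_from_controls(new, n_points)

        def sim_at(mag):
            sb = build(mag)
            return None if sb is None else (shape_similarity(shape, sb), sb)

        target = rng.uniform(*similarity_band)
        lo_m, hi_m = 0.5, 40.0
        r_hi, r_lo = sim_at(hi_m), sim_at(lo_m)
        if r_hi is None or r_lo is None or not (r_hi[0] < target < r_lo[0]):
            continue
        for _ in range(30):
            mid = 0.5 * (lo_m + hi_m)
            r = sim_at(mid)
            if r is None:
                break
            sim, sb = r
            if abs(sim - target) < 1e-4 or hi_m - lo_m < 1e-3:
                if (similarity_band[0] <= sim <= similarity_band[1]
                        and _is_simple(sb)):
                    return ShapePair(shape_a=shape, shape_b=sb, similarity=sim)
                break
            if sim > target:
                lo_m = mid
            else:
                hi_m = mid
    return None


def _label(pair: ShapePair, params: ModelParams) -> ShapePair:
    diff = segment_count_difference(encode(pair.shape_a, params),
                                    encode(pair.shape_b, params))
    return replace(pair, segment_diff=diff)


def _match_bin_means(bins: dict[int, list[ShapePair]], n_per: int,
                     tol: float, max_pool: int = 24):
    """Select n_per pairs per bin so the bin means of similarity agree.

    Every size-``n_per`` subset of each bin's pool (pools first trimmed to
    the ``max_pool`` members nearest the grand mean) is enumerated; a common
    target mean is chosen to minimize the worst bin's distance to it, and
    each bin contributes its nearest-mean subset.  Raises MatchingError if
    the resulting spread still exceeds ``tol``.
    """
    from itertools import combinations

    t0 = float(np.mean([p.similarity for pool in bins.values()
                        for p in pool]))
    per_bin = {}
    for cond, pool in bins.items():
        pool = sorted(pool, key=lambda p: abs(p.similarity - t0))[:max_pool]
        sims = np.array([p.similarity for p in pool])
        combos = np.array(list(combinations(range(len(pool)), n_per)))
        means = sims[combos].mean(axis=1)
        order = np.argsort(means)
        per_bin[cond] = (pool, combos[order], means[order])

    # candidate targets: achievable means of the sparsest bin (subsampled)
    sparsest = min(per_bin, key=lambda c: per_bin[c][2].size)
    cand = per_bin[sparsest][2]
    if cand.size > 4000:
        cand = cand[:: cand.size // 4000]

    def nearest_idx(means, t):
        i = np.searchsorted(means, t)
        i = np.clip([i - 1, i], 0, means.size - 1)
        return i[np.argmin(np.abs(means[i] - t))]

    best_t, best_cost = None, np.inf
    for t in cand:
        cost = max(abs(per_bin[c][2][nearest_idx(per_bin[c][2], t)] - t)
                   for c in per_bin)
        if cost < best_cost:
            best_cost, best_t = cost, t

    selected = {}
    chosen_means = []
    for cond, (pool, combos, means) in per_bin.items():
        i = nearest_idx(means, best_t)
        selected[cond] = [pool[j] for j in combos[i]]
        chosen_means.append(means[i])
    spread = max(chosen_means) - min(chosen_means)
    if spread > tol:
        raise MatchingError(
            f"bin-mean spread {spread:.2e} exceeds tolerance {tol:.0e}; "
            "per-bin pool sizes: "
            + ", ".join(f"{c}: {len(v)}" for c, v in sorted(bins.items()))
        )
    return selected


def build_matched_pairs(n_per_condition: int,
                        similarity_band=(0.97, 0.98),
                        params: ModelParams = ModelParams(),
                        rng=None,
                        spec: SplineShapeSpec = SplineShapeSpec(),
                        max_candidates: int = 3000,
                        mean_tol: float = 1e-4,
                        conditions=(0, 1, 2, 3, 4),
                        pool_factor: float = 3.0) -> dict[int, list[ShapePair]]:
    """Build a similarity-matched corpus of deformed shape pairs.

    Candidate pairs are generated, kept when their physical similarity falls
    inside ``similarity_band``, and binned by the difference in
    constant-curvature segment count between the two members under
    ``params``.  Each condition bin is then subsampled to ``n_per_condition``
    pairs so that the bins' mean similarities agree within ``mean_tol``.

    Raises :class:`MatchingError` (with per-bin counts) when the candidate
    pool cannot support the requested matching.
    """
    rng = _as_rng(rng)
    lo, hi = similarity_band
    want = max(n_per_condition + 3, round(pool_factor * n_per_condition))
    bins: dict[int, list[ShapePair]] = {c: [] for c in conditions}
    n_candidates = 0
    while n_candidates < max_candidates:
        if all(len(v) >= want for v in bins.values()):
            break
        n_candidates += 1
        seed = int(rng.integers(0, 2**31 - 1))
        shape, cp = gen_spline_shape(replace(spec, seed=seed),
                                     return_controls=True)
        pair = deform_pair_in_band(shape, cp, (lo, hi), rng)
        if pair is None:
            continue
        pair = replace(_label(pair, params), seed=seed)
        if pair.segment_diff in bins and len(bins[pair.segment_diff]) < want:
            bins[pair.segment_diff].append(pair)
    short = {c: len(v) for c, v in bins.items() if len(v) < n_per_condition}
    if short:
        raise MatchingError(
            f"candidate pool exhausted after {n_candidates} candidates; "
            "underfilled bins: "
            + ", ".join(f"{c}: {n}" for c, n in sorted(short.items()))
        )
    return _match_bin_means(bins, n_per_condition, mean_tol)
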
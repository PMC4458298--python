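"""Ground-truth scene generation and dynamic measurement synthesis.

A dynamic acquisition is modelled as

    Psi = sum_p  c_p(t_k) * a_p  +  B  +  eps ,

a K x N stack of frames: each of P localized fluorescent sources
contributes its fixed spatial pattern a_p (a boundary measurement pattern
rendered through the FEM weight matrix, or a reconstructed-image pattern)
scaled by its nonnegative time course c_p, plus a static background frame
B and additive zero-mean Gaussian noise eps.  Noise strength is given
either as a variance or as a peak-signal-to-noise ratio
PSNR = 10 log10(s^2 / sigma^2) with s^2 the peak power of the clean
frames.

The module also provides the purely synthetic local-dominance generator
(each source owns at least one pixel where all other sources vanish) used
to exercise the exact-recovery guarantee of the convex separation engine
independently of the FEM, and image-domain organ-like source generators
mirroring dynamic contrast studies with correlated (overlapping blood-pool
organs, similar pharmacokinetics) and uncorrelated (disjoint organs,
complementary kinetics) sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AlreadySubtractedError,
    InvalidParameterError,
    RasterizationError,
    ShapeMismatchError,
)
from .forward import (
    OpticalProperties,
    SystemMatrix,
    boundary_detectors,
    concentration_to_yield,
)
from .mesh import build_rect_mesh

#: Default acquisition grid (minutes) of a six-frame dynamic contrast study.
DEFAULT_TIMES_MIN = (5.0, 10.0, 15.0, 30.0, 60.0, 120.0)


@dataclass(frozen=True)
class TimeCourse:
    """Sampled nonnegative concentration/yield course of one source."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.size < 2 or t.size != v.size:
            raise InvalidParameterError("need K >= 2 matching times/values")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(v < 0):
            raise InvalidParameterError("course values must be >= 0")

    @property
    def K(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class Inclusion:
    """Disk-shaped fluorescent region with its own kinetics."""

    center: tuple
    radius: float
    course: TimeCourse
    epsilon: float = 1.0  # molar extinction, mm^-1 M^-1
    eta: float = 1.0      # quantum yield

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("inclusion radius must be > 0")


@dataclass
class Scene:
    """Phantom geometry + optics + inclusions + acquisition layout."""

    width: float
    height: float
    edge_len: float
    optics: OpticalProperties
    inclusions: list
    n_excitation_sources: int = 4
    detector_every: int = 2
    background: float | np.ndarray | None = None

    def __post_init__(self):
        if not self.inclusions:
            raise InvalidParameterError("scene needs at least one inclusion")
        for inc in self.inclusions:
            cx, cy = inc.center
            margin = min(cx - inc.radius, cy - inc.radius,
                         self.width - cx - inc.radius,
                         self.height - cy - inc.radius)
            if margin < 1.0:
                raise InvalidParameterError(
                    f"inclusion at {inc.center} closer than 1 mm to the boundary")

    def build_system(self) -> SystemMatrix:
        from .forward import build_weight_matrix, perimeter_sources
        mesh = build_rect_mesh(self.width, self.height, self.edge_len)
        srcs = perimeter_sources(self.width, self.height,
                                 self.n_excitation_sources, self.optics)
        dets = boundary_detectors(mesh, every=self.detector_every)
        return build_weight_matrix(mesh, self.optics, srcs, dets)

    @property
    def times(self) -> np.ndarray:
        return self.inclusions[0].course.times


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise, specified by PSNR (dB) or variance."""

    psnr_db: float | None = None
    variance: float | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.psnr_db is None) == (self.variance is None):
            raise InvalidParameterError("give exactly one of psnr_db or variance")
        if self.variance is not None and self.variance < 0:
            raise InvalidParameterError("variance must be >= 0")

    def sigma2(self, peak_power: float) -> float:
        if self.variance is not None:
            return float(self.variance)
        return psnr_to_variance(self.psnr_db, peak_power)


@dataclass
class MeasurementStack:
    """K x N stack of boundary (or image) frames with acquisition times."""

    frames: np.ndarray
    times: np.ndarray
    background_subtracted: bool = True
    sum_normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 2 or self.frames.shape[0] < 2:
            raise ShapeMismatchError("frames must be K x N with K >= 2")
        if self.times.size != self.frames.shape[0]:
            raise ShapeMismatchError("times length must equal frame count")
        if not np.all(np.isfinite(self.frames)):
            raise InvalidParameterError("frames contain non-finite values")

    @property
    def K(self) -> int:
        return self.frames.shape[0]

    @property
    def N(self) -> int:
        return self.frames.shape[1]


def psnr_to_variance(psnr_db: float, peak_power: float) -> float:
    """sigma^2 = s^2 * 10^(-PSNR/10) for peak clean power s^2."""
    if peak_power <= 0:
        raise InvalidParameterError("peak power must be > 0")
    return peak_power * 10.0 ** (-psnr_db / 10.0)


def render_source_patterns(scene: Scene, system: SystemMatrix) -> np.ndarray:
    """Per-inclusion boundary patterns: A applied to the unit-concentration
    yield indicator of each inclusion.  Returns (P, N)."""
    mesh = system.mesh
    patterns = np.empty((len(scene.inclusions), system.n_measurements))
    for p, inc in enumerate(scene.inclusions):
        d2 = ((mesh.nodes[:, 0] - inc.center[0]) ** 2
              + (mesh.nodes[:, 1] - inc.center[1]) ** 2)
        mask = d2 <= inc.radius ** 2
        if not mask.any():
            raise RasterizationError(
                f"inclusion at {inc.center} covers no mesh node at "
                f"h={scene.edge_len} mm")
        x = np.where(mask, concentration_to_yield(1.0, inc.epsilon, inc.eta), 0.0)
        patterns[p] = system.apply(x)
    return patterns


def simulate_dynamic_measurements(patterns, time_courses, noise: NoiseSpec | None = None,
                                  background=None) -> MeasurementStack:
    """Mix patterns with their time courses: frame k = sum_p c_p(t_k) a_p
    (+ background + noise)."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if len(time_courses) != patterns.shape[0]:
        raise ShapeMismatchError(
            f"{patterns.shape[0]} patterns but {len(time_courses)} time courses")
    times = time_courses[0].times
    for tc in time_courses[1:]:
        if not np.array_equal(tc.times, times):
            raise ShapeMismatchError("all time courses must share one time grid")
    C = np.stack([tc.values for tc in time_courses], axis=1)  # K x P
    frames = C @ patterns
    meta = {}
    subtracted = True
    if background is not None:
        bg = np.broadcast_to(np.asarray(background, dtype=float),
                             (frames.shape[1],)).copy()
        frames = frames + bg[None, :]
        meta["preinjection"] = bg
        subtracted = False
    if noise is not None:
        peak_power = float(np.max(np.abs(C @ patterns)) ** 2)
        sigma2 = noise.sigma2(peak_power)
        rng = np.random.default_rng(noise.seed)
        frames = frames + rng.normal(0.0, np.sqrt(sigma2), size=frames.shape)
        meta["noise_sigma2"] = sigma2
    return MeasurementStack(frames=frames, times=times.copy(),
                            background_subtracted=subtracted, meta=meta)


def subtract_background(stack: MeasurementStack, preinjection_frame) -> MeasurementStack:
    """Remove a static background by subtracting a pre-injection frame.

    Values are not clipped: under noise small negatives are legitimate and
    clipping would bias the affine geometry the separation relies on.
    """
    if stack.background_subtracted:
        raise AlreadySubtractedError("stack is already background-subtracted")
    pre = np.asarray(preinjection_frame, dtype=float)
    if pre.shape != (stack.N,):
        raise ShapeMismatchError(
            f"preinjection frame shape {pre.shape} != (N,) = ({stack.N},)")
    return MeasurementStack(frames=stack.frames - pre[None, :],
                            times=stack.times.copy(),
                            background_subtracted=True,
                            meta={k: v for k, v in stack.meta.items()
                                  if k != "preinjection"})


def make_local_dominant_sources(P: int, N: int, dominance_fraction: float = 0.05,
                                seed: int = 0) -> np.ndarray:
    """P nonnegative patterns with exact local dominance.

    Each source owns a disjoint block of ``max(1, round(f*N))`` pure pixels
    where all other sources are exactly zero; remaining pixels carry
    independent uniform values for every source.
    """
    if not 0 < dominance_fraction < 1.0 / P:
        raise InvalidParameterError("need 0 < dominance_fraction < 1/P")
    k = max(1, int(round(dominance_fraction * N)))
    if N < P * k:
        raise InvalidParameterError(f"N={N} too small for {P} x {k} pure pixels")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    patterns = rng.uniform(0.0, 1.0, size=(P, N))
    for p in range(P):
        pure = perm[p * k:(p + 1) * k]
        patterns[:, pure] = 0.0
        patterns[p, pure] = rng.uniform(0.5, 1.5, size=k)
    return patterns


def check_local_dominance(patterns: np.ndarray) -> bool:
    """True iff every source has a pixel where it is positive and all
    others are exactly zero."""
    patterns = np.atleast_2d(patterns)
    for p in range(patterns.shape[0]):
        others = np.delete(patterns, p, axis=0)
        pure = (patterns[p] > 0) & np.all(others == 0, axis=0)
        if not pure.any():
            return False
    return True


def random_courses(K: int, P: int, seed=0, low: float = 0.1, high: float = 1.0,
                   max_cond: float = 15.0) -> np.ndarray:
    """Random nonnegative K x P course matrix with bounded condition number
    (redrawn until the columns are well separated)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    for _ in range(200):
        C = rng.uniform(low, high, size=(K, P))
        if np.linalg.cond(C) <= max_cond:
            return C
    raise InvalidParameterError("could not draw a well-conditioned course matrix")


def courses_with_correlation(base: TimeCourse, target_r: float, seed: int = 0,
                             label: str = "") -> TimeCourse:
    """Second course whose centered correlation with ``base`` equals
    ``target_r`` (the dial for correlated-kinetics scenes)."""
    if not -1.0 < target_r < 1.0:
        raise InvalidParameterError("target_r must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    b = base.values - base.values.mean()
    nb = np.linalg.norm(b)
    if nb == 0:
        raise InvalidParameterError("base course is constant")
    for _ in range(100):
        w = rng.standard_normal(base.K)
        w -= w.mean()
        w -= (w @ b) / nb**2 * b
        nw = np.linalg.norm(w)
        if nw > 1e-12:
            break
    v = target_r * b / nb + np.sqrt(1.0 - target_r**2) * w / nw
    v = v - v.min() + 0.05  # shift to strictly positive; centering is unaffected
    v *= base.values.max() / v.max()
    return TimeCourse(times=base.times.copy(), values=v, label=label)


# ---------------------------------------------------------------------------
# Image-domain simulation scenes (organ-like sources on a pixel grid)
# ---------------------------------------------------------------------------

def _ellipse(shape, center, radii):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (((xx - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2) <= 1.0


def heart_course() -> TimeCourse:
    """Blood-pool kinetics: immediate peak then exponential washout."""
    return TimeCourse(times=np.array(DEFAULT_TIMES_MIN),
                      values=np.array([1.0, 0.85, 0.70, 0.45, 0.20, 0.05]),
                      label="heart")


def lungs_course() -> TimeCourse:
    """Perfused-organ kinetics: near-immediate filling with a slightly
    delayed peak and slower washout than the blood pool; its temporal
    correlation with the heart course is about 0.8."""
    return TimeCourse(times=np.array(DEFAULT_TIMES_MIN),
                      values=np.array([0.75, 0.88, 0.92, 0.78, 0.50, 0.22]),
                      label="lungs")


def liver_course() -> TimeCourse:
    """Uptake/excretion kinetics, complementary to the blood pool.

    The course is orthogonalized (after centering) against the heart
    course so that its centered temporal correlation with it is exactly
    zero, mirroring an uncorrelated-kinetics study; the projection step
    shrinks the curve's dynamic swing, so the orthogonalized curve is
    rescaled back to the base curve's own centered amplitude.
    """
    h = heart_course().values
    base = np.array([0.20, 0.38, 0.55, 0.80, 0.95, 0.60])
    hc = h - h.mean()
    bc = base - base.mean()
    vc = bc - (np.dot(bc, hc) / np.dot(hc, hc)) * hc
    vc *= np.linalg.norm(bc) / np.linalg.norm(vc)
    v = vc - vc.min() + 0.18  # residual dye keeps late frames above dark
    v *= 1.0 / v.max()
    return TimeCourse(times=np.array(DEFAULT_TIMES_MIN), values=v, label="liver")


def correlated_image_sources(shape=(32, 32)) -> np.ndarray:
    """Two overlapping uniform-intensity organ images (blood pool and an
    adjacent perfused organ sharing a rim region).  The overlap makes the
    sources spatially non-orthogonal, so orthogonality/independence-based
    separation degrades on them, while each organ core still provides
    pure pixels."""
    s1 = _ellipse(shape, center=(13.0, 16.0), radii=(3.2, 4.0)).astype(float)
    s2 = _ellipse(shape, center=(18.0, 15.2), radii=(3.8, 4.6)).astype(float)
    return np.stack([s1.ravel(), s2.ravel()])


def uncorrelated_image_sources(shape=(32, 32)) -> np.ndarray:
    """Two disjoint compact uniform-intensity sources (small dye-filled
    tubes or organs in different body regions, each covering ~1-2% of the
    field of view); spatially near-orthogonal, with exact pure pixels."""
    s1 = _ellipse(shape, center=(shape[1] * 0.25, shape[0] * 0.50),
                  radii=(1.8, 2.2)).astype(float)
    s2 = _ellipse(shape, center=(shape[1] * 0.75, shape[0] * 0.48),
                  radii=(2.0, 2.4)).astype(float)
    return np.stack([s1.ravel(), s2.ravel()])


def simulation_sources(kind: str, shape=None):
    """(patterns, time_courses) for the two canonical dynamic studies.

    ``kind='correlated'``: spatially overlapping organ sources with
    similar kinetics (temporal correlation ~0.8) -- the regime where
    orthogonality/independence assumptions break;
    ``kind='uncorrelated'``: small disjoint sources with complementary,
    temporally orthogonal kinetics -- the regime where every method works.
    Patterns are scaled so the clean mixed frames have peak amplitude 1.
    """
    if kind == "correlated":
        patterns = correlated_image_sources(shape if shape is not None else (32, 32))
        courses = [heart_course(), lungs_course()]
    elif kind == "uncorrelated":
        patterns = uncorrelated_image_sources(shape if shape is not None else (32, 32))
        courses = [heart_course(), liver_course()]
    else:
        raise InvalidParameterError(f"unknown simulation kind {kind!r}")
    C = np.stack([tc.values for tc in courses], axis=1)
    peak = np.max(C @ patterns)
    return patterns / peak, courses
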
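"""Synthetic midsagittal-cervix phantoms and synthetic screening cohorts.

A phantom is a speckle-textured grayscale image containing a bright
glandular band wrapped around a darker curved endocervical canal.  The
canal centerline is an explicit parametric curve (straight segment,
circular arc through three points, or quadratic/cubic Bezier), so the
true chord length, arc length and os endpoints are known analytically
— the test bed against which the segmentation network and the length
calipers are judged.

Cohort generation draws per-subject cervical lengths for the three
measurement methods from group-wise normal models whose defaults mimic
a first-trimester screening population: the traced-arc (AI-line)
length separates term from spontaneous-preterm groups (term
43.3 +/- 9.2 mm vs 38.8 +/- 6.5 mm overall preterm) while the chord-based
single-line and two-line lengths are nearly non-informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .images import CanalMask, UltrasoundImage, as_spacing

CENTERLINE_KINDS = ("straight", "circular_arc", "bezier_quadratic", "bezier_cubic")
_N_CONTROL = {"straight": 2, "circular_arc": 3, "bezier_quadratic": 3, "bezier_cubic": 4}


class CenterlineOutOfViewError(ValueError):
    """The canal centerline (plus margin) leaves the field of view."""


@dataclass
class PhantomSpec:
    """Parametric description of one curved-canal scene.

    Control points are (row_mm, col_mm) positions.  ``circular_arc``
    interprets them as start / on-arc / end; Bezier kinds as the usual
    control polygon.  ``speckle_params`` is (mean background intensity,
    multiplicative noise scale).
    """

    centerline_kind: str
    control_points: Sequence[tuple[float, float]]
    canal_halfwidth_mm: float = 1.5
    gland_band_mm: float = 2.5
    pixel_spacing_mm: float = 0.2
    image_shape_px: tuple[int, int] = (256, 512)
    speckle_params: tuple[float, float] = (0.45, 0.25)
    seed: int = 0

    def __post_init__(self):
        if self.centerline_kind not in CENTERLINE_KINDS:
            raise ValueError(
                f"unknown centerline kind {self.centerline_kind!r}; "
                f"expected one of {CENTERLINE_KINDS}"
            )
        need = _N_CONTROL[self.centerline_kind]
        self.control_points = [tuple(map(float, p)) for p in self.control_points]
        if len(self.control_points) != need:
            raise ValueError(
                f"{self.centerline_kind} needs {need} control points, "
                f"got {len(self.control_points)}"
            )
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.canal_halfwidth_mm < 2 * self.pixel_spacing_mm:
            raise ValueError(
                "canal_halfwidth_mm must be >= 2 * pixel_spacing_mm so the "
                "canal is resolvable"
            )
        if self.gland_band_mm <= 0:
            raise ValueError("gland_band_mm must be positive")
        self._check_margin()

    @property
    def fov_mm(self) -> tuple[float, float]:
        r, c = self.image_shape_px
        return ((r - 1) * self.pixel_spacing_mm, (c - 1) * self.pixel_spacing_mm)

    def _check_margin(self):
        margin = self.gland_band_mm
        fr, fc = self.fov_mm
        for i, (pr, pc) in enumerate(self.control_points):
            if not (margin <= pr <= fr - margin and margin <= pc <= fc - margin):
                raise CenterlineOutOfViewError(
                    f"control point {i} at ({pr:.2f}, {pc:.2f}) mm violates the "
                    f"{margin:.2f} mm margin inside the {fr:.1f} x {fc:.1f} mm field of view"
                )


# ---------------------------------------------------------------------------
# parametric centerline
# ---------------------------------------------------------------------------

def _circle_through(p0, p1, p2):
    """Circumcenter and radius of three non-collinear points."""
    a, b, c = (np.asarray(p, float) for p in (p0, p1, p2))
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if abs(d) < 1e-12:
        raise ValueError("circular_arc control points are collinear")
    ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
    uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
    center = np.array([ux, uy])
    return center, float(np.linalg.norm(a - center))


def _arc_angles(spec):
    p0, pm, p1 = spec.control_points
    center, radius = _circle_through(p0, pm, p1)
    th0 = np.arctan2(p0[1] - center[1], p0[0] - center[0])
    thm = np.arctan2(pm[1] - center[1], pm[0] - center[0])
    th1 = np.arctan2(p1[1] - center[1], p1[0] - center[0])
    # choose sweep direction so the mid point lies on the traversed arc
    ccw = (thm - th0) % (2 * np.pi)
    ccw_end = (th1 - th0) % (2 * np.pi)
    if ccw <= ccw_end:
        sweep = ccw_end
    else:
        sweep = ccw_end - 2 * np.pi
    return center, radius, th0, sweep


def centerline_point(spec: PhantomSpec, t):
    """Curve position r(t) in mm for t in [0, 1]; vectorised over t."""
    t = np.atleast_1d(np.asarray(t, float))
    cps = [np.asarray(p, float) for p in spec.control_points]
    if spec.centerline_kind == "straight":
        p0, p1 = cps
        out = p0 + t[:, None] * (p1 - p0)
    elif spec.centerline_kind == "circular_arc":
        center, radius, th0, sweep = _arc_angles(spec)
        th = th0 + t * sweep
        out = center + radius * np.stack([np.cos(th), np.sin(th)], axis=1)
    elif spec.centerline_kind == "bezier_quadratic":
        p0, p1, p2 = cps
        u = (1 - t)[:, None]
        tt = t[:, None]
        out = u * u * p0 + 2 * u * tt * p1 + tt * tt * p2
    else:  # bezier_cubic
        p0, p1, p2, p3 = cps
        u = (1 - t)[:, None]
        tt = t[:, None]
        out = (u ** 3 * p0 + 3 * u ** 2 * tt * p1 + 3 * u * tt ** 2 * p2 + tt ** 3 * p3)
    return out


def centerline_speed(spec: PhantomSpec, t):
    """|r'(t)| in mm, from the closed-form derivative of each kind."""
    t = np.atleast_1d(np.asarray(t, float))
    cps = [np.asarray(p, float) for p in spec.control_points]
    if spec.centerline_kind == "straight":
        p0, p1 = cps
        return np.full(t.shape, float(np.linalg.norm(p1 - p0)))
    if spec.centerline_kind == "circular_arc":
        _, radius, _, sweep = _arc_angles(spec)
        return np.full(t.shape, radius * abs(sweep))
    if spec.centerline_kind == "bezier_quadratic":
        p0, p1, p2 = cps
        d = 2 * (1 - t)[:, None] * (p1 - p0) + 2 * t[:, None] * (p2 - p1)
        return np.linalg.norm(d, axis=1)
    p0, p1, p2, p3 = cps
    u = (1 - t)[:, None]
    tt = t[:, None]
    d = 3 * u ** 2 * (p1 - p0) + 6 * u * tt * (p2 - p1) + 3 * tt ** 2 * (p3 - p2)
    return np.linalg.norm(d, axis=1)


def true_arc_length(spec: PhantomSpec) -> float:
    """Arc length of the parametric centerline via adaptive quadrature
    (relative error well below 1e-6)."""
    val, _ = integrate.quad(
        lambda t: float(centerline_speed(spec, t)[0]), 0.0, 1.0,
        epsabs=1e-10, epsrel=1e-10, limit=200,
    )
    return float(val)


def true_chord_length(spec: PhantomSpec) -> float:
    ends = centerline_point(spec, [0.0, 1.0])
    return float(np.linalg.norm(ends[1] - ends[0]))


@dataclass
class GroundTruth:
    """Analytic geometry of a phantom: straight internal-to-external-os
    distance, centerline arc length, and key pixel coordinates."""

    chord_mm: float
    arc_mm: float
    os_internal_px: tuple[float, float]
    os_external_px: tuple[float, float]
    apex_px: tuple[float, float]

    def __post_init__(self):
        if self.arc_mm < self.chord_mm - 1e-9:
            raise ValueError("arc length cannot be shorter than the chord")


def generate_phantom(spec: PhantomSpec):
    """Render one phantom: (UltrasoundImage, CanalMask, GroundTruth).

    The mask is every pixel within ``canal_halfwidth_mm`` of the
    centerline; the image shows a bright glandular band of thickness
    ``gland_band_mm`` around the darker canal on a multiplicative
    speckle background.  Identical spec (including seed) gives
    bit-identical rasters.
    """
    rows, cols = spec.image_shape_px
    sp = spec.pixel_spacing_mm

    arc = true_arc_length(spec)
    chord = true_chord_length(spec)
    n_samples = max(1024, int(4 * arc / sp) + 1)
    t = np.linspace(0.0, 1.0, n_samples)
    pts = centerline_point(spec, t)

    margin = spec.gland_band_mm
    fr, fc = spec.fov_mm
    bad = (
        (pts[:, 0] < margin) | (pts[:, 0] > fr - margin)
        | (pts[:, 1] < margin) | (pts[:, 1] > fc - margin)
    )
    if np.any(bad):
        k = int(np.argmax(bad))
        cp = np.asarray(spec.control_points, float)
        nearest = int(np.argmin(np.linalg.norm(cp - pts[k], axis=1)))
        raise CenterlineOutOfViewError(
            f"centerline exits the field of view near control point {nearest} "
            f"(curve position {tuple(np.round(pts[k], 2))} mm)"
        )

    rr, cc = np.meshgrid(np.arange(rows) * sp, np.arange(cols) * sp, indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()])
    dist = cKDTree(pts).query(grid, workers=1)[0].reshape(rows, cols)

    mask = (dist <= spec.canal_halfwidth_mm).astype(np.uint8)

    bg_mean, noise_scale = spec.speckle_params
    intensity = np.full((rows, cols), bg_mean, dtype=np.float64)
    gland = (dist > spec.canal_halfwidth_mm) & (
        dist <= spec.canal_halfwidth_mm + spec.gland_band_mm
    )
    intensity[gland] = 0.85
    intensity[dist <= spec.canal_halfwidth_mm] = 0.18
    intensity = gaussian_filter(intensity, sigma=1.0)

    rng = np.random.default_rng(spec.seed)
    speckle = rng.rayleigh(scale=np.sqrt(2.0 / np.pi), size=(rows, cols))
    speckle = gaussian_filter(speckle, sigma=0.7)
    img = intensity * (1.0 - noise_scale + noise_scale * speckle)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    ends = centerline_point(spec, [0.0, 1.0])
    chord_vec = ends[1] - ends[0]
    chord_norm = np.linalg.norm(chord_vec)
    if chord_norm < 1e-12:
        apex_mm = pts[len(pts) // 2]
    else:
        rel = pts - ends[0]
        perp = np.abs(rel[:, 0] * chord_vec[1] - rel[:, 1] * chord_vec[0]) / chord_norm
        apex_mm = pts[int(np.argmax(perp))]

    def to_px(p):
        return (float(p[0] / sp), float(p[1] / sp))

    truth = GroundTruth(
        chord_mm=chord,
        arc_mm=arc,
        os_internal_px=to_px(ends[0]),
        os_external_px=to_px(ends[1]),
        apex_px=to_px(apex_mm),
    )
    image_id = f"phantom-{spec.centerline_kind}-{spec.seed}"
    return (
        UltrasoundImage(img, sp, image_id=image_id),
        CanalMask(mask, sp, image_id=image_id),
        truth,
    )


def random_phantom_spec(
    rng: np.random.Generator,
    image_shape_px: tuple[int, int] = (64, 128),
    pixel_spacing_mm: float = 0.35,
    kinds: Sequence[str] = ("circular_arc", "bezier_quadratic", "bezier_cubic"),
) -> PhantomSpec:
    """Draw a random in-view curved canal for training/evaluation sets.

    Curves run roughly left-to-right across the frame with a random
    vertical bow, mimicking the span of a midsagittal canal.
    """
    rows, cols = image_shape_px
    fr, fc = (rows - 1) * pixel_spacing_mm, (cols - 1) * pixel_spacing_mm
    halfwidth = float(rng.uniform(2.0, 2.8)) * pixel_spacing_mm
    gland = float(rng.uniform(2.5, 4.0)) * pixel_spacing_mm
    margin = gland + halfwidth + pixel_spacing_mm
    kind = str(rng.choice(list(kinds)))

    col0 = float(rng.uniform(margin, 0.25 * fc))
    col1 = float(rng.uniform(0.75 * fc, fc - margin))
    row0 = float(rng.uniform(0.3 * fr, 0.7 * fr))
    row1 = float(rng.uniform(0.3 * fr, 0.7 * fr))
    bow = float(rng.uniform(-0.28, 0.28)) * fr

    def clamp_row(v):
        return float(np.clip(v, margin, fr - margin))

    if kind == "circular_arc":
        mid = (clamp_row(0.5 * (row0 + row1) + bow), 0.5 * (col0 + col1))
        cps = [(row0, col0), mid, (row1, col1)]
    elif kind == "bezier_quadratic":
        # control point may overshoot; keep its hull inside the margin
        cps = [(row0, col0),
               (clamp_row(0.5 * (row0 + row1) + 2 * bow), 0.5 * (col0 + col1)),
               (row1, col1)]
    else:
        cps = [(row0, col0),
               (clamp_row(row0 + 1.5 * bow), col0 + (col1 - col0) / 3),
               (clamp_row(row1 + 1.5 * bow), col0 + 2 * (col1 - col0) / 3),
               (row1, col1)]
    return PhantomSpec(
        centerline_kind=kind,
        control_points=cps,
        canal_halfwidth_mm=halfwidth,
        gland_band_mm=gland,
        pixel_spacing_mm=pixel_spacing_mm,
        image_shape_px=image_shape_px,
        speckle_params=(0.45, 0.25),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


# ---------------------------------------------------------------------------
# synthetic screening cohorts
# ---------------------------------------------------------------------------

GROUPS = ("term", "sptb_32_36", "sptb_lt32")

#: Default group-wise (mean, SD) in mm per measurement method.  The
#: traced-arc method carries the real group separation; the chord-based
#: methods are nearly non-informative, reflecting how a curved canal
#: hides its true length from straight-line calipers.
DEFAULT_EFFECT_MODEL: dict[str, dict[str, tuple[float, float]]] = {
    "cl_single_mm": {
        "term": (33.6, 3.6), "sptb_32_36": (33.2, 3.5), "sptb_lt32": (33.4, 1.2),
    },
    "cl_two_mm": {
        "term": (36.9, 4.6), "sptb_32_36": (36.6, 4.5), "sptb_lt32": (35.4, 2.8),
    },
    "cl_ai_mm": {
        "term": (43.3, 9.2), "sptb_32_36": (38.9, 6.9), "sptb_lt32": (37.3, 1.9),
    },
}

MIN_CL_MM = 5.0  # draws truncated to physically plausible lengths


@dataclass
class ScreeningCohort:
    """Per-subject measurement table plus the generating parameters.

    ``table`` columns: subject_id, ga_weeks, cl_single_mm, cl_two_mm,
    cl_ai_mm, outcome, and the adjustment covariates age, bmi, parity,
    prior_ptb_or_surgery.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"subject_id", "ga_weeks", "cl_single_mm", "cl_two_mm",
                    "cl_ai_mm", "outcome"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cohort table missing columns {sorted(missing)}")
        bad = set(self.table["outcome"].unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown outcome labels {sorted(bad)}")
        for col in ("cl_single_mm", "cl_two_mm", "cl_ai_mm"):
            if np.any(self.table[col].to_numpy() <= 0):
                raise ValueError(f"{col} contains non-positive lengths")

    def group(self, name: str) -> pd.DataFrame:
        return self.table[self.table["outcome"] == name]

    @property
    def n(self) -> int:
        return len(self.table)


def _clark_max_moments(m1, s1, m2, s2, r):
    """Mean and SD of max(X1, X2) for correlated normals (Clark, 1961)."""
    from scipy.stats import norm

    th2 = s1 * s1 + s2 * s2 - 2.0 * r * s1 * s2
    if th2 < 1e-12:
        return max(m1, m2), max(s1, s2)
    th = np.sqrt(th2)
    a = (m1 - m2) / th
    big, small = norm.cdf(a), norm.pdf(a)
    eb = m1 * big + m2 * (1.0 - big) + th * small
    eb2 = (
        (m1 * m1 + s1 * s1) * big
        + (m2 * m2 + s2 * s2) * (1.0 - big)
        + (m1 + m2) * th * small
    )
    return eb, float(np.sqrt(max(eb2 - eb * eb, 0.0)))


def _arc_from_chords(single, two, ms, mt, ma, rho, rng):
    """Arc draws >= max(chords) with moments matched to model ``ma``."""
    from scipy.stats import norm, rankdata

    base = np.maximum(single, two)
    n = base.size
    mb, sb = _clark_max_moments(*ms, *mt, rho)
    mean_exc = ma[0] - mb
    var_exc = ma[1] ** 2 - sb ** 2
    if var_exc > 1e-9 and mean_exc > 1e-9:
        k = mean_exc * mean_exc / var_exc
        return base + rng.gamma(k, var_exc / mean_exc, n)
    if mean_exc > 1e-9 and var_exc <= 1e-9:
        # requested arc variance no larger than the chord-max variance:
        # deterministic quantile map onto the target normal, floored at
        # the chord max so the ordering never breaks
        if sb > 1e-9 and ma[1] > 0:
            q = (rankdata(base, method="average") - 0.5) / n
            return np.maximum(base, norm.ppf(q, ma[0], ma[1]))
        return np.maximum(base, ma[0] + ma[1] * rng.standard_normal(n))
    # requested arc mean does not exceed the chord-max mean: arcs hug
    # their chords
    return base.copy()


def generate_cohort(
    n_term: int,
    n_32_36: int,
    n_lt32: int,
    effect_model: dict | None = None,
    seed: int = 0,
    method_correlation: float = 0.8,
) -> ScreeningCohort:
    """Draw a synthetic screening cohort from group-wise normal models.

    The chord methods measure the same cervix, so their draws share a
    latent per-subject factor (correlation ``method_correlation``).
    The traced-arc value is built structurally as
    ``max(single, two) + excess`` with a nonnegative gamma excess whose
    parameters are calibrated (via Clark's moments of the max of two
    correlated normals) so the arc's mean and SD match the requested
    model; when the requested arc SD is smaller than the SD of the
    chord maximum, a rank-based quantile map to the target normal is
    used instead.  Either way every subject satisfies arc >= chords
    exactly while group moments track the stated parameters.  Lengths
    are truncated at > 5 mm.  Reproducible for a fixed seed.
    """
    sizes = {"term": int(n_term), "sptb_32_36": int(n_32_36), "sptb_lt32": int(n_lt32)}
    if any(v < 0 for v in sizes.values()):
        raise ValueError("group sizes must be nonnegative")
    if sum(sizes.values()) == 0:
        raise ValueError("at least one group must be non-empty")
    if not (0.0 <= method_correlation < 1.0):
        raise ValueError("method_correlation must lie in [0, 1)")
    model = effect_model or DEFAULT_EFFECT_MODEL
    rho = method_correlation
    rng = np.random.default_rng(seed)

    frames = []
    sid = 0
    for grp, n in sizes.items():
        if n == 0:
            continue
        z = rng.standard_normal(n)
        cols = {}
        for m in ("cl_single_mm", "cl_two_mm"):
            mean, sd = model[m][grp]
            e = rng.standard_normal(n)
            draw = mean + sd * (rho * z + np.sqrt(1.0 - rho * rho) * e)
            cols[m] = np.maximum(draw, MIN_CL_MM + 1e-6)
        ai = _arc_from_chords(
            cols["cl_single_mm"], cols["cl_two_mm"],
            model["cl_single_mm"][grp], model["cl_two_mm"][grp],
            model["cl_ai_mm"][grp], rho, rng,
        )
        cols["cl_ai_mm"] = np.maximum(ai, MIN_CL_MM + 1e-6)
        frames.append(pd.DataFrame({
            "subject_id": [f"S{sid + i:05d}" for i in range(n)],
            "ga_weeks": np.clip(rng.normal(12.6, 0.5, n), 11.0, 14.0),
            "cl_single_mm": cols["cl_single_mm"],
            "cl_two_mm": cols["cl_two_mm"],
            "cl_ai_mm": cols["cl_ai_mm"],
            "outcome": grp,
            "age": rng.normal(32.8, 4.7, n),
            "bmi": np.clip(rng.normal(22.3, 3.0, n), 15.0, None),
            "parity": (rng.random(n) < 0.41).astype(int),
            "prior_ptb_or_surgery": (rng.random(n) < 0.055).astype(int),
        }))
        sid += n
    table = pd.concat(frames, ignore_index=True)
    params = {"sizes": sizes, "effect_model": model, "seed": seed,
              "method_correlation": rho}
    return ScreeningCohort(table=table, params=params)
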
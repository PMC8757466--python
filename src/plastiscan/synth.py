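"""Synthetic polymer/matrix IR spectra and full hyperspectral test scenes.

Emulates, at desk scale, the spectral pathologies that make microplastics
pixel classification hard in FPA-uFTIR transmission measurements:

* **Beer-Lambert band structure** — each class has a fixed set of
  Lorentzian absorption bands scaled by a dimensionless thickness factor.
* **Total absorption (TA)** — thick particles saturate: modeled as a
  smooth exponential approach to a ceiling absorbance, which first shifts
  relative peak ratios and ultimately flattens the spectrum.
* **Mie-type baseline distortion** — an additive low-frequency sinusoid
  plus a linear baseline slope.
* **Noise** — i.i.d. Gaussian absorbance noise per band.

The 21 polymer band tables below are curated *synthetic* templates: their
band positions are loosely inspired by characteristic vibrations (C-H
stretches near 2850-2950 cm^-1, carbonyls near 1700-1740 cm^-1, ...) but
are chosen to be mutually distinguishable ground truth for testing — they
are not a spectral library and make no claim of per-polymer spectroscopic
accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classes import CLASS_IDS, SUBSTRATE, class_index
from .envi import HyperspectralImage, WavenumberAxis, default_axis

__all__ = [
    "PeakSpec",
    "PolymerTemplate",
    "DistortionSpec",
    "DistortionRanges",
    "EllipseShape",
    "FiberShape",
    "PlantedParticle",
    "SceneSpec",
    "builtin_templates",
    "random_scene_spec",
    "synth_spectrum",
    "synth_scene",
    "make_reference_library",
]


@dataclass(frozen=True)
class PeakSpec:
    """One absorption band: center (cm^-1), HWHM width (cm^-1), height (AU)."""

    center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.height < 0:
            raise ValueError("peak height must be non-negative")


@dataclass(frozen=True)
class PolymerTemplate:
    """Band table of one class; ``baseline_level`` is a flat offset in AU."""

    class_id: str
    peaks: tuple[PeakSpec, ...]
    baseline_level: float = 0.0

    def __post_init__(self) -> None:
        if self.class_id not in CLASS_IDS:
            raise ValueError(f"unknown class id '{self.class_id}'")
        if self.class_id != "Other" and len(self.peaks) == 0:
            raise ValueError("polymer templates need at least one peak")


@dataclass(frozen=True)
class DistortionSpec:
    """Concrete distortion applied to one spectrum (or one particle).

    mie_amplitude/mie_period/mie_phase parameterize the additive sinusoid
    emulating Mie baseline oscillation; baseline_slope is AU per cm^-1;
    ta_ceiling is the saturation absorbance of the total-absorption model;
    noise_sigma is the per-band Gaussian noise level in AU.
    """

    mie_amplitude: float = 0.0
    mie_period: float = 1000.0
    mie_phase: float = 0.0
    baseline_slope: float = 0.0
    ta_ceiling: float = math.inf
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mie_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("mie_amplitude and noise_sigma must be >= 0")
        if not self.ta_ceiling > 0:
            raise ValueError("ta_ceiling must be positive")
        if self.mie_period <= 0:
            raise ValueError("mie_period must be positive")


@dataclass(frozen=True)
class DistortionRanges:
    """Uniform sampling ranges for per-spectrum/per-particle distortion draws.

    Defaults describe a moderately adverse measurement: baseline
    oscillations up to ~0.08 AU (comparable to weak bands), saturation
    ceilings of 1.5-2.5 AU as seen for thick particles in transmission,
    and 0.008 AU rms noise.
    """

    mie_amplitude: tuple[float, float] = (0.0, 0.08)
    mie_period: tuple[float, float] = (600.0, 1500.0)
    mie_phase: tuple[float, float] = (0.0, 2.0 * math.pi)
    baseline_slope: tuple[float, float] = (-2e-5, 2e-5)
    ta_ceiling: tuple[float, float] = (1.5, 2.5)
    noise_sigma: float = 0.008

    def draw(self, rng: np.random.Generator) -> DistortionSpec:
        u = lambda lo_hi: float(rng.uniform(*lo_hi))
        return DistortionSpec(
            mie_amplitude=u(self.mie_amplitude),
            mie_period=u(self.mie_period),
            mie_phase=u(self.mie_phase),
            baseline_slope=u(self.baseline_slope),
            ta_ceiling=u(self.ta_ceiling),
            noise_sigma=self.noise_sigma,
        )


# --------------------------------------------------------------------------
# built-in templates

def _t(cid: str, *bands: tuple[float, float, float]) -> PolymerTemplate:
    return PolymerTemplate(cid, tuple(PeakSpec(*b) for b in bands))


_TEMPLATES: tuple[PolymerTemplate, ...] = (
    # (center cm^-1, HWHM cm^-1, height AU)
    _t("PP", (2950, 18, 0.75), (2918, 16, 0.60), (1455, 14, 0.40), (1376, 10, 0.45)),
    _t("PE", (2915, 14, 0.85), (2848, 13, 0.65), (1472, 10, 0.35)),
    _t("PVC", (2912, 20, 0.45), (1427, 16, 0.50), (1331, 12, 0.35), (1254, 14, 0.55)),
    _t("PU", (3330, 40, 0.40), (2940, 22, 0.40), (1730, 18, 0.60), (1530, 20, 0.50)),
    _t("PET", (2960, 24, 0.25), (1715, 16, 0.90), (1410, 14, 0.35), (1340, 12, 0.30)),
    _t("PS", (3026, 14, 0.45), (2920, 18, 0.50), (1601, 8, 0.40), (1493, 10, 0.55)),
    _t("ABS", (2922, 18, 0.55), (2237, 10, 0.30), (1602, 8, 0.35), (1494, 10, 0.40)),
    _t("PA", (3298, 45, 0.55), (2932, 20, 0.45), (1638, 18, 0.80), (1545, 18, 0.60)),
    _t("PC", (2968, 18, 0.35), (1770, 14, 0.80), (1503, 10, 0.55), (1409, 10, 0.30)),
    _t("PMMA", (2995, 18, 0.35), (2950, 16, 0.40), (1728, 14, 0.95), (1434, 12, 0.45)),
    _t("CA", (3480, 60, 0.30), (2940, 22, 0.30), (1742, 16, 0.85), (1368, 12, 0.45)),
    _t("EVAc", (2920, 16, 0.70), (2850, 14, 0.50), (1738, 14, 0.55), (1370, 10, 0.30)),
    _t("EVOH", (3340, 55, 0.60), (2918, 16, 0.55), (2850, 14, 0.40), (1330, 14, 0.30)),
    _t("PAN", (2938, 18, 0.45), (2243, 8, 0.65), (1452, 12, 0.40)),
    _t("PBT", (2960, 20, 0.30), (1712, 15, 0.85), (1458, 12, 0.30), (1268, 14, 0.45)),
    _t("PEEK", (3064, 16, 0.25), (1651, 12, 0.55), (1594, 12, 0.60), (1488, 10, 0.65)),
    _t("POM", (2980, 22, 0.45), (2920, 18, 0.40), (1470, 14, 0.25), (1383, 10, 0.35)),
    _t("PPSU", (3070, 18, 0.30), (1585, 10, 0.55), (1487, 10, 0.60), (1323, 12, 0.50)),
    _t("PSU", (2968, 16, 0.40), (1586, 10, 0.50), (1504, 10, 0.55), (1294, 12, 0.55)),
    _t("silicone", (2963, 14, 0.50), (1412, 10, 0.25), (1261, 8, 0.85)),
    _t("PLA", (2997, 16, 0.30), (2946, 14, 0.30), (1751, 14, 0.90), (1453, 10, 0.35)),
    # broad-band bio-organic / mineral matrix stand-in
    _t("Other", (3400, 180, 0.35), (2925, 60, 0.30), (1640, 90, 0.40), (1420, 120, 0.30)),
)


def builtin_templates() -> tuple[PolymerTemplate, ...]:
    """The 22 built-in class templates (21 polymers + ``Other``), Table order."""
    return _TEMPLATES


# --------------------------------------------------------------------------
# spectrum synthesis

def synth_spectrum(
    template: PolymerTemplate,
    thickness: float,
    distortion: DistortionSpec,
    axis: WavenumberAxis | None = None,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Simulate one observed absorbance spectrum.

    The ideal spectrum is ``A_ideal(v) = thickness * sum_k L_k(v) +
    baseline_level`` with Lorentzian bands ``L_k``; the observed spectrum
    saturates smoothly toward the TA ceiling,

        ``A_obs = c * (1 - exp(-A_ideal / c))  (+ Mie term + noise)``,

    so that for thin particles ``A_obs ~ A_ideal`` while for thick ones all
    bands converge to ``c`` and peak-height ratios drift toward 1.
    Deterministic for a fixed seed.
    """
    if axis is None:
        axis = default_axis()
    if len(axis) == 0:
        raise ValueError("empty wavenumber axis")
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    v = axis.values
    ideal = np.full(v.shape, template.baseline_level, dtype=float)
    if thickness > 0:
        for p in template.peaks:
            ideal += thickness * p.height * p.width**2 / ((v - p.center) ** 2 + p.width**2)

    c = distortion.ta_ceiling
    if math.isinf(c):
        observed = ideal.copy()
    else:
        observed = c * -np.expm1(-ideal / c)

    if distortion.mie_amplitude != 0.0:
        observed += distortion.mie_amplitude * np.sin(
            2.0 * math.pi * v / distortion.mie_period + distortion.mie_phase
        )
    if distortion.baseline_slope != 0.0:
        observed += distortion.baseline_slope * (v - axis.lo)
    if distortion.noise_sigma > 0.0:
        observed += rng.normal(0.0, distortion.noise_sigma, size=v.shape)
    return observed


# --------------------------------------------------------------------------
# scenes

@dataclass(frozen=True)
class EllipseShape:
    """Filled ellipse: center (row, col) in pixels, semi-axes, angle in degrees."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_deg: float = 0.0

    def rasterize(self, rows: int, cols: int) -> np.ndarray:
        rr, cc = np.mgrid[0:rows, 0:cols]
        dr = rr - self.center[0]
        dc = cc - self.center[1]
        th = math.radians(self.angle_deg)
        # major axis measured from the row direction (along increasing col)
        u = dc * math.cos(th) + dr * math.sin(th)
        w = -dc * math.sin(th) + dr * math.cos(th)
        a, b = self.semi_axes
        mask = (u / a) ** 2 + (w / b) ** 2 <= 1.0
        return np.argwhere(mask)


@dataclass(frozen=True)
class FiberShape:
    """One-pixel-wide fiber: center (row, col), length in pixels, angle in degrees."""

    center: tuple[float, float]
    length: float
    angle_deg: float = 0.0

    def rasterize(self, rows: int, cols: int) -> np.ndarray:
        th = math.radians(self.angle_deg)
        n = max(2, int(math.ceil(self.length * 4)))
        t = np.linspace(-(self.length - 1) / 2.0, (self.length - 1) / 2.0, n)
        r = np.rint(self.center[0] + t * math.sin(th)).astype(int)
        c = np.rint(self.center[1] + t * math.cos(th)).astype(int)
        # walk the sampled path inserting a bridge pixel on diagonal steps so
        # the fiber is edge-connected (4-connectivity), like a physical fiber
        # wider than the sampling grid
        path: list[tuple[int, int]] = [(int(r[0]), int(c[0]))]
        for rr, cc in zip(r[1:], c[1:]):
            pr, pc = path[-1]
            if (rr, cc) == (pr, pc):
                continue
            if rr != pr and cc != pc:
                path.append((int(rr), pc))
            path.append((int(rr), int(cc)))
        pix = np.unique(np.asarray(path, dtype=int), axis=0)
        keep = (pix[:, 0] >= 0) & (pix[:, 0] < rows) & (pix[:, 1] >= 0) & (pix[:, 1] < cols)
        return pix[keep]


@dataclass(frozen=True)
class PlantedParticle:
    template: PolymerTemplate
    shape: EllipseShape | FiberShape
    thickness: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for a synthetic scene with ground truth.

    Background (filter substrate after background correction) is pure
    Gaussian noise around zero absorbance. Each planted particle carries
    its class spectrum under a single per-particle distortion draw, with
    per-pixel noise on top; overlaps are resolved by draw order (later
    wins). ``matrix_fraction`` is the share matrix/(matrix+particle) of
    non-substrate pixels covered by blobs of the ``Other`` class.
    """

    rows: int = 64
    cols: int = 64
    pixel_pitch: float = 11.0
    particles: tuple[PlantedParticle, ...] = ()
    matrix_fraction: float = 0.0
    distortion: DistortionRanges = field(default_factory=DistortionRanges)
    background_sigma: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.matrix_fraction < 1.0):
            raise ValueError("matrix_fraction must be in [0, 1)")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("scene must have at least one pixel")


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene."""

    label_map: np.ndarray               # (rows, cols) int, SUBSTRATE/-1 background
    particles: list[dict]               # id, class_id, pixels (n,2) array
    matrix_pixels: np.ndarray           # (m, 2) pixel coordinates of matrix blobs


def synth_scene(spec: SceneSpec) -> tuple[HyperspectralImage, SceneTruth]:
    """Render a scene spec into a cube plus ground-truth labels/particles."""
    rng = np.random.default_rng(spec.seed)
    axis = default_axis()
    n_bands = len(axis)
    cube = rng.standard_normal((spec.rows, spec.cols, n_bands), dtype=np.float32)
    cube *= spec.background_sigma
    labels = np.full((spec.rows, spec.cols), SUBSTRATE, dtype=np.int16)
    owner = np.full((spec.rows, spec.cols), -1, dtype=np.int32)

    for k, planted in enumerate(spec.particles):
        pix = planted.shape.rasterize(spec.rows, spec.cols)
        if len(pix) == 0:
            continue
        dist = spec.distortion.draw(rng)
        base = synth_spectrum(
            planted.template, planted.thickness,
            replace(dist, noise_sigma=0.0), axis, seed=rng,
        )
        noise = rng.normal(0.0, dist.noise_sigma, size=(len(pix), n_bands))
        cube[pix[:, 0], pix[:, 1], :] = (base[None, :] + noise).astype(np.float32)
        labels[pix[:, 0], pix[:, 1]] = class_index(planted.template.class_id)
        owner[pix[:, 0], pix[:, 1]] = k

    # matrix blobs of the "Other" class on free background pixels
    matrix_pix: list[np.ndarray] = []
    n_particle = int(np.sum(owner >= 0))
    if spec.matrix_fraction > 0.0 and n_particle > 0:
        other = next(t for t in _TEMPLATES if t.class_id == "Other")
        target = spec.matrix_fraction / (1.0 - spec.matrix_fraction) * n_particle
        n_matrix = 0
        while n_matrix < target:
            cr = rng.uniform(0, spec.rows)
            cc = rng.uniform(0, spec.cols)
            rad = rng.uniform(1.0, 3.0)
            blob = EllipseShape((cr, cc), (rad, rad)).rasterize(spec.rows, spec.cols)
            blob = blob[labels[blob[:, 0], blob[:, 1]] == SUBSTRATE]
            if len(blob) == 0:
                continue
            dist = spec.distortion.draw(rng)
            base = synth_spectrum(other, float(rng.uniform(0.5, 1.5)),
                                  replace(dist, noise_sigma=0.0), axis, seed=rng)
            noise = rng.normal(0.0, dist.noise_sigma, size=(len(blob), n_bands))
            cube[blob[:, 0], blob[:, 1], :] = (base[None, :] + noise).astype(np.float32)
            labels[blob[:, 0], blob[:, 1]] = class_index("Other")
            matrix_pix.append(blob)
            n_matrix += len(blob)

    particles = []
    next_id = 1
    for k, planted in enumerate(spec.particles):
        pix = np.argwhere(owner == k)
        if len(pix) == 0:
            continue  # fully overpainted by a later particle
        particles.append({
            "id": next_id,
            "class_id": planted.template.class_id,
            "pixels": pix,
        })
        next_id += 1

    truth = SceneTruth(
        label_map=labels,
        particles=particles,
        matrix_pixels=(np.concatenate(matrix_pix) if matrix_pix
                       else np.empty((0, 2), dtype=int)),
    )
    img = HyperspectralImage(cube=cube, axis=axis, pixel_pitch=spec.pixel_pitch)
    return img, truth


def _edge_connected(pixels: np.ndarray) -> bool:
    pix = {tuple(p) for p in np.asarray(pixels, dtype=int)}
    stack = [next(iter(pix))]
    seen = {stack[0]}
    while stack:
        r, c = stack.pop()
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in pix and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(pix)


def random_scene_spec(
    n_particles: int,
    rows: int = 256,
    cols: int = 256,
    seed: int = 0,
    *,
    class_ids: tuple[str, ...] | None = None,
    matrix_fraction: float = 0.0,
    distortion: DistortionRanges | None = None,
) -> SceneSpec:
    """Scene spec with ``n_particles`` well-separated random particles.

    The image is divided into a grid of cells and each particle (random
    ellipse or one-pixel fiber) is planted near the center of its own
    cell, so particles never touch and per-class counts are unambiguous.
    Classes cycle through ``class_ids`` (default: all polymer classes).
    """
    if class_ids is None:
        class_ids = tuple(c for c in CLASS_IDS if c != "Other")
    rng = np.random.default_rng(seed)
    per_side = int(math.ceil(math.sqrt(n_particles)))
    cell_r, cell_c = rows / per_side, cols / per_side
    if min(cell_r, cell_c) < 14:
        raise ValueError("image too small to separate that many particles")
    cells = [(i, j) for i in range(per_side) for j in range(per_side)]
    order = rng.permutation(len(cells))[:n_particles]

    by_id = {t.class_id: t for t in _TEMPLATES}
    planted = []
    for k, ci in enumerate(order):
        i, j = cells[ci]
        # redraw until the rasterized shape is non-empty and edge-connected,
        # so the planted truth is recoverable as a single particle
        for _ in range(50):
            cr = (i + 0.5) * cell_r + rng.uniform(-1.5, 1.5)
            cc = (j + 0.5) * cell_c + rng.uniform(-1.5, 1.5)
            if rng.uniform() < 0.3:
                shape: EllipseShape | FiberShape = FiberShape(
                    (cr, cc), length=float(rng.uniform(5, 11)),
                    angle_deg=float(rng.uniform(0, 180)),
                )
            else:
                a = float(rng.uniform(1.5, 4.5))
                b = float(rng.uniform(1.2, a))
                shape = EllipseShape((cr, cc), (a, b),
                                     angle_deg=float(rng.uniform(0, 180)))
            pix = shape.rasterize(rows, cols)
            if len(pix) >= 3 and _edge_connected(pix):
                break
        template = by_id[class_ids[k % len(class_ids)]]
        planted.append(PlantedParticle(
            template=template, shape=shape,
            thickness=float(rng.uniform(0.6, 1.8)),
        ))
    return SceneSpec(
        rows=rows, cols=cols, particles=tuple(planted),
        matrix_fraction=matrix_fraction, seed=int(rng.integers(0, 2**31 - 1)),
        distortion=distortion if distortion is not None else DistortionRanges(),
    )


# --------------------------------------------------------------------------
# reference libraries

def make_reference_library(
    templates: tuple[PolymerTemplate, ...] | None = None,
    n_per_class: int = 100,
    thickness_range: tuple[float, float] = (0.5, 2.0),
    distortion: DistortionRanges | None = None,
    seed: int = 0,
    *,
    mimic_paper_balance: bool = False,
    total: int | None = None,
    axis: WavenumberAxis | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate a labeled reference spectra set.

    Returns ``(X, y)`` with spectra as rows and integer class codes. By
    default the set is balanced with ``n_per_class`` spectra per template.
    With ``mimic_paper_balance=True`` and a ``total`` budget, half the
    budget goes to the ``Other`` matrix class and the rest is split evenly
    over the polymer classes — mirroring a reference set in which half the
    spectra represent matrix rather than microplastics.
    """
    if templates is None:
        templates = _TEMPLATES
    if distortion is None:
        distortion = DistortionRanges()
    if axis is None:
        axis = default_axis()
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)

    counts: dict[str, int] = {}
    if mimic_paper_balance:
        if total is None:
            total = n_per_class * len(templates)
        n_other = total // 2
        polymers = [t for t in templates if t.class_id != "Other"]
        if not polymers:
            raise ValueError("balanced library needs at least one polymer class")
        per_poly = (total - n_other) // len(polymers)
        extra = (total - n_other) - per_poly * len(polymers)
        for i, t in enumerate(polymers):
            counts[t.class_id] = per_poly + (1 if i < extra else 0)
        counts["Other"] = n_other
    else:
        counts = {t.class_id: n_per_class for t in templates}

    X_rows: list[np.ndarray] = []
    y_rows: list[int] = []
    for t in templates:
        n = counts.get(t.class_id, 0)
        for _ in range(n):
            d = distortion.draw(rng)
            thick = float(rng.uniform(*thickness_range))
            X_rows.append(synth_spectrum(t, thick, d, axis, seed=rng))
            y_rows.append(class_index(t.class_id))
    return np.asarray(X_rows), np.asarray(y_rows, dtype=np.int64)
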
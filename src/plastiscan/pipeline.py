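"""Four-step hyperspectral image analysis for microplastics.

1. **Substrate detection** — filter-background pixels carry no spectral
   information after background correction; they are found statistically
   from the per-pixel spectral standard deviation and excluded.
2. **Pixel classification** — the forest assigns every remaining pixel to
   one of the 22 classes, with the winning vote fraction kept as a
   per-pixel reliability.
3. **Lateral post-processing** — a modal filter over each pixel's
   8-neighborhood cleans up isolated misclassifications using the
   information of neighboring pixels.
4. **Particle detection & characterization** — 4-connected (edge-sharing)
   same-class components become particles with geometric descriptors
   (length, width, aspect ratio, area, orientation) and a reliability.

Programmatic particle editing (merging fiber fragments, adding/removing
pixels) supports the dual-control step in which an analyst corrects
particles that agglomeration, overlap or total absorption split or
truncated.

Pixel coordinates are (row, col), 0-based, origin top-left; orientation is
the major-axis angle against the image row direction in degrees, folded
to [0, 180).
"""

from __future__ import annotations

import csv
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .classes import CLASS_IDS, SUBSTRATE, class_index, class_name
from .envi import HyperspectralImage
from .forest import RDFModel, preprocess_spectrum

__all__ = [
    "Particle",
    "ParticleTable",
    "PipelineConfig",
    "detect_substrate",
    "classify_pixels",
    "lateral_postprocess",
    "detect_particles",
    "characterize_particle",
    "merge_particles",
    "edit_particle_pixels",
    "run_pipeline",
    "export_csv",
    "read_csv",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class PipelineConfig:
    """Tunables of the four analysis steps.

    ``substrate_k`` scales the robust threshold median + k*MAD on the
    per-pixel spectral standard deviation (default 3); ``passes`` is the
    number of modal-filter iterations (default 1); ``min_pixels`` drops
    components smaller than the given pixel count (default 1: keep all);
    ``reliability_after_postprocess`` recomputes particle reliability from
    the post-processed map instead of the raw classification.
    """

    substrate_k: float = 3.0
    passes: int = 1
    min_pixels: int = 1
    pixel_pitch: float | None = None
    reliability_after_postprocess: bool = False

    def __post_init__(self) -> None:
        if self.substrate_k < 0:
            raise ValueError("substrate_k must be >= 0")
        if self.passes < 0 or self.min_pixels < 1:
            raise ValueError("passes >= 0 and min_pixels >= 1 required")


# --------------------------------------------------------------------------
# step 1: substrate detection

def detect_substrate(img: HyperspectralImage, k: float = 3.0) -> np.ndarray:
    """Boolean background mask: True where the pixel is filter substrate.

    Uses the spectral standard deviation per pixel as signal score; a
    pixel is substrate iff score <= median + k*MAD over the image. The
    substrate set is non-shrinking in ``k``.
    """
    score = np.std(np.asarray(img.cube, dtype=np.float64), axis=2)
    med = float(np.median(score))
    mad = float(np.median(np.abs(score - med)))
    if math.isinf(k):
        return np.ones(score.shape, dtype=bool)
    return score <= med + k * mad


# --------------------------------------------------------------------------
# step 2: pixel classification

def classify_pixels(
    model: RDFModel, img: HyperspectralImage, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Label every non-substrate pixel; returns (label map, probability map).

    The label map holds class codes with SUBSTRATE (-1) for masked pixels;
    the probability map holds the winning vote fraction (NaN on substrate).
    """
    rows, cols, _ = img.shape
    labels = np.full((rows, cols), SUBSTRATE, dtype=np.int16)
    probs = np.full((rows, cols), np.nan, dtype=np.float64)
    keep = ~np.asarray(mask, dtype=bool)
    if keep.any():
        spectra = np.asarray(img.cube[keep], dtype=np.float64)
        if len(model.axis) != spectra.shape[1] or not np.allclose(
            model.axis.values, img.axis.values
        ):
            spectra = preprocess_spectrum(spectra, img.axis, model.axis,
                                          model.preprocess)
            spectra = np.atleast_2d(spectra)
        votes = model.predict_proba(spectra)
        labels[keep] = np.argmax(votes, axis=1)
        probs[keep] = np.max(votes, axis=1)
    return labels, probs


# --------------------------------------------------------------------------
# step 3: lateral post-processing

def lateral_postprocess(labelmap: np.ndarray, passes: int = 1) -> np.ndarray:
    """Modal filter on the label map; substrate is never created nor consumed.

    Per pass (synchronous update), each non-substrate pixel takes the
    modal class among the non-substrate labels of its 8-neighborhood plus
    itself. If the current label ties for the mode it is kept; a tie
    between other classes goes to the earlier class in class order.
    """
    labels = np.asarray(labelmap).copy()
    n_classes = len(CLASS_IDS)
    kernel = np.ones((3, 3), dtype=np.float64)  # includes the center pixel
    for _ in range(passes):
        counts = np.zeros(labels.shape + (n_classes,), dtype=np.float64)
        for c in range(n_classes):
            counts[:, :, c] = ndimage.convolve(
                (labels == c).astype(np.float64), kernel, mode="constant", cval=0.0
            )
        best = np.argmax(counts, axis=2)          # earliest class on ties
        best_count = np.take_along_axis(
            counts, best[:, :, None], axis=2
        )[:, :, 0]
        fg = labels != SUBSTRATE
        cur = np.where(fg, labels, 0)
        cur_count = np.take_along_axis(counts, cur[:, :, None], axis=2)[:, :, 0]
        new = np.where(cur_count >= best_count, labels, best)
        labels = np.where(fg, new, SUBSTRATE).astype(labels.dtype)
    return labels


# --------------------------------------------------------------------------
# step 4: particle detection & characterization

@dataclass
class Particle:
    """A connected same-class pixel set with geometric descriptors.

    ``area`` in um^2, ``length``/``width`` in um (center span plus one
    pixel pitch, so a single pixel has length = width = pitch),
    ``orientation`` in degrees in [0, 180) against the row direction.
    """

    id: int
    class_id: str
    pixels: np.ndarray              # (n, 2) row, col
    area: float
    length: float
    width: float
    aspect_ratio: float
    orientation: float
    centroid: tuple[float, float]
    reliability: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass
class ParticleTable:
    """Detected particles plus the context needed for editing operations."""

    particles: list[Particle] = field(default_factory=list)
    pixel_pitch: float = 11.0

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    def get(self, particle_id: int) -> Particle:
        for p in self.particles:
            if p.id == particle_id:
                return p
        raise KeyError(f"no particle with id {particle_id}")

    def next_id(self) -> int:
        return 1 + max((p.id for p in self.particles), default=0)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.particles:
            counts[p.class_id] = counts.get(p.class_id, 0) + 1
        return counts


def detect_particles(labelmap: np.ndarray, min_pixels: int = 1) -> list[dict]:
    """Connected components (4-connectivity, per class) of a label map.

    Returns raw components as dicts with keys ``class_code`` and
    ``pixels``; components smaller than ``min_pixels`` are dropped. Ids
    are implied by list position: components are ordered by the raster
    position of their first (topmost, then leftmost) pixel.
    """
    labels = np.asarray(labelmap)
    comps: list[dict] = []
    for c in np.unique(labels):
        if c == SUBSTRATE:
            continue
        lab, n = ndimage.label(labels == c, structure=_FOUR_CONN)
        for i in range(1, n + 1):
            pix = np.argwhere(lab == i)
            if len(pix) >= min_pixels:
                comps.append({"class_code": int(c), "pixels": pix})
    comps.sort(key=lambda d: (int(d["pixels"][0, 0]), int(d["pixels"][0, 1])))
    return comps


def characterize_particle(
    pixels: np.ndarray,
    pitch: float,
    probmap: np.ndarray | None = None,
    *,
    particle_id: int = 0,
    class_id: str = "Other",
) -> Particle:
    """Fill in geometry and reliability for a pixel set.

    Centroid and second moments are computed on pixel centers; length and
    width are the spans of the projections on the principal axes plus one
    pitch, so geometry degrades gracefully to pitch x pitch for a single
    pixel. With isotropic moments the orientation is defined as 0.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or len(pixels) == 0:
        raise ValueError("particle pixel set must be a non-empty (n, 2) array")
    centroid = pixels.mean(axis=0)
    centered = pixels - centroid

    # second-moment matrix in (col, row) so angle is against the row direction
    xy = centered[:, ::-1]
    cov = xy.T @ xy / len(xy)
    evals, evecs = np.linalg.eigh(cov)       # ascending eigenvalues
    if math.isclose(evals[0], evals[1], rel_tol=0.0, abs_tol=1e-12):
        major = np.array([1.0, 0.0])
        minor = np.array([0.0, 1.0])
    else:
        major = evecs[:, 1]
        minor = evecs[:, 0]

    span_major = float(np.ptp(xy @ major)) if len(xy) > 1 else 0.0
    span_minor = float(np.ptp(xy @ minor)) if len(xy) > 1 else 0.0
    length = span_major * pitch + pitch
    width = span_minor * pitch + pitch
    if width > length:                      # guard: ptp on discrete grids
        length, width = width, length
        major = minor

    angle = math.degrees(math.atan2(major[1], major[0])) % 180.0
    if math.isclose(evals[0], evals[1], rel_tol=0.0, abs_tol=1e-12):
        angle = 0.0

    if probmap is not None:
        rel = float(np.nanmean(probmap[pixels[:, 0].astype(int),
                                       pixels[:, 1].astype(int)]))
    else:
        rel = float("nan")

    return Particle(
        id=particle_id,
        class_id=class_id,
        pixels=np.asarray(pixels, dtype=int),
        area=len(pixels) * pitch**2,
        length=length,
        width=width,
        aspect_ratio=length / width,
        orientation=angle,
        centroid=(float(centroid[0]), float(centroid[1])),
        reliability=rel,
    )


def _is_connected(pixels: np.ndarray) -> bool:
    pix = {tuple(p) for p in np.asarray(pixels, dtype=int)}
    if not pix:
        return False
    stack = [next(iter(pix))]
    seen = {stack[0]}
    while stack:
        r, c = stack.pop()
        for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if nb in pix and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(pix)


def merge_particles(
    table: ParticleTable,
    ids: list[int],
    bridge_pixels: np.ndarray | None = None,
    probmap: np.ndarray | None = None,
) -> ParticleTable:
    """Merge particles of one class (e.g. fragments of a fiber) into one.

    Optional operator-supplied bridge pixels are added to the union;
    geometry and reliability are recomputed, a fresh id is assigned and
    the old ids retired. Raises on unknown ids or mixed classes.
    """
    members = [table.get(i) for i in ids]
    if len({p.class_id for p in members}) != 1:
        raise ValueError("cannot merge particles of different classes")
    union = [p.pixels for p in members]
    if bridge_pixels is not None and len(bridge_pixels):
        union.append(np.asarray(bridge_pixels, dtype=int).reshape(-1, 2))
    pixels = np.unique(np.concatenate(union, axis=0), axis=0)
    merged = characterize_particle(
        pixels, table.pixel_pitch, probmap,
        particle_id=table.next_id(), class_id=members[0].class_id,
    )
    if probmap is None:
        # preserve pixel-weighted reliability when no map is available
        w = sum(p.n_pixels * p.reliability for p in members)
        merged.reliability = w / sum(p.n_pixels for p in members)
    keep = [p for p in table.particles if p.id not in set(ids)]
    return ParticleTable(particles=keep + [merged], pixel_pitch=table.pixel_pitch)


def edit_particle_pixels(
    table: ParticleTable,
    particle_id: int,
    add: np.ndarray | None = None,
    remove: np.ndarray | None = None,
    labelmap: np.ndarray | None = None,
    probmap: np.ndarray | None = None,
    *,
    on_split: str = "error",
) -> ParticleTable:
    """Add and/or remove pixels of one particle, keeping geometry consistent.

    If the removal disconnects the particle, ``on_split='error'`` rejects
    the edit while ``on_split='split'`` re-labels the fragments as
    separate particles. If a ``labelmap`` is passed it is updated in place
    (added pixels take the particle's class, removed ones SUBSTRATE).
    """
    if on_split not in ("error", "split"):
        raise ValueError("on_split must be 'error' or 'split'")
    p = table.get(particle_id)
    pix = {tuple(q) for q in p.pixels}
    added = {tuple(q) for q in np.asarray(add, dtype=int).reshape(-1, 2)} if add is not None else set()
    removed = {tuple(q) for q in np.asarray(remove, dtype=int).reshape(-1, 2)} if remove is not None else set()
    new_pix = (pix | added) - removed
    if not new_pix:
        raise ValueError("edit would remove every pixel of the particle")

    arr = np.asarray(sorted(new_pix), dtype=int)
    fragments = [arr]
    if not _is_connected(arr):
        if on_split == "error":
            raise ValueError("edit disconnects the particle; pass on_split='split'")
        lab = np.zeros(arr.max(axis=0) + 1, dtype=bool)
        lab[arr[:, 0], arr[:, 1]] = True
        cc, n = ndimage.label(lab, structure=_FOUR_CONN)
        fragments = [np.argwhere(cc == i) for i in range(1, n + 1)]

    code = class_index(p.class_id)
    if labelmap is not None:
        for r, c in removed & pix:
            labelmap[r, c] = SUBSTRATE
        for r, c in added:
            labelmap[r, c] = code

    keep = [q for q in table.particles if q.id != particle_id]
    next_id = 1 + max((q.id for q in keep), default=0)
    out = list(keep)
    for frag in fragments:
        part = characterize_particle(frag, table.pixel_pitch, probmap,
                                     particle_id=next_id, class_id=p.class_id)
        if probmap is None:
            part.reliability = p.reliability
        out.append(part)
        next_id += 1
    return ParticleTable(particles=out, pixel_pitch=table.pixel_pitch)


# --------------------------------------------------------------------------
# composition & export

def run_pipeline(
    img: HyperspectralImage,
    model: RDFModel,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[ParticleTable, np.ndarray, np.ndarray, dict[str, int]]:
    """Run the four analysis steps on a cube.

    Returns (particle table, post-processed label map, probability map,
    per-class particle counts). Reliability is averaged from the vote
    fractions of the raw classification unless configured otherwise.
    """
    pitch = config.pixel_pitch if config.pixel_pitch is not None else img.pixel_pitch
    mask = detect_substrate(img, config.substrate_k)
    labels_raw, probs = classify_pixels(model, img, mask)
    labels = lateral_postprocess(labels_raw, config.passes)
    if config.reliability_after_postprocess:
        # keep vote fractions only where the post-processed label agrees
        probs_for_rel = np.where(labels == labels_raw, probs, np.nan)
    else:
        probs_for_rel = probs
    comps = detect_particles(labels, config.min_pixels)
    particles = [
        characterize_particle(
            comp["pixels"], pitch, probs_for_rel,
            particle_id=i + 1, class_id=class_name(comp["class_code"]),
        )
        for i, comp in enumerate(comps)
    ]
    table = ParticleTable(particles=particles, pixel_pitch=pitch)
    return table, labels, probs, table.class_counts()


_CSV_COLUMNS = (
    "id", "class", "n_pixels", "area_um2", "length_um", "width_um",
    "aspect_ratio", "orientation_deg", "centroid_row", "centroid_col",
    "reliability",
)


def export_csv(table: ParticleTable, path: str | os.PathLike) -> None:
    """Write the particle list as an RFC-4180 CSV with a header row."""
    tmp = os.fspath(path) + ".tmp"
    with open(tmp, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for p in table.particles:
            writer.writerow([
                p.id, p.class_id, p.n_pixels,
                f"{p.area:.6f}", f"{p.length:.6f}", f"{p.width:.6f}",
                f"{p.aspect_ratio:.6f}", f"{p.orientation:.6f}",
                f"{p.centroid[0]:.6f}", f"{p.centroid[1]:.6f}",
                f"{p.reliability:.6f}",
            ])
    os.replace(tmp, path)


def read_csv(path: str | os.PathLike) -> list[dict]:
    """Read back an exported particle list (numeric fields as floats)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        rows = []
        for rec in reader:
            out: dict = {"id": int(rec["id"]), "class": rec["class"],
                         "n_pixels": int(rec["n_pixels"])}
            for key in _CSV_COLUMNS[3:]:
                out[key] = float(rec[key])
            rows.append(out)
        return rows
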
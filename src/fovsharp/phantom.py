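"""Digital leg-CT phantoms and FOV-dependent reconstruction simulation.

A phantom is a 2-D cross-section of a lower extremity — soft-tissue body
ellipse, cortical bone circles, contrast-filled vessel circles of
femoral-to-pedal calibre, and mural calcification arcs — extruded along z
(with optional vessel taper).  ``simulate_reconstruction`` images the
phantom the way a CT reconstruction with a given field of view (FOV) does:
a fixed detector-limited Gaussian point-spread function, area averaging
over the voxel aperture (``fov_diameter / matrix`` mm), and additive
Gaussian noise.  Because the matrix is fixed at 512, a larger FOV means a
larger voxel aperture and hence a blurrier image — the physical effect the
sharpness metric measures.

The rating simulator draws ordinal 1–5 image-quality scores from a
discretised latent-normal model whose default per-segment moments are the
published per-segment Likert means and standard deviations
(:data:`LIKERT_MOMENTS`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .ct_io import AIR_HU, CTVolume, GridGeometry, in_plane_voxel_size

__all__ = [
    "Ellipse",
    "Circle",
    "CalcificationArc",
    "PhantomSpec",
    "ReconSpec",
    "RatingSpec",
    "RenderError",
    "CoverageError",
    "LIKERT_MOMENTS",
    "LEVELS",
    "SIDES",
    "FOVS",
    "LARGE_FOV_MM",
    "SMALL_FOV_MM",
    "render_phantom",
    "simulate_reconstruction",
    "simulate_pair",
    "simulate_ratings",
    "random_phantom_spec",
]

LEVELS: tuple[str, ...] = ("femoral", "popliteal", "crural", "pedal")
SIDES: tuple[str, ...] = ("right", "left")
FOVS: tuple[str, ...] = ("large", "small")

#: Default paired reconstruction FOV diameters (mm): a two-leg "full-body"
#: FOV versus a single-leg FOV, at a fixed 512 matrix.
LARGE_FOV_MM: float = 423.0
SMALL_FOV_MM: float = 220.0

#: Published per-segment Likert moments (mean, sd) by (level, fov) — the
#: calibration of the rating simulator.
LIKERT_MOMENTS: dict[tuple[str, str], tuple[float, float]] = {
    ("femoral", "large"): (4.02, 0.65),
    ("femoral", "small"): (4.70, 0.48),
    ("popliteal", "large"): (3.82, 0.63),
    ("popliteal", "small"): (4.65, 0.52),
    ("crural", "large"): (3.06, 0.72),
    ("crural", "small"): (4.18, 0.72),
    ("pedal", "large"): (2.79, 0.73),
    ("pedal", "small"): (3.87, 0.82),
}


class RenderError(ValueError):
    """Phantom structure falls outside the rendering grid."""


class CoverageError(ValueError):
    """Reconstruction grid does not cover the phantom."""


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    hu: float = 40.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        a, b = self.semi_axes
        return ((x - self.center[0]) / a) ** 2 + ((y - self.center[1]) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class Circle:
    center: tuple[float, float]
    radius: float
    hu: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.center[0]) ** 2 + (y - self.center[1]) ** 2 <= self.radius**2


@dataclass(frozen=True)
class CalcificationArc:
    """Mural calcification: an angular arc straddling a vessel wall."""

    vessel_index: int
    angle_start_deg: float
    angle_extent_deg: float
    thickness: float  # radial thickness in mm
    hu: float = 800.0

    def contains_on(self, vessel: Circle, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx = x - vessel.center[0]
        dy = y - vessel.center[1]
        r = np.hypot(dx, dy)
        radial = np.abs(r - vessel.radius) <= self.thickness / 2.0
        ang = np.degrees(np.arctan2(dy, dx)) % 360.0
        rel = (ang - self.angle_start_deg) % 360.0
        return radial & (rel <= self.angle_extent_deg)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric anatomy of one leg cross-section.

    Rendering layers structures in listed order (later wins):
    body, bones, vessels, calcifications.
    """

    body: Ellipse
    bones: tuple[Circle, ...] = ()
    vessels: tuple[Circle, ...] = ()
    calcifications: tuple[CalcificationArc, ...] = ()
    background_hu: float = AIR_HU
    vessel_taper: float = 0.0  # fractional radius shrink from first to last slice

    def __post_init__(self) -> None:
        for v in self.vessels:
            if not (0.3 <= v.radius <= 6.0):
                raise ValueError(
                    f"vessel radius {v.radius} mm outside the femoral-to-pedal "
                    "calibre range [0.3, 6.0] mm"
                )
        for s in (*self.bones, *self.vessels):
            if not self._circle_in_body(s):
                raise ValueError(f"structure {s} not inside the body ellipse")
        for c in self.calcifications:
            if not 0 <= c.vessel_index < len(self.vessels):
                raise ValueError("calcification references a missing vessel")
        if not 0 <= self.vessel_taper < 1:
            raise ValueError("vessel_taper must be in [0, 1)")

    def _circle_in_body(self, c: Circle) -> bool:
        ang = np.linspace(0, 2 * math.pi, 32, endpoint=False)
        x = c.center[0] + c.radius * np.cos(ang)
        y = c.center[1] + c.radius * np.sin(ang)
        return bool(np.all(self.body.contains(x, y)))


@dataclass(frozen=True)
class ReconSpec:
    """FOV-dependent reconstruction parameters.

    ``psf_fwhm`` is the detector-limited intrinsic in-plane resolution
    (FOV-independent); the FOV enters through the voxel aperture
    ``fov_diameter / matrix`` over which the signal is area-averaged.
    """

    fov_diameter: float
    matrix: int = 512
    n_slices: int = 6
    slice_spacing: float = 0.4
    psf_fwhm: float = 0.6
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm <= 0:
            raise ValueError("psf_fwhm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def voxel_size(self) -> float:
        return in_plane_voxel_size(self.fov_diameter, self.matrix)


@dataclass(frozen=True)
class RatingSpec:
    """Latent-normal ordinal rating model for the reader study.

    ``moments`` maps (level, fov) to the latent (mean, sd) on the 1–5
    Likert scale; defaults are the published per-segment moments.
    """

    n_exams: int = 100
    n_readers: int = 3
    moments: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(LIKERT_MOMENTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for key, (m, s) in self.moments.items():
            if not (1.0 <= m <= 5.0):
                raise ValueError(f"latent mean {m} for {key} outside [1, 5]")
            if s <= 0:
                raise ValueError(f"latent sd must be > 0, got {s} for {key}")
        if self.n_exams < 1 or self.n_readers < 1:
            raise ValueError("n_exams and n_readers must be >= 1")


def render_phantom(
    spec: PhantomSpec,
    oversample_spacing: float = 0.1,
    n_slices: int = 6,
    slice_spacing: float = 0.4,
    margin: float = 12.0,
) -> CTVolume:
    """Render the ground-truth phantom on a high-resolution grid.

    The grid covers the body ellipse plus ``margin`` mm of air on all
    sides, centred on the body centre.  Each voxel takes the HU of the
    last-listed structure containing its centre.
    """
    if oversample_spacing > 0.1:
        raise ValueError("oversample_spacing must be <= 0.1 mm")
    a, b = spec.body.semi_axes
    half = max(a, b) + margin
    n = int(math.ceil(2 * half / oversample_spacing))
    if n % 2 == 0:
        n += 1  # odd so the central voxel sits exactly on the body centre
    geom = GridGeometry.from_fov(
        n * oversample_spacing,
        n,
        n_slices,
        slice_spacing,
        center=(spec.body.center[0], spec.body.center[1], 0.0),
    )
    x = geom.voxel_centers(0)[:, None]
    y = geom.voxel_centers(1)[None, :]
    lo_x, hi_x = x.min(), x.max()
    lo_y, hi_y = y.min(), y.max()
    for s in (*spec.bones, *spec.vessels):
        if not (
            lo_x <= s.center[0] - s.radius
            and s.center[0] + s.radius <= hi_x
            and lo_y <= s.center[1] - s.radius
            and s.center[1] + s.radius <= hi_y
        ):
            raise RenderError(f"structure {s} outside the rendering grid")

    base = np.full((n, n), spec.background_hu, dtype=np.float64)
    base[spec.body.contains(x, y)] = spec.body.hu
    for bone in spec.bones:
        base[bone.contains(x, y)] = bone.hu

    vol = np.empty((n, n, n_slices), dtype=np.float64)
    for k in range(n_slices):
        sl = base.copy()
        scale = 1.0
        if spec.vessel_taper > 0 and n_slices > 1:
            scale = 1.0 - spec.vessel_taper * k / (n_slices - 1)
        scaled = [
            Circle(v.center, v.radius * scale, v.hu) for v in spec.vessels
        ]
        for v in scaled:
            sl[v.contains(x, y)] = v.hu
        for c in spec.calcifications:
            sl[c.contains_on(scaled[c.vessel_index], x, y)] = c.hu
        vol[:, :, k] = sl
    return CTVolume(vol, geom, identifier="phantom-truth")


def _box_kernel(width_px: float) -> np.ndarray:
    """Odd-length separable kernel averaging over a box of fractional width."""
    if width_px <= 1.0:
        return np.array([1.0])
    half = (width_px - 1.0) / 2.0
    m = int(math.ceil(half))
    k = np.ones(2 * m + 1)
    frac = 1.0 - (m - half)  # weight of the partially covered end pixels
    k[0] = k[-1] = frac
    return k / k.sum()


def simulate_reconstruction(truth: CTVolume, recon: ReconSpec) -> CTVolume:
    """Image a ground-truth phantom at a given reconstruction FOV.

    Pipeline: (1) in-plane Gaussian PSF blur of FWHM ``psf_fwhm``;
    (2) area-average over the voxel aperture (box of width
    ``fov_diameter/matrix``) and sample on the 512-matrix grid centred on
    the phantom; (3) add zero-mean Gaussian noise, seeded.  The effective
    in-plane blur FWHM is ~``sqrt(psf_fwhm**2 + voxel_size**2)``, so a
    larger FOV yields a blurrier reconstruction.
    """
    dx, dy = truth.geometry.in_plane_spacing
    voxel = recon.voxel_size
    # phantom must fit inside the reconstruction FOV
    truth_extent = truth.geometry.fov_diameter
    if truth_extent > recon.fov_diameter:
        raise CoverageError(
            f"phantom extent {truth_extent:.1f} mm exceeds FOV {recon.fov_diameter} mm"
        )
    if recon.n_slices != truth.geometry.n_slices or not math.isclose(
        recon.slice_spacing, truth.geometry.slice_spacing
    ):
        raise CoverageError("reconstruction z-grid must match the truth z-grid")
    if max(dx, dy) > voxel / 2.0:
        raise ValueError(
            f"truth spacing {max(dx, dy)} mm too coarse for target voxel {voxel} mm"
        )

    sigma_px = recon.psf_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / dx
    blurred = ndimage.gaussian_filter(
        truth.values, sigma=(sigma_px, sigma_px * dx / dy, 0.0),
        mode="constant", cval=AIR_HU,
    )
    kx = _box_kernel(voxel / dx)
    ky = _box_kernel(voxel / dy)
    blurred = ndimage.convolve1d(blurred, kx, axis=0, mode="constant", cval=AIR_HU)
    blurred = ndimage.convolve1d(blurred, ky, axis=1, mode="constant", cval=AIR_HU)

    cx = truth.geometry.origin[0] + dx * (truth.geometry.shape[0] - 1) / 2.0
    cy = truth.geometry.origin[1] + dy * (truth.geometry.shape[1] - 1) / 2.0
    geom = GridGeometry.from_fov(
        recon.fov_diameter,
        recon.matrix,
        recon.n_slices,
        recon.slice_spacing,
        center=(cx, cy, truth.geometry.origin[2]
                + recon.slice_spacing * (recon.n_slices - 1) / 2.0),
    )
    ix = (geom.voxel_centers(0) - truth.geometry.origin[0]) / dx
    iy = (geom.voxel_centers(1) - truth.geometry.origin[1]) / dy
    gx, gy = np.meshgrid(ix, iy, indexing="ij")
    out = np.empty(geom.shape, dtype=np.float64)
    coords = np.stack([gx.ravel(), gy.ravel()])
    for k in range(geom.n_slices):
        out[:, :, k] = ndimage.map_coordinates(
            blurred[:, :, k], coords, order=1, mode="constant", cval=AIR_HU
        ).reshape(gx.shape)
    if recon.noise_sd > 0:
        rng = np.random.default_rng(recon.seed)
        out += rng.normal(0.0, recon.noise_sd, size=out.shape)
    return CTVolume(out, geom, identifier=f"recon-fov{recon.fov_diameter:g}")


def simulate_pair(
    spec: PhantomSpec,
    fov_large: float = LARGE_FOV_MM,
    fov_small: float = SMALL_FOV_MM,
    n_slices: int = 6,
    slice_spacing: float = 0.4,
    psf_fwhm: float = 0.6,
    noise_sd: float = 10.0,
    seed: int = 0,
    oversample_spacing: float = 0.1,
) -> tuple[CTVolume, CTVolume, CTVolume]:
    """Render a phantom and reconstruct it at two FOVs from one acquisition.

    Returns ``(truth, large_fov_recon, small_fov_recon)``.  The two
    reconstructions share the phantom and z-grid and differ only in FOV —
    the paired-reconstruction scenario the sharpness comparison targets.
    """
    truth = render_phantom(spec, oversample_spacing, n_slices, slice_spacing)
    common = dict(n_slices=n_slices, slice_spacing=slice_spacing,
                  psf_fwhm=psf_fwhm, noise_sd=noise_sd)
    large = simulate_reconstruction(
        truth, ReconSpec(fov_diameter=fov_large, seed=seed * 2 + 1, **common)
    )
    small = simulate_reconstruction(
        truth, ReconSpec(fov_diameter=fov_small, seed=seed * 2 + 2, **common)
    )
    return truth, large, small


def random_phantom_spec(seed: int) -> PhantomSpec:
    """Draw a plausible random leg cross-section.

    Body semi-axes 45–65 mm; one or two bones (tibia/fibula calibre,
    radius 8–14 mm); three to five contrast-filled vessels (radius
    0.8–4 mm); up to two mural calcification arcs.
    """
    rng = np.random.default_rng(seed)
    a = rng.uniform(50.0, 65.0)
    b = rng.uniform(45.0, a)
    body = Ellipse((0.0, 0.0), (a, b), hu=40.0)

    def sample_inside(radius: float, placed: list[Circle], tries: int = 200):
        for _ in range(tries):
            ang = rng.uniform(0, 2 * math.pi)
            rr = math.sqrt(rng.uniform(0, 1)) * 0.75
            x = rr * (a - radius - 3.0) * math.cos(ang)
            y = rr * (b - radius - 3.0) * math.sin(ang)
            if all(
                math.hypot(x - c.center[0], y - c.center[1]) > radius + c.radius + 2.0
                for c in placed
            ):
                return (x, y)
        raise RuntimeError("could not place structure")

    placed: list[Circle] = []
    bones = []
    for _ in range(int(rng.integers(1, 3))):
        r = rng.uniform(8.0, 14.0)
        bones.append(Circle(sample_inside(r, placed), r, hu=1200.0))
        placed.append(bones[-1])
    vessels = []
    for _ in range(int(rng.integers(3, 6))):
        r = rng.uniform(0.8, 4.0)
        vessels.append(Circle(sample_inside(r, placed), r, hu=350.0))
        placed.append(vessels[-1])
    calcs = []
    big = [i for i, v in enumerate(vessels) if v.radius >= 2.0]
    for i in big[: int(rng.integers(0, 3))]:
        calcs.append(
            CalcificationArc(
                vessel_index=i,
                angle_start_deg=float(rng.uniform(0, 360)),
                angle_extent_deg=float(rng.uniform(60, 150)),
                thickness=float(rng.uniform(0.6, 1.2)),
            )
        )
    return PhantomSpec(
        body=body,
        bones=tuple(bones),
        vessels=tuple(vessels),
        calcifications=tuple(calcs),
        vessel_taper=float(rng.uniform(0.0, 0.15)),
    )


def simulate_ratings(spec: RatingSpec) -> pd.DataFrame:
    """Draw an ordinal reader-rating table from the latent-normal model.

    For each (exam, side, level, fov, reader) cell a latent normal draw
    with the cell's (mean, sd) is rounded half-up to the nearest integer
    and clipped to [1, 5].  A score of 1 is flagged non-diagnostic.
    Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    keys = [
        (exam, side, level, fov)
        for exam in range(1, spec.n_exams + 1)
        for side in SIDES
        for level in LEVELS
        for fov in FOVS
    ]
    for exam, side, level, fov in keys:
        mean, sd = spec.moments[(level, fov)]
        latent = rng.normal(mean, sd, size=spec.n_readers)
        score = np.clip(np.floor(latent + 0.5), 1, 5).astype(int)
        for reader in range(1, spec.n_readers + 1):
            rows.append((exam, side, level, fov, reader, int(score[reader - 1])))
    df = pd.DataFrame(
        rows, columns=["exam", "side", "level", "fov", "reader", "score"]
    )
    df["non_diagnostic"] = df["score"] == 1
    return df
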
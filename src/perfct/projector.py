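"""Equiangular fan-beam projection and the counting-noise model.

The system matrix is assembled once per scan geometry by Siddon ray tracing
(exact ray/pixel intersection lengths) and cached as a ``scipy.sparse`` CSR
matrix, so forward projection and its exact adjoint back-projection are
sparse mat-vecs.  Line integrals are dimensionless (attenuation in cm^-1
times path length in cm).

Noise follows the Beer-Lambert counting model: surviving photons are
``I = I0 * exp(-P)``, a Poisson draw with that mean plus Gaussian readout
noise gives the measured counts, non-positive counts are clamped to one
before the log, and the noisy line integral is ``ln(I0 / counts)``.

Coordinate conventions: the image center sits at the isocenter, x to the
right and y up; pixel (row, col) = (0, 0) is the top-left corner.  The x-ray
source rotates on a circle of radius ``source_to_iso``; detector elements are
spread equiangularly on an arc centered on the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

MM_TO_CM = 0.1


@dataclass(frozen=True)
class ScanGeometry:
    """Equiangular fan-beam acquisition description.

    Defaults correspond to the full-scale acquisition (1000 views over 360
    degrees, 377 arc detectors, 570/470 mm source/detector distances); the
    fan half-angle is derived so the fan covers the image-inscribed circle
    with a one-bin margin.
    """

    n_views: int = 1000
    angular_range: float = 360.0      # degrees
    n_detectors: int = 377
    source_to_iso: float = 570.0      # mm
    iso_to_detector: float = 470.0    # mm
    grid_size: int = 256
    pixel_spacing: float = 1.0        # mm

    def __post_init__(self):
        if self.n_views < 1 or self.n_detectors < 2:
            raise ValueError("need at least 1 view and 2 detectors")
        if self.fov_radius >= self.source_to_iso:
            raise ValueError("source must lie outside the field of view")

    @property
    def fov_radius(self) -> float:
        """Radius of the image-inscribed circle, mm."""
        return self.grid_size * self.pixel_spacing / 2.0

    @property
    def fan_half_angle(self) -> float:
        """Half fan angle (rad), covering the FOV circle plus one bin."""
        base = float(np.arcsin(self.fov_radius / self.source_to_iso))
        return base * (1.0 + 2.0 / self.n_detectors)

    @property
    def detector_pitch(self) -> float:
        """Angular spacing between detector elements, rad."""
        return 2.0 * self.fan_half_angle / self.n_detectors

    @property
    def detector_angles(self) -> np.ndarray:
        """Detector-element angles gamma relative to the central ray, rad."""
        k = np.arange(self.n_detectors)
        return (k - (self.n_detectors - 1) / 2.0) * self.detector_pitch

    @property
    def view_angles(self) -> np.ndarray:
        """Source angular positions beta, rad (endpoint excluded)."""
        return np.deg2rad(
            np.arange(self.n_views) * self.angular_range / self.n_views
        )

    def fov_mask(self) -> np.ndarray:
        """Boolean image of the reconstruction circle (pixels inside the FOV).

        Pixels outside the inscribed circle are crossed by few or no rays
        and are not reconstructible; reconstructions are constrained to
        this support.
        """
        n = self.grid_size
        c = (n - 1) / 2.0
        ix = (np.arange(n) - c) * self.pixel_spacing
        r = np.hypot(ix[None, :], ix[:, None])
        return r <= self.fov_radius

    def source_position(self, beta: float) -> np.ndarray:
        return self.source_to_iso * np.array([np.cos(beta), np.sin(beta)])

    def ray_directions(self, beta: float) -> np.ndarray:
        """Unit direction of each detector ray for view angle ``beta``."""
        ang = beta + np.pi + self.detector_angles
        return np.stack([np.cos(ang), np.sin(ang)], axis=1)


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise parameters of the low-dose acquisition."""

    I0: float = 2.5e5              # incident photons per ray
    readout_variance: float = 10.0  # Gaussian readout noise, counts^2
    clamp_floor: float = 1.0       # counts substituted for non-positive draws
    seed: int = 0

    def __post_init__(self):
        if self.I0 <= 0:
            raise ValueError("I0 must be positive")
        if self.clamp_floor < 1:
            raise ValueError("clamp_floor must be at least 1")


@dataclass(frozen=True)
class SinogramSeries:
    """Per-frame line integrals, ``(n_views, n_detectors, n_frames)``."""

    data: np.ndarray
    geometry: ScanGeometry
    dt: float = 1.0

    def __post_init__(self):
        nv, nd = self.data.shape[:2]
        if nv != self.geometry.n_views or nd != self.geometry.n_detectors:
            raise ValueError("sinogram dimensions do not match the geometry")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("sinogram contains non-finite values")

    @property
    def n_frames(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]


def _trace_bundle(
    sources: np.ndarray, dirs: np.ndarray, grid_size: int, spacing: float
):
    """Siddon tracing of a bundle of rays against a centered square grid.

    Returns ``(ray_idx, pix_idx, length_cm)`` flat arrays.  Parametric form:
    every crossing of a grid line contributes a parameter t (in mm along the
    unit direction); sorted, clipped parameters delimit the per-pixel
    segments, whose midpoints identify the pixel.
    """
    n = grid_size
    half = n * spacing / 2.0
    n_rays = sources.shape[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(np.abs(dirs) < 1e-12, np.nan, 1.0 / dirs)
    planes = -half + spacing * np.arange(n + 1)

    # slab entry/exit
    t_lo = np.full(n_rays, -np.inf)
    t_hi = np.full(n_rays, np.inf)
    for ax in (0, 1):
        with np.errstate(invalid="ignore"):
            t1 = (-half - sources[:, ax]) * inv[:, ax]
            t2 = (half - sources[:, ax]) * inv[:, ax]
        lo = np.fmin(t1, t2)
        hi = np.fmax(t1, t2)
        parallel = ~np.isfinite(inv[:, ax])
        inside = np.abs(sources[:, ax]) < half
        lo = np.where(parallel, np.where(inside, -np.inf, np.inf), lo)
        hi = np.where(parallel, np.where(inside, np.inf, -np.inf), hi)
        t_lo = np.maximum(t_lo, lo)
        t_hi = np.minimum(t_hi, hi)
    hit = t_lo < t_hi
    t_lo = np.where(hit, t_lo, 0.0)
    t_hi = np.where(hit, t_hi, 0.0)

    with np.errstate(invalid="ignore"):
        tx = (planes[None, :] - sources[:, :1]) * inv[:, :1]
        ty = (planes[None, :] - sources[:, 1:2]) * inv[:, 1:2]
    t_all = np.concatenate(
        [tx, ty, t_lo[:, None], t_hi[:, None]], axis=1
    )
    t_all = np.where(np.isfinite(t_all), t_all, t_lo[:, None])
    t_all = np.clip(t_all, t_lo[:, None], t_hi[:, None])
    t_all.sort(axis=1)

    seg = np.diff(t_all, axis=1)
    mid = 0.5 * (t_all[:, 1:] + t_all[:, :-1])
    px = sources[:, 0:1] + mid * dirs[:, 0:1]
    py = sources[:, 1:2] + mid * dirs[:, 1:2]
    col = np.floor((px + half) / spacing).astype(np.int64)
    row = np.floor((half - py) / spacing).astype(np.int64)
    ok = (
        (seg > 1e-9 * spacing)
        & (col >= 0) & (col < n) & (row >= 0) & (row < n)
        & hit[:, None]
    )
    ray_idx = np.broadcast_to(np.arange(n_rays)[:, None], seg.shape)[ok]
    pix_idx = (row * n + col)[ok]
    return ray_idx, pix_idx, seg[ok] * MM_TO_CM


def siddon_trace(
    source, detector, grid_size: int, pixel_spacing: float = 1.0
) -> list[tuple[tuple[int, int], float]]:
    """Trace one ray from ``source`` to ``detector`` (mm, isocenter origin).

    Returns ``[((row, col), length_cm), ...]`` for every pixel the ray
    crosses; empty if the ray misses the grid.  The summed lengths equal the
    chord length of the ray inside the grid.
    """
    source = np.asarray(source, dtype=float)
    detector = np.asarray(detector, dtype=float)
    d = detector - source
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("degenerate ray: source and detector coincide")
    _, pix, lengths = _trace_bundle(
        source[None, :], (d / norm)[None, :], grid_size, pixel_spacing
    )
    n = grid_size
    return [
        ((int(p // n), int(p % n)), float(l)) for p, l in zip(pix, lengths)
    ]


_MATRIX_CACHE: dict[ScanGeometry, sp.csr_matrix] = {}


def system_matrix(geometry: ScanGeometry) -> sp.csr_matrix:
    """Sparse Siddon system matrix ``A`` of shape (n_views*n_detectors, n_pix).

    Row ``v * n_detectors + d`` holds the intersection lengths (cm) of ray
    (view v, detector d) with each image pixel.  Cached per geometry.
    """
    cached = _MATRIX_CACHE.get(geometry)
    if cached is not None:
        return cached
    n = geometry.grid_size
    nd = geometry.n_detectors
    rows, cols, vals = [], [], []
    chunk = max(1, int(2e6 // (nd * (2 * n + 4))))
    betas = geometry.view_angles
    for start in range(0, geometry.n_views, chunk):
        vb = betas[start:start + chunk]
        srcs = np.repeat(
            geometry.source_to_iso
            * np.stack([np.cos(vb), np.sin(vb)], axis=1),
            nd, axis=0,
        )
        dirs = np.concatenate([geometry.ray_directions(b) for b in vb], axis=0)
        ridx, pidx, lens = _trace_bundle(srcs, dirs, n, geometry.pixel_spacing)
        rows.append(ridx + start * nd)
        cols.append(pidx)
        vals.append(lens)
    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geometry.n_views * nd, n * n),
    ).tocsr()
    _MATRIX_CACHE[geometry] = A
    return A


def forward_project(mu: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Line integrals of the attenuation image ``mu`` (cm^-1), one frame.

    Returns a ``(n_views, n_detectors)`` sinogram.
    """
    mu = np.asarray(mu, dtype=float)
    if mu.shape != (geometry.grid_size, geometry.grid_size):
        raise ValueError("image does not match the geometry grid")
    if not np.all(np.isfinite(mu)):
        raise ValueError("attenuation image contains non-finite values")
    A = system_matrix(geometry)
    return (A @ mu.ravel()).reshape(geometry.n_views, geometry.n_detectors)


def back_project(sino: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Exact adjoint of :func:`forward_project` (unfiltered back-projection)."""
    sino = np.asarray(sino, dtype=float)
    if sino.shape != (geometry.n_views, geometry.n_detectors):
        raise ValueError("sinogram does not match the geometry")
    A = system_matrix(geometry)
    return (A.T @ sino.ravel()).reshape(geometry.grid_size, geometry.grid_size)


def project_series(mu_series: np.ndarray, geometry: ScanGeometry, dt: float = 1.0) -> SinogramSeries:
    """Forward-project every frame of a ``(ny, nx, nt)`` attenuation series."""
    ny, nx, nt = mu_series.shape
    A = system_matrix(geometry)
    flat = mu_series.reshape(ny * nx, nt)
    sino = (A @ flat).reshape(geometry.n_views, geometry.n_detectors, nt)
    return SinogramSeries(data=sino, geometry=geometry, dt=dt)


def add_counting_noise(sino, model: NoiseModel):
    """Apply the Beer-Lambert Poisson + Gaussian-readout noise model.

    Accepts a ``SinogramSeries`` or a raw array; the noise stream of frame
    ``i`` is seeded from ``(model.seed, i)`` so frames are independent and
    the whole experiment is reproducible.
    """
    if isinstance(sino, SinogramSeries):
        noisy = add_counting_noise(sino.data, model)
        return SinogramSeries(data=noisy, geometry=sino.geometry, dt=sino.dt)
    P = np.asarray(sino, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("line integrals must be finite")
    single = P.ndim == 2
    if single:
        P = P[:, :, None]
    out = np.empty_like(P)
    for i in range(P.shape[2]):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=model.seed, spawn_key=(i,))
        )
        expected = model.I0 * np.exp(-P[:, :, i])
        counts = rng.poisson(expected).astype(float)
        counts += rng.normal(0.0, np.sqrt(model.readout_variance), counts.shape)
        counts = np.where(counts <= 0.0, model.clamp_floor, counts)
        out[:, :, i] = np.log(model.I0 / counts)
    return out[:, :, 0] if single else out


def operator_norm(geometry: ScanGeometry, n_iter: int = 50) -> float:
    """Spectral norm of the system matrix by power iteration (deterministic)."""
    A = system_matrix(geometry)
    rng = np.random.default_rng(0)
    x = rng.standard_normal(A.shape[1])
    x /= np.linalg.norm(x)
    s = 0.0
    for _ in range(n_iter):
        y = A.T @ (A @ x)
        s = np.linalg.norm(y)
        if s == 0:
            return 0.0
        x = y / s
    return float(np.sqrt(s))
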
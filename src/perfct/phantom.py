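"""Digital brain-perfusion phantom.

Generates a single-slice dynamic contrast-enhanced CT brain phantom with
analytically known perfusion parameters: a tissue label map (skull, CSF,
gray/white matter, a feeding artery, and an optional penumbra + ischemic-core
lesion), per-tissue time-intensity curves driven by a gamma-variate arterial
input function through the indicator-dilution model, and the rendered dynamic
Hounsfield-unit series.  Because every curve is built by forward convolution
from known CBF/CBV, the phantom provides exact ground truth for testing the
deconvolution chain end to end.

Conventions
-----------
* Images are ``(ny, nx)`` float arrays; dynamic series are ``(ny, nx, nt)``.
* Frame ``i`` (0-based) is sampled at ``t = i * dt`` seconds.
* CBF is in mL/100 g/min, CBV in mL/100 g, MTT = 60*CBV/CBF in seconds.
* The tissue residue function is mono-exponential, ``R(t) = exp(-t/MTT)``,
  which satisfies R(0) = 1 and R(inf) = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: linear attenuation coefficient of water at the effective energy, cm^-1
MU_WATER = 0.239

#: brain tissue density, g/mL
RHO_BRAIN = 1.04

#: large-to-small-vessel hematocrit correction factor
K_HEMATOCRIT = 0.73

# integer labels of the phantom compartments
AIR, SKULL, CSF, GM, WM, VESSEL, PENUMBRA, CORE = range(8)

LABEL_NAMES = {
    AIR: "air", SKULL: "skull", CSF: "csf", GM: "gm", WM: "wm",
    VESSEL: "vessel", PENUMBRA: "penumbra", CORE: "core",
}


class ConfigurationError(ValueError):
    """A phantom or geometry configuration that cannot be realized."""


@dataclass(frozen=True)
class TissueParams:
    """Baseline CT number and perfusion parameters of one tissue class."""

    baseline_hu: float
    cbf: float = 0.0   # mL/100 g/min; 0 marks a non-perfused tissue
    cbv: float = 0.0   # mL/100 g

    @property
    def perfused(self) -> bool:
        return self.cbf > 0.0 and self.cbv > 0.0

    @property
    def mtt(self) -> float:
        """Mean transit time in seconds (central volume principle)."""
        if not self.perfused:
            return float("nan")
        return 60.0 * self.cbv / self.cbf


@dataclass(frozen=True)
class GammaVariateAif:
    """Gamma-variate arterial input function, as contrast enhancement in HU.

    ``ce(t) = amplitude * (u/shape)**shape * exp(shape - u)`` with
    ``u = (t - delay)/scale`` for ``t > delay`` and 0 before arrival; the
    peak value equals ``amplitude`` and occurs at ``delay + shape*scale``.
    """

    amplitude: float = 150.0   # peak enhancement, HU
    delay: float = 10.0        # bolus arrival time, s
    shape: float = 3.0         # dimensionless shape
    scale: float = 1.5         # time scale, s

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        u = (t - self.delay) / self.scale
        out = np.zeros_like(u)
        pos = u > 0
        out[pos] = (
            self.amplitude
            * (u[pos] / self.shape) ** self.shape
            * np.exp(self.shape - u[pos])
        )
        return out


@dataclass(frozen=True)
class LesionSpec:
    """Penumbra + ischemic core, as CBF/CBV scale factors on the host tissue.

    Centers and radii are in units of ``grid_size`` (fractions), measured from
    the image center with x to the right and y up.
    """

    center: tuple[float, float] = (-0.18, 0.12)
    penumbra_radius: float = 0.12
    core_radius: float = 0.05
    penumbra_cbf_scale: float = 0.4
    penumbra_cbv_scale: float = 0.9
    core_cbf_scale: float = 0.15
    core_cbv_scale: float = 0.4


def default_tissue_table() -> dict[int, TissueParams]:
    gm = TissueParams(baseline_hu=40.0, cbf=60.0, cbv=4.0)
    wm = TissueParams(baseline_hu=30.0, cbf=25.0, cbv=2.0)
    return {
        AIR: TissueParams(baseline_hu=-1000.0),
        SKULL: TissueParams(baseline_hu=1000.0),
        CSF: TissueParams(baseline_hu=15.0),
        GM: gm,
        WM: wm,
        # the vessel pixel time course is the AIF itself, not a convolution
        VESSEL: TissueParams(baseline_hu=45.0),
        PENUMBRA: gm,   # scale factors applied in build_phantom
        CORE: gm,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the synthetic dynamic brain slice."""

    grid_size: int = 256
    pixel_spacing: float = 1.0          # mm
    n_frames: int = 50
    dt: float = 1.0                     # s
    tissue_table: dict[int, TissueParams] = field(default_factory=default_tissue_table)
    lesion: LesionSpec | None = None
    aif_params: GammaVariateAif = field(default_factory=GammaVariateAif)
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 32:
            raise ConfigurationError("grid_size must be at least 32")
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        table = dict(self.tissue_table)
        if self.lesion is not None:
            les = self.lesion
            host = table[GM]
            table[PENUMBRA] = replace(
                host,
                cbf=host.cbf * les.penumbra_cbf_scale,
                cbv=host.cbv * les.penumbra_cbv_scale,
            )
            table[CORE] = replace(
                host,
                cbf=host.cbf * les.core_cbf_scale,
                cbv=host.cbv * les.core_cbv_scale,
            )
        object.__setattr__(self, "tissue_table", table)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def scaled_roi_size(self, size_at_256: int) -> int:
        """ROI edge lengths are stated on the 256-pixel grid; scale with it."""
        return max(6, int(round(size_at_256 * self.grid_size / 256)))


@dataclass(frozen=True)
class LabelMap:
    """Tissue label image plus the named regions used by the analysis."""

    labels: np.ndarray                 # (ny, nx) int
    brain_mask: np.ndarray             # (ny, nx) bool
    rois: dict[str, np.ndarray]        # name -> (ny, nx) bool

    def __post_init__(self):
        for name, roi in self.rois.items():
            if roi.shape != self.labels.shape:
                raise ConfigurationError(f"ROI {name!r} does not match the grid")


@dataclass(frozen=True)
class DynamicSeries:
    """A dynamic image stack ``(ny, nx, nt)`` with uniform temporal sampling."""

    data: np.ndarray
    dt: float

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("DynamicSeries data must be (ny, nx, nt)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


def _grid_coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates with the origin at the image center, y up."""
    c = (n - 1) / 2.0
    ix = np.arange(n) - c
    x = np.broadcast_to(ix[None, :], (n, n))
    y = np.broadcast_to(-ix[:, None], (n, n))  # row 0 is the top of the image
    return x, y


def build_phantom(spec: PhantomSpec) -> LabelMap:
    """Construct the tissue label map for ``spec``.

    The slice is a disc brain inside a skull annulus: gray matter in the upper
    half-plane, white matter in the lower, two ventricular CSF discs near the
    center, a vessel disc standing in for the internal carotid artery, and,
    when a lesion is requested, concentric penumbra/core discs in the gray
    matter.  Also returns the named ROIs: the square around the artery used
    for AIF extraction, the contralateral-normal square, and the lesion pixel
    sets.  Deterministic for a given spec.
    """
    n = spec.grid_size
    x, y = _grid_coords(n)
    r = np.hypot(x, y)

    brain_r = 0.40 * n
    skull_inner, skull_outer = 0.42 * n, 0.47 * n
    if skull_outer > (n - 1) / 2.0:
        raise ConfigurationError("skull does not fit inside the grid")

    labels = np.full((n, n), AIR, dtype=np.int32)
    labels[(r >= skull_inner) & (r <= skull_outer)] = SKULL
    brain = r <= brain_r
    labels[brain & (y >= 0)] = GM
    labels[brain & (y < 0)] = WM

    # lateral ventricles
    for sx in (-0.08, 0.08):
        vent = np.hypot(x - sx * n, y - 0.03 * n) <= 0.055 * n
        labels[vent & brain] = CSF

    # feeding artery (internal-carotid stand-in), lower half of the brain
    vx, vy = 0.0, -0.30
    vessel = np.hypot(x - vx * n, y - vy * n) <= max(1.5, 0.035 * n)
    if not (vessel & brain).any():
        raise ConfigurationError("vessel disc lies outside the brain")
    labels[vessel & brain] = VESSEL

    rois: dict[str, np.ndarray] = {}

    def _square(cx_frac: float, cy_frac: float, size: int) -> np.ndarray:
        half = size / 2.0
        m = (np.abs(x - cx_frac * n) < half) & (np.abs(y - cy_frac * n) < half)
        if m.sum() < size * size - 2 * size:  # clipped by the grid edge
            raise ConfigurationError("ROI square extends outside the grid")
        return m

    rois["ica"] = _square(vx, vy, spec.scaled_roi_size(20))

    if spec.lesion is not None:
        les = spec.lesion
        lx, ly = les.center
        d = np.hypot(x - lx * n, y - ly * n)
        pen = (d <= les.penumbra_radius * n) & brain
        core = (d <= les.core_radius * n) & brain
        if not pen.any():
            raise ConfigurationError("lesion lies outside the brain")
        pen_only = pen & ~core & (labels == GM)
        core = core & (labels == GM)
        labels[pen_only] = PENUMBRA
        labels[core] = CORE
        rois["penumbra"] = labels == PENUMBRA
        rois["core"] = labels == CORE
        # mirror of the lesion center in the opposite hemisphere
        rois["contralateral"] = _square(-lx, ly, spec.scaled_roi_size(18))

    return LabelMap(labels=labels, brain_mask=brain, rois=rois)


def tissue_ce_curve(
    cbf: float, cbv: float, aif: np.ndarray, dt: float
) -> np.ndarray:
    """Contrast-enhancement time course of a tissue with flow ``cbf``.

    Implements the indicator-dilution convolution
    ``CE(t) = (rho/k_H) * CBF * (AIF (*) R)(t)`` as a rectangle-rule discrete
    convolution on the frame grid, with the discrete-exponential residue

        ``R_j = (1 - dt/MTT)**j``

    i.e. ``R(t) = exp(-t/tau)`` with the decay rate adjusted so that the
    rectangle-rule area ``dt * sum(R_j)`` equals MTT exactly.  This keeps
    both ends of the central volume principle consistent at the acquisition
    sampling: R(0) = 1 (so deconvolution recovers CBF from the curve
    maximum) and the area ratio of the output to the AIF reproduces CBV
    through the standard CBV formula.  Requires MTT > dt.

    Parameters
    ----------
    cbf, cbv : float
        Ground-truth perfusion (mL/100 g/min, mL/100 g); both must be > 0.
    aif : ndarray
        Arterial enhancement per frame (HU), nonnegative.
    dt : float
        Frame spacing in seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cbf <= 0 or cbv <= 0:
        raise ValueError("cbf and cbv must be positive for a perfused tissue")
    aif = np.asarray(aif, dtype=float)
    n = aif.size
    mtt = 60.0 * cbv / cbf
    if mtt <= dt:
        raise ValueError("MTT must exceed the frame spacing dt")
    cbf_g_s = cbf / 6000.0  # mL/100g/min -> mL/g/s
    residue = (1.0 - dt / mtt) ** np.arange(n)
    k = (RHO_BRAIN / K_HEMATOCRIT) * cbf_g_s * residue
    return dt * np.convolve(aif, k)[:n]


def render_dynamic_hu(labelmap: LabelMap, spec: PhantomSpec) -> DynamicSeries:
    """Render the dynamic HU series from the label map and tissue table.

    Each pixel's value is its tissue baseline plus the tissue CE curve;
    vessel pixels carry the AIF directly.  With the default 10 s bolus delay
    and 1 s sampling the first eight frames are pure baseline.
    """
    t = spec.frame_times
    aif = spec.aif_params(t)
    ny, nx = labelmap.labels.shape
    out = np.zeros((ny, nx, spec.n_frames), dtype=float)
    for label, tissue in spec.tissue_table.items():
        mask = labelmap.labels == label
        if not mask.any():
            continue
        if label == VESSEL:
            curve = tissue.baseline_hu + aif
        elif tissue.perfused:
            curve = tissue.baseline_hu + tissue_ce_curve(
                tissue.cbf, tissue.cbv, aif, spec.dt
            )
        else:
            curve = np.full(spec.n_frames, tissue.baseline_hu)
        out[mask, :] = curve
    return DynamicSeries(data=out, dt=spec.dt)


def ground_truth_maps(labelmap: LabelMap, spec: PhantomSpec):
    """Analytic CBF/CBV/MTT maps implied by the tissue table (for testing)."""
    shape = labelmap.labels.shape
    cbf = np.zeros(shape)
    cbv = np.zeros(shape)
    for label, tissue in spec.tissue_table.items():
        if not tissue.perfused:
            continue
        mask = labelmap.labels == label
        cbf[mask] = tissue.cbf
        cbv[mask] = tissue.cbv
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf > 0, 60.0 * cbv / cbf, 0.0)
    return cbf, cbv, mtt


def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    """CT number (HU) to linear attenuation coefficient (cm^-1).

    Affine calibration through water (0 HU -> 0.239 cm^-1) and air
    (-1000 HU -> 0 cm^-1), clipped below at zero.
    """
    mu = MU_WATER * (np.asarray(hu, dtype=float) / 1000.0 + 1.0)
    return np.clip(mu, 0.0, None)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hu_to_mu` for non-negative attenuation values."""
    return 1000.0 * (np.asarray(mu, dtype=float) / MU_WATER - 1.0)
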
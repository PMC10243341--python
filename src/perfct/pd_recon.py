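"""Spatio-temporally regularized reconstruction by a primal-dual solver.

Four objectives over the dynamic attenuation series ``x`` (or its low-rank /
sparse split ``x = L + S``) are supported, all sharing the quadratic data
term ``(1/2) ||A x - b||_F^2`` with ``A`` the fan-beam system operator
applied frame by frame:

* ``TV``   — ``+ alpha * ||grad3 x||_1``, the spatio-temporal total
  variation with ``grad3 = (d/dx, d/dy, d/dt)``;
* ``TGV``  — ``+ TGV^2_alpha(x) = min_v alpha1 ||grad3 x - v||_1
  + alpha0 ||E v||_1`` with ``E`` the symmetrized gradient, the second-order
  total generalized variation that penalizes deviation from piecewise-affine
  behavior instead of piecewise-constant (no staircase artifacts);
* ``LTV`` / ``LTGV`` — the same regularizers applied to the sparse dynamic
  component ``S`` plus a nuclear-norm penalty ``beta * ||L||_*`` on the
  Casorati matrix (pixels x frames) of the time-coherent background ``L``.

All are solved with the Chambolle-Pock first-order primal-dual iteration:
the data term is dualized with resolvent ``q <- (q + sigma(A xbar - b)) /
(1 + sigma)``, each l1 term is dualized with a pointwise projection onto the
(isotropic) l-infinity ball, and the nuclear norm enters as a primal prox by
singular-value thresholding.

Step-size stability: the iteration runs on the system operator rescaled to
unit spectral norm — equivalently, it minimizes the objective above scaled
by ``1/||A||^2``, which has the same minimizer — so the fixed step sizes
``sigma = tau = 0.25`` are meaningful while ``alpha``/``beta`` keep their
raw-operator balance.  If the composite operator norm still violates the
convergence condition ``sigma * tau * ||K||^2 <= 1`` (as it can for the TGV
variants), both steps are scaled down jointly and the effective values are
reported.

Setting ``geometry=None`` selects identity-operator (denoising) mode, in
which ``b`` is an image-domain series and no unit conversion is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from perfct.phantom import MU_WATER, DynamicSeries, mu_to_hu
from perfct.projector import ScanGeometry, SinogramSeries, operator_norm, system_matrix

METHODS = ("tv", "tgv", "ltv", "ltgv")

# weights of the 6 independent symmetric-tensor components (xx, yy, tt,
# xy, xt, yt): off-diagonals appear twice in the full tensor
SYM_WEIGHTS = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


@dataclass(frozen=True)
class RegularizerConfig:
    """Method selector and all solver hyperparameters."""

    method: str = "tv"
    alpha: float = 0.0025        # TV / LTV weight
    alpha1: float = 0.0025       # TGV first-order weight
    alpha0: float | None = None  # TGV second-order weight; default 2 * alpha1
    beta: float = 2.0            # nuclear-norm weight (LTV / LTGV)
    sigma: float = 0.25          # dual step size
    tau: float = 0.25            # primal step size
    eps_tol: float = 1e-6        # relative-change stopping tolerance
    n_max: int = 500             # iteration cap
    temporal_weight: float = 1.0  # scale of d/dt relative to spatial gradients

    def __post_init__(self):
        if self.method.lower() not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        object.__setattr__(self, "method", self.method.lower())
        if self.alpha0 is None:
            object.__setattr__(self, "alpha0", 2.0 * self.alpha1)
        for name in ("alpha", "alpha1", "alpha0", "beta", "sigma", "tau",
                     "eps_tol", "temporal_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_max < 1:
            raise ValueError("n_max must be at least 1")

    @property
    def weight(self) -> float:
        """The first-order l1 weight actually used by the selected method."""
        return self.alpha if self.method in ("tv", "ltv") else self.alpha1


@dataclass
class LSDecomposition:
    """Low-rank (L) and sparse (S) components of a dynamic series."""

    L: DynamicSeries
    S: DynamicSeries


@dataclass
class SolveReport:
    """Iteration diagnostics of one primal-dual solve."""

    n_iters: int = 0
    converged: bool = False
    relative_change_history: list = field(default_factory=list)
    objective_history: list = field(default_factory=list)
    operator_norm: float = 1.0
    composite_norm: float = 1.0
    sigma_eff: float = 0.25
    tau_eff: float = 0.25


# ---------------------------------------------------------------------------
# difference operators

def _dfwd(a: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference with replicate (Neumann) boundary: last row 0."""
    out = np.zeros_like(a)
    src = [slice(None)] * a.ndim
    src[axis] = slice(0, a.shape[axis] - 1)
    out[tuple(src)] = np.diff(a, axis=axis)
    return out


def _dfwd_T(b: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of :func:`_dfwd` (a negative backward difference)."""
    out = np.zeros_like(b)
    n = b.shape[axis]
    sl = lambda s: tuple(
        s if i == axis else slice(None) for i in range(b.ndim)
    )
    out[sl(slice(0, n - 1))] = -b[sl(slice(0, n - 1))]
    out[sl(slice(1, n))] += b[sl(slice(0, n - 1))]
    return out


def grad3(x: np.ndarray, temporal_weight: float = 1.0) -> np.ndarray:
    """Spatio-temporal gradient of a ``(ny, nx, nt)`` series.

    Returns shape ``(3, ny, nx, nt)`` ordered (d/dx, d/dy, w * d/dt); x runs
    along columns, y along rows.  A single-frame series yields a zero
    temporal component (with a warning).
    """
    if x.ndim != 3:
        raise ValueError("grad3 expects a (ny, nx, nt) array")
    if x.shape[2] < 2:
        warnings.warn("single-frame series: temporal gradient set to zero")
    return np.stack([
        _dfwd(x, 1),
        _dfwd(x, 0),
        temporal_weight * _dfwd(x, 2),
    ])


def div3(p: np.ndarray, temporal_weight: float = 1.0) -> np.ndarray:
    """Negative adjoint of :func:`grad3`: ``<grad3 x, p> = -<x, div3 p>``."""
    return -(
        _dfwd_T(p[0], 1)
        + _dfwd_T(p[1], 0)
        + temporal_weight * _dfwd_T(p[2], 2)
    )


def sym_grad(v: np.ndarray, temporal_weight: float = 1.0) -> np.ndarray:
    """Symmetrized gradient E(v) = (grad3 v + grad3 v^T) / 2 of a 3-field.

    Input shape ``(3, ny, nx, nt)``; output holds the 6 independent tensor
    components ``(xx, yy, tt, xy, xt, yt)``.  Inner products on the output
    space carry weight 2 on the off-diagonal components.
    """
    dx = lambda a: _dfwd(a, 1)
    dy = lambda a: _dfwd(a, 0)
    dt = lambda a: temporal_weight * _dfwd(a, 2)
    vx, vy, vt = v
    return np.stack([
        dx(vx),
        dy(vy),
        dt(vt),
        0.5 * (dx(vy) + dy(vx)),
        0.5 * (dx(vt) + dt(vx)),
        0.5 * (dy(vt) + dt(vy)),
    ])


def sym_grad_adjoint(r: np.ndarray, temporal_weight: float = 1.0) -> np.ndarray:
    """Adjoint of :func:`sym_grad` w.r.t. the weighted tensor inner product."""
    dxT = lambda a: _dfwd_T(a, 1)
    dyT = lambda a: _dfwd_T(a, 0)
    dtT = lambda a: temporal_weight * _dfwd_T(a, 2)
    rxx, ryy, rtt, rxy, rxt, ryt = r
    return np.stack([
        dxT(rxx) + dyT(rxy) + dtT(rxt),
        dyT(ryy) + dxT(rxy) + dtT(ryt),
        dtT(rtt) + dxT(rxt) + dyT(ryt),
    ])


# ---------------------------------------------------------------------------
# proximal operators

def soft_threshold(z: np.ndarray, t: float, axis: int | None = None,
                   weights: np.ndarray | None = None) -> np.ndarray:
    """Shrink ``z`` toward zero by ``t`` (prox of ``t * ||.||_1``).

    With ``axis`` given, the isotropic vector-magnitude convention is used:
    the Euclidean magnitude along that axis (optionally weighted) is reduced
    by ``t`` and floored at zero, preserving direction.
    """
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    z = np.asarray(z, dtype=float)
    if axis is None:
        return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)
    zsq = z**2
    if weights is not None:
        w = np.asarray(weights, float).reshape(
            [-1 if i == axis % z.ndim else 1 for i in range(z.ndim)]
        )
        zsq = w * zsq
    mag = np.sqrt(np.sum(zsq, axis=axis, keepdims=True))
    scale = np.maximum(1.0 - t / np.maximum(mag, 1e-300), 0.0)
    return z * scale


def _project_linf(p: np.ndarray, radius: float,
                  weights: np.ndarray | None = None) -> np.ndarray:
    """Pointwise projection of a component-stacked field onto the l2-ball
    of ``radius`` (the dual of the isotropic l1 norm); component axis 0."""
    psq = p**2
    if weights is not None:
        psq = weights.reshape((-1,) + (1,) * (p.ndim - 1)) * psq
    mag = np.sqrt(np.sum(psq, axis=0, keepdims=True))
    return p / np.maximum(1.0, mag / radius)


def _l1_iso(p: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Isotropic l1 norm: sum over pixels of the pointwise magnitude."""
    psq = p**2
    if weights is not None:
        psq = weights.reshape((-1,) + (1,) * (p.ndim - 1)) * psq
    return float(np.sum(np.sqrt(np.sum(psq, axis=0))))


def svt(M: np.ndarray, t: float) -> np.ndarray:
    """Singular-value thresholding (prox of ``t * ||.||_*``)."""
    if t < 0:
        raise ValueError("threshold must be nonnegative")
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    if t == 0:
        return M.copy()
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    s = np.maximum(s - t, 0.0)
    return (U * s) @ Vt


def _svt_series(x: np.ndarray, t: float) -> np.ndarray:
    """SVT on the Casorati matrix (pixels x frames) of a dynamic series."""
    ny, nx, nt = x.shape
    return svt(x.reshape(ny * nx, nt), t).reshape(ny, nx, nt)


# ---------------------------------------------------------------------------
# system operator wrapper

class _SystemOp:
    """Frame-wise application of A / A^T, rescaled to unit spectral norm."""

    def __init__(self, geometry: ScanGeometry | None, image_shape):
        self.geometry = geometry
        self.image_shape = image_shape
        if geometry is None:
            self.norm = 1.0
            self._A = None
        else:
            self._A = system_matrix(geometry)
            self.norm = operator_norm(geometry)

    def A(self, x: np.ndarray) -> np.ndarray:
        if self._A is None:
            return x
        ny, nx, nt = x.shape
        g = self.geometry
        return (self._A @ x.reshape(ny * nx, nt)).reshape(
            g.n_views, g.n_detectors, nt
        ) / self.norm

    def At(self, y: np.ndarray) -> np.ndarray:
        if self._A is None:
            return y
        ny, nx, nt = self.image_shape
        nv, nd, _ = y.shape
        return (self._A.T @ y.reshape(nv * nd, nt)).reshape(
            ny, nx, nt
        ) / self.norm


_COMPOSITE_NORM_CACHE: dict = {}


def _composite_norm(op: _SystemOp, method: str, tw: float, shape) -> float:
    """Power-iteration estimate of ||K|| for the method's stacked operator.

    K maps the method's primal block (x; x,v; L,S; or L,S,v) to its dual
    block; the estimate is the square root of the dominant eigenvalue of
    K*K, with the weighted inner product on the symmetric-tensor part.
    """
    key = (op.geometry, method, tw, shape)
    cached = _COMPOSITE_NORM_CACHE.get(key)
    if cached is not None:
        return cached

    with_v = method in ("tgv", "ltgv")
    with_ls = method in ("ltv", "ltgv")
    rng = np.random.default_rng(0)
    blocks = [rng.standard_normal(shape)]
    if with_ls:
        blocks.append(rng.standard_normal(shape))
    if with_v:
        blocks.append(rng.standard_normal((3,) + shape))

    def kkt(blocks):
        if with_ls:
            L, S = blocks[0], blocks[1]
            ax = op.A(L + S)
            g = grad3(S, tw)
        else:
            x = blocks[0]
            ax = op.A(x)
            g = grad3(x, tw)
        if with_v:
            v = blocks[-1]
            g = g - v
            ev = sym_grad(v, tw)
        atq = op.At(ax)
        dv = div3(g, tw)
        out = []
        if with_ls:
            out += [atq, atq - dv]
        else:
            out += [atq - dv]
        if with_v:
            out += [-g + sym_grad_adjoint(ev, tw)]
        return out

    est = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(30):
            new = kkt(blocks)
            s = np.sqrt(sum(np.sum(a**2) for a in new))
            if s == 0:
                break
            est = np.sqrt(s)
            blocks = [a / s for a in new]
    _COMPOSITE_NORM_CACHE[key] = est
    return est


# ---------------------------------------------------------------------------
# the solver

def _fbp_init(sino: SinogramSeries) -> np.ndarray:
    from perfct.fbp import fbp_series_mu

    return fbp_series_mu(sino, sino.geometry, "ram-lak")


def reconstruct(
    sino_series,
    geometry: ScanGeometry | None,
    config: RegularizerConfig,
    init: np.ndarray | None = None,
    objective_cadence: int = 0,
    record_objective: bool = False,
):
    """Solve the selected reconstruction problem with Chambolle-Pock.

    Parameters
    ----------
    sino_series : SinogramSeries or ndarray
        Measured line integrals ``b``; with ``geometry=None`` an image-domain
        series to be denoised (identity operator mode).
    geometry : ScanGeometry or None
        Fan-beam acquisition; ``None`` selects denoising mode.
    config : RegularizerConfig
        Objective and solver controls.
    init : ndarray, optional
        Initial iterate in operator-domain units; defaults to the Ram-Lak
        FBP series (the L component for LTV/LTGV, with S started at zero).
    objective_cadence : int
        With ``record_objective``, additionally evaluate the objective every
        this many iterations.
    record_objective : bool
        Evaluate the (exact) objective at the initial and final iterates.
        Off by default: for the TGV variants each evaluation solves the
        inner minimization over v, which costs a noticeable fraction of the
        reconstruction itself.

    Returns
    -------
    (series, ls, report)
        ``series`` is the reconstructed :class:`DynamicSeries` in HU (or the
        input units in denoising mode); ``ls`` is the HU-domain
        :class:`LSDecomposition` for LTV/LTGV, else ``None``.
    """
    method = config.method
    tw = config.temporal_weight

    if isinstance(sino_series, SinogramSeries):
        b_raw = sino_series.data
        dt = sino_series.dt
    else:
        b_raw = np.asarray(sino_series, dtype=float)
        dt = 1.0
    if b_raw.ndim == 2:
        b_raw = b_raw[:, :, None]

    if geometry is None:
        image_shape = b_raw.shape
    else:
        image_shape = (geometry.grid_size, geometry.grid_size, b_raw.shape[2])
    op = _SystemOp(geometry, image_shape)
    b = b_raw / op.norm

    if init is None:
        if geometry is None:
            x = b_raw.copy()
        else:
            x = _fbp_init(
                sino_series if isinstance(sino_series, SinogramSeries)
                else SinogramSeries(data=b_raw, geometry=geometry, dt=dt)
            )
    else:
        x = np.asarray(init, dtype=float).copy()
        if x.shape != image_shape:
            raise ValueError("init does not match the problem dimensions")

    sigma, tau = config.sigma, config.tau
    Knorm = _composite_norm(op, method, tw, image_shape)
    if sigma * tau * Knorm**2 > 0.99:
        scale = np.sqrt(0.99 / (sigma * tau * Knorm**2))
        sigma *= scale
        tau *= scale

    report = SolveReport(
        operator_norm=op.norm, composite_norm=Knorm,
        sigma_eff=sigma, tau_eff=tau,
    )

    # reconstructions are supported on the FOV circle; pixels outside it are
    # crossed by few or no rays and would drift freely
    if geometry is not None:
        fov = geometry.fov_mask()[:, :, None].astype(float)
    else:
        fov = None

    def clip_support(a):
        return a if fov is None else a * fov

    with_ls = method in ("ltv", "ltgv")
    with_v = method in ("tgv", "ltgv")
    # all regularization weights are defined against the data term of the
    # unit-spectral-norm rescaled system, (1/2)||A x/||A|| - b/||A||||^2:
    # on that scale the 1e-4..1e-2 range of alpha is the operating range.
    # The nuclear norm is averaged per frame (beta * ||L||_* / N_f), which
    # puts beta ~ 2 at the Casorati singular-value scale separating the
    # static background from noise and contrast dynamics, independent of
    # the series length.
    w1 = config.weight
    alpha0 = config.alpha0
    beta = config.beta / image_shape[2]

    x = clip_support(x)
    if with_ls:
        L, S = x.copy(), np.zeros_like(x)
        Lb, Sb = L.copy(), S.copy()
    else:
        xb = x.copy()
    if with_v:
        v = np.zeros((3,) + image_shape)
        vb = v.copy()

    q = np.zeros_like(b)
    p = np.zeros((3,) + image_shape)
    if with_v:
        r = np.zeros((6,) + image_shape)

    def current():
        return L + S if with_ls else x

    def objective():
        if with_ls:
            return objective_value((L, S), b_raw, geometry, config,
                                   v_init=v if with_v else None)
        return objective_value(x, b_raw, geometry, config,
                               v_init=v if with_v else None)

    if record_objective:
        report.objective_history.append(objective())

    prev = current().copy()
    for it in range(1, config.n_max + 1):
        # dual updates
        if with_ls:
            q = (q + sigma * (op.A(Lb + Sb) - b)) / (1.0 + sigma)
            reg_target = Sb
        else:
            q = (q + sigma * (op.A(xb) - b)) / (1.0 + sigma)
            reg_target = xb
        g = grad3(reg_target, tw)
        if with_v:
            p = _project_linf(p + sigma * (g - vb), w1)
            r = _project_linf(r + sigma * sym_grad(vb, tw), alpha0,
                              SYM_WEIGHTS)
        else:
            p = _project_linf(p + sigma * g, w1)

        # primal updates (+ extrapolation with theta = 1)
        atq = op.At(q)
        dv = div3(p, tw)
        if with_ls:
            L_new = clip_support(_svt_series(L - tau * atq, tau * beta))
            S_new = clip_support(S - tau * (atq - dv))
            Lb = 2.0 * L_new - L
            Sb = 2.0 * S_new - S
            L, S = L_new, S_new
        else:
            x_new = clip_support(x - tau * (atq - dv))
            xb = 2.0 * x_new - x
            x = x_new
        if with_v:
            v_new = v - tau * (-p + sym_grad_adjoint(r, tw))
            vb = 2.0 * v_new - v
            v = v_new

        cur = current()
        denom = np.linalg.norm(prev)
        diff = np.linalg.norm(cur - prev)
        rel = diff / denom if denom > 0 else np.linalg.norm(cur)
        report.relative_change_history.append(rel)
        report.n_iters = it
        if rel > 1e6 or not np.isfinite(rel):
            raise RuntimeError(
                "primal-dual iteration diverged; the step sizes sigma/tau "
                "likely violate sigma * tau * ||K||^2 <= 1"
            )
        if record_objective and objective_cadence and it % objective_cadence == 0:
            report.objective_history.append(objective())
        if rel < config.eps_tol:
            report.converged = True
            break
        prev = cur.copy()

    if record_objective and not (
        objective_cadence and report.n_iters % objective_cadence == 0
    ):
        report.objective_history.append(objective())

    xc = current()
    if geometry is None:
        series = DynamicSeries(data=xc, dt=dt)
        ls = (
            LSDecomposition(
                L=DynamicSeries(data=L, dt=dt),
                S=DynamicSeries(data=S, dt=dt),
            )
            if with_ls else None
        )
    else:
        series = DynamicSeries(data=mu_to_hu(xc), dt=dt)
        # L is an image (affine HU map); S is a difference image (linear map)
        ls = (
            LSDecomposition(
                L=DynamicSeries(data=mu_to_hu(L), dt=dt),
                S=DynamicSeries(data=S * (1000.0 / MU_WATER), dt=dt),
            )
            if with_ls else None
        )
    return series, ls, report


# ---------------------------------------------------------------------------
# objective evaluation

def _tgv_cost(x: np.ndarray, alpha1: float, alpha0: float, tw: float,
              v_init: np.ndarray | None = None, tol: float = 1e-8,
              n_max: int = 2000) -> float:
    """Exact second-order TGV of ``x``: the inner minimization over v is run
    to tolerance with a small primal-dual iteration."""
    g = grad3(x, tw)
    v = np.zeros_like(g) if v_init is None else v_init.copy()
    vb = v.copy()
    r = np.zeros((6,) + x.shape)
    # ||E|| <= sqrt(12); steps chosen for sigma * tau * ||E||^2 < 1
    sigma = tau = 0.28
    cost = alpha1 * _l1_iso(g - v) + alpha0 * _l1_iso(
        sym_grad(v, tw), SYM_WEIGHTS
    )
    for _ in range(n_max):
        r = _project_linf(r + sigma * sym_grad(vb, tw), alpha0, SYM_WEIGHTS)
        z = v - tau * sym_grad_adjoint(r, tw)
        # prox of tau * alpha1 ||g - v||_1 in v
        v_new = g + soft_threshold(z - g, tau * alpha1, axis=0)
        vb = 2.0 * v_new - v
        chg = np.linalg.norm(v_new - v) / max(np.linalg.norm(v), 1e-12)
        v = v_new
        new_cost = alpha1 * _l1_iso(g - v) + alpha0 * _l1_iso(
            sym_grad(v, tw), SYM_WEIGHTS
        )
        if chg < tol:
            cost = new_cost
            break
        cost = new_cost
    return cost


def objective_value(
    x_or_ls,
    sino_series,
    geometry: ScanGeometry | None,
    config: RegularizerConfig,
    v_init: np.ndarray | None = None,
) -> float:
    """Evaluate the selected objective at ``x`` (or ``(L, S)``).

    Evaluates the objective in the solver's own scaling: the quadratic data
    term of the unit-spectral-norm rescaled system with all regularization
    weights as given (see :func:`reconstruct`).  For the TGV variants the
    inner minimization over the auxiliary field v is solved to tolerance
    (warm started from ``v_init`` when provided).
    """
    if isinstance(sino_series, SinogramSeries):
        b_raw = sino_series.data
    else:
        b_raw = np.asarray(sino_series, dtype=float)
    if b_raw.ndim == 2:
        b_raw = b_raw[:, :, None]

    tw = config.temporal_weight
    method = config.method
    if method in ("ltv", "ltgv"):
        L, S = x_or_ls
        L = np.asarray(L, float)
        S = np.asarray(S, float)
        x = L + S
        reg_target = S
    else:
        x = np.asarray(x_or_ls, float)
        reg_target = x
    if x.ndim == 2:
        x = x[:, :, None]
        reg_target = reg_target.reshape(x.shape)

    op = _SystemOp(geometry, x.shape)
    resid = op.A(x) - b_raw / op.norm
    val = 0.5 * float(np.sum(resid**2))
    beta_eff = config.beta / x.shape[2]  # per-frame nuclear norm

    if method == "tv":
        val += config.alpha * _l1_iso(grad3(reg_target, tw))
    elif method == "ltv":
        val += config.alpha * _l1_iso(grad3(reg_target, tw))
        val += beta_eff * _nuclear(L)
    elif method == "tgv":
        val += _tgv_cost(reg_target, config.alpha1, config.alpha0, tw, v_init)
    else:  # ltgv
        val += _tgv_cost(reg_target, config.alpha1, config.alpha0, tw, v_init)
        val += beta_eff * _nuclear(L)
    return val


def _nuclear(L: np.ndarray) -> float:
    ny, nx, nt = L.shape
    return float(np.sum(np.linalg.svd(
        L.reshape(ny * nx, nt), compute_uv=False
    )))
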
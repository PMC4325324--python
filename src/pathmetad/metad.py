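"""Well-tempered metadynamics: hill deposition, bias evaluation, walls, FES.

Gaussian hills are deposited at a fixed pace along the biased CV(s); in the
well-tempered scheme the deposit height decays as w0*exp(-V/(kB*deltaT)), so
the bias converges and relates to the free energy by
F = -(T+deltaT)/deltaT * V.  Restraining walls (half-harmonic) keep auxiliary
CVs -- typically the distance-from-path z -- inside a chosen region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB
from .fes import Axis, FESGrid
from .sampler import ToySystem, integrate, make_cv_evaluator
from .trace import CVTrace

__all__ = [
    "Hill",
    "WallRestraint",
    "BiasState",
    "evaluate_bias",
    "next_hill_height",
    "wall_energy",
    "run_wtmetad",
    "fes_from_bias",
    "StaticBiasController",
]

#: hills are neglected beyond this many sigmas from their center
HILL_CUTOFF_SIGMA = 6.0


@dataclass
class Hill:
    """One deposited Gaussian: center (per-CV), widths sigma, height, time."""

    center: np.ndarray
    sigma: np.ndarray
    height: float
    time: float

    def __post_init__(self):
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma <= 0) or self.height <= 0:
            raise ValueError("hill widths and height must be positive")


@dataclass
class WallRestraint:
    """Half-harmonic restraint on one CV: 0 on the allowed side, else
    (1/2) k (value - threshold)^2."""

    cv_id: str
    threshold: float
    spring: float
    side: str = "upper"

    def __post_init__(self):
        if self.spring < 0:
            raise ValueError("wall spring must be non-negative")
        if self.side not in ("upper", "lower"):
            raise ValueError("wall side must be 'upper' or 'lower'")


@dataclass
class BiasState:
    """The history-dependent bias: deposited hills plus run settings.

    ``sigma`` is the per-CV hill width used for new deposits; ``pace`` the
    deposition period (ps); ``w0`` the initial hill height (kJ/mol).
    """

    T: float
    deltaT: float
    pace: float
    w0: float
    sigma: np.ndarray = field(default_factory=lambda: np.array([0.03]))
    walls: list[WallRestraint] = field(default_factory=list)
    biased_cv_ids: list[str] = field(default_factory=lambda: ["s"])
    hills: list[Hill] = field(default_factory=list)

    def __post_init__(self):
        if self.deltaT <= 0 or self.pace <= 0 or self.w0 <= 0:
            raise ValueError("deltaT, pace and w0 must be positive")
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        times = [h.time for h in self.hills]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("hills must be sorted by time")

    @property
    def gamma(self) -> float:
        """Bias factor (T + deltaT)/T."""
        return (self.T + self.deltaT) / self.T

    def hill_arrays(self):
        if not self.hills:
            k = len(self.biased_cv_ids)
            return np.empty((0, k)), np.empty((0, k)), np.empty(0), np.empty(0)
        centers = np.stack([h.center for h in self.hills])
        sigmas = np.stack([h.sigma for h in self.hills])
        heights = np.array([h.height for h in self.hills])
        times = np.array([h.time for h in self.hills])
        return centers, sigmas, heights, times


def _gaussian_sum(points, centers, sigmas, heights):
    """Sum of Gaussians at ``points`` (m, k); hills truncated at 6 sigma."""
    if len(centers) == 0:
        return np.zeros(len(points))
    diff = (points[:, None, :] - centers[None, :, :]) / sigmas[None, :, :]
    arg = 0.5 * (diff ** 2).sum(axis=-1)
    vals = heights[None, :] * np.exp(-arg)
    vals[arg > 0.5 * HILL_CUTOFF_SIGMA ** 2] = 0.0
    return vals.sum(axis=1)


def evaluate_bias(bias: BiasState, point) -> float:
    """Total deposited bias V (kJ/mol) at a CV-space point (walls excluded)."""
    point = np.atleast_1d(np.asarray(point, dtype=float))
    centers, sigmas, heights, _ = bias.hill_arrays()
    return float(_gaussian_sum(point[None, :], centers, sigmas, heights)[0])


def next_hill_height(bias: BiasState, point) -> float:
    """Well-tempered height of the next hill: w0 * exp(-V/(kB*deltaT))."""
    v = evaluate_bias(bias, point)
    return bias.w0 * np.exp(-v / (KB * bias.deltaT))


def wall_energy(wall: WallRestraint, value: float) -> float:
    """Half-harmonic wall energy at a CV value (continuous, C1 at threshold)."""
    if wall.side == "upper":
        excess = value - wall.threshold
    else:
        excess = wall.threshold - value
    if excess <= 0.0:
        return 0.0
    return 0.5 * wall.spring * excess * excess


def fes_from_bias(bias: BiasState, grid_spec,
                  time_average_fraction: float = 0.0) -> FESGrid:
    """Free-energy surface implied by the bias: F = -(T+deltaT)/deltaT * V.

    ``grid_spec`` is a list of :class:`~pathmetad.fes.Axis` or (lo, hi, n[,
    label]) tuples, one per biased CV.  With ``time_average_fraction`` > 0
    the FES is averaged over the bias as it stood at each deposition in the
    final fraction of the run, which damps the well-tempered ripples.  The
    result is shifted so min F = 0.  An empty bias gives a flat zero grid.
    """
    axes = [ax if isinstance(ax, Axis) else Axis(*ax) for ax in grid_spec]
    shape = tuple(ax.n for ax in axes)
    mesh = np.meshgrid(*[ax.centers() for ax in axes], indexing="ij")
    points = np.stack([m.reshape(-1) for m in mesh], axis=1)
    centers, sigmas, heights, times = bias.hill_arrays()
    prefactor = (bias.T + bias.deltaT) / bias.deltaT
    if len(centers) == 0:
        return FESGrid(axes, np.zeros(shape))
    if time_average_fraction <= 0.0:
        v = _gaussian_sum(points, centers, sigmas, heights)
        f = -prefactor * v
        return FESGrid(axes, (f - f.min()).reshape(shape))
    t_start = times[-1] * (1.0 - time_average_fraction)
    first = int(np.searchsorted(times, t_start))
    first = min(first, len(times) - 1)
    v = _gaussian_sum(points, centers[:first], sigmas[:first], heights[:first])
    acc = np.zeros_like(v)
    n_snap = 0
    for i in range(first, len(centers)):
        v = v + _gaussian_sum(points, centers[i:i + 1], sigmas[i:i + 1],
                              heights[i:i + 1])
        acc += v
        n_snap += 1
    f = -prefactor * acc / n_snap
    return FESGrid(axes, (f - f.min()).reshape(shape))


# ---------------------------------------------------------------------------
# controllers coupling the bias to the Langevin engine


class _HillBuffer:
    """Growable hill storage with fast 1-CV evaluation.

    For a single biased CV the accumulated bias and its derivative are also
    kept on a fine uniform grid updated per deposit, so per-step lookups are
    O(1) linear interpolations (grid spacing is chosen well below the hill
    width, keeping the interpolation error orders of magnitude under kBT).
    Points outside the grid fall back to the exact Gaussian sum.
    """

    GRID_POINTS = 4001

    def __init__(self, capacity: int, k: int, grid_range=None):
        self.centers = np.empty((capacity, k))
        self.sigmas = np.empty((capacity, k))
        self.heights = np.empty(capacity)
        self.times = np.empty(capacity)
        self.n = 0
        self.grid = None
        if k == 1 and grid_range is not None:
            lo, hi = grid_range
            self.grid = np.linspace(lo, hi, self.GRID_POINTS)
            self.dx = self.grid[1] - self.grid[0]
            self.v_grid = np.zeros(self.GRID_POINTS)
            self.dv_grid = np.zeros(self.GRID_POINTS)

    def add(self, center, sigma, height, time):
        i = self.n
        self.centers[i] = center
        self.sigmas[i] = sigma
        self.heights[i] = height
        self.times[i] = time
        self.n += 1
        if self.grid is not None:
            c, s = float(center[0]), float(sigma[0])
            lo = np.searchsorted(self.grid, c - HILL_CUTOFF_SIGMA * s)
            hi = np.searchsorted(self.grid, c + HILL_CUTOFF_SIGMA * s)
            x = self.grid[lo:hi]
            g = height * np.exp(-0.5 * ((x - c) / s) ** 2)
            self.v_grid[lo:hi] += g
            self.dv_grid[lo:hi] += -g * (x - c) / s ** 2

    def _exact(self, point):
        n = self.n
        diff = (point[None, :] - self.centers[:n]) / self.sigmas[:n]
        arg = 0.5 * (diff ** 2).sum(axis=1)
        mask = arg <= 0.5 * HILL_CUTOFF_SIGMA ** 2
        g = np.where(mask, self.heights[:n] * np.exp(-arg), 0.0)
        v = g.sum()
        dv = -(g[:, None] * diff / self.sigmas[:n]).sum(axis=0)
        return float(v), dv

    def value_and_deriv(self, point):
        """V and dV/dx_k at one CV point."""
        if self.n == 0:
            return 0.0, np.zeros(self.centers.shape[1])
        if self.grid is not None:
            x = point[0]
            if self.grid[0] <= x <= self.grid[-1]:
                j = int((x - self.grid[0]) / self.dx)
                j = min(j, len(self.grid) - 2)
                frac = (x - self.grid[j]) / self.dx
                v = (1.0 - frac) * self.v_grid[j] + frac * self.v_grid[j + 1]
                dv = (1.0 - frac) * self.dv_grid[j] + frac * self.dv_grid[j + 1]
                return float(v), np.array([dv])
        return self._exact(point)


class WTMetadController:
    """Deposits well-tempered hills and applies bias + wall forces."""

    def __init__(self, params: BiasState, cv_names, n_hills_max, pace_steps,
                 grid_range=None):
        self.params = params
        k = len(params.biased_cv_ids)
        self.biased_cols = [cv_names.index(c) for c in params.biased_cv_ids]
        self.buffer = _HillBuffer(n_hills_max, k, grid_range=grid_range)
        self.pace_steps = pace_steps
        self.kb_dt = KB * params.deltaT
        self.wall_cols = [(cv_names.index(w.cv_id), w) for w in params.walls]
        self.sigma = params.sigma

    def _point(self, values):
        return values[self.biased_cols]

    def force(self, values, grads):
        _, dv = self.buffer.value_and_deriv(self._point(values))
        f = -np.einsum("k,kd->d", dv, grads[self.biased_cols])
        for col, wall in self.wall_cols:
            excess = (values[col] - wall.threshold if wall.side == "upper"
                      else wall.threshold - values[col])
            if excess > 0.0:
                sign = 1.0 if wall.side == "upper" else -1.0
                f -= sign * wall.spring * excess * grads[col]
        return f

    def bias_energy(self, values) -> float:
        v, _ = self.buffer.value_and_deriv(self._point(values))
        return v

    def after_step(self, step, time, values):
        if step % self.pace_steps == 0:
            point = self._point(values)
            v, _ = self.buffer.value_and_deriv(point)
            height = self.params.w0 * np.exp(-v / self.kb_dt)
            self.buffer.add(point, self.sigma, height, time)

    def to_bias_state(self) -> BiasState:
        buf = self.buffer
        hills = [Hill(center=buf.centers[i].copy(), sigma=buf.sigmas[i].copy(),
                      height=float(buf.heights[i]), time=float(buf.times[i]))
                 for i in range(buf.n)]
        p = self.params
        return BiasState(T=p.T, deltaT=p.deltaT, pace=p.pace, w0=p.w0,
                         sigma=p.sigma.copy(), walls=list(p.walls),
                         biased_cv_ids=list(p.biased_cv_ids), hills=hills)


class StaticBiasController:
    """Applies a fixed, non-growing bias (plus walls) during sampling."""

    def __init__(self, bias: BiasState, cv_names=None):
        names = cv_names if cv_names is not None else list(bias.biased_cv_ids)
        k = len(bias.biased_cv_ids)
        self.buffer = _HillBuffer(max(len(bias.hills), 1), k)
        for h in bias.hills:
            self.buffer.add(h.center, h.sigma, h.height, h.time)
        self.biased_cols = [names.index(c) for c in bias.biased_cv_ids
                            if c in names]
        if len(self.biased_cols) != k:
            # fall back to positional mapping (e.g. 1-D coordinate named 'x')
            self.biased_cols = list(range(k))
        self.wall_cols = [(names.index(w.cv_id), w) for w in bias.walls
                          if w.cv_id in names]

    def force(self, values, grads):
        point = values[self.biased_cols]
        _, dv = self.buffer.value_and_deriv(point)
        f = -np.einsum("k,kd->d", dv, grads[self.biased_cols])
        for col, wall in self.wall_cols:
            excess = (values[col] - wall.threshold if wall.side == "upper"
                      else wall.threshold - values[col])
            if excess > 0.0:
                sign = 1.0 if wall.side == "upper" else -1.0
                f -= sign * wall.spring * excess * grads[col]
        return f

    def bias_energy(self, values) -> float:
        v, _ = self.buffer.value_and_deriv(values[self.biased_cols])
        return v

    def after_step(self, step, time, values):
        pass


def run_wtmetad(system: ToySystem, path, params: BiasState, n_steps: int,
                seed: int | None = None, record_every: int | None = None,
                aux_paths=()):
    """Run well-tempered metadynamics on a system.

    The bias acts on the first CV (path progress s, or the bare coordinate
    for 1-D systems); walls listed in ``params`` act on their named CV
    (typically z).  Hills are deposited every ``params.pace`` ps with the
    adaptive well-tempered height.  ``aux_paths`` is a sequence of
    (prefix, ReferencePath) whose unbiased (s, z) are recorded for
    post-processing.

    Returns ``(CVTrace, BiasState, trajectory)``, reproducible from the seed.
    """
    dt = system.timestep
    pace_steps = int(round(params.pace / dt))
    if pace_steps < 1 or abs(pace_steps * dt - params.pace) > 1e-9 * params.pace:
        raise ValueError("pace must be a whole number of timesteps")
    if record_every is None:
        record_every = max(pace_steps // 10, 1)
    if pace_steps % record_every != 0:
        raise ValueError("pace must be a multiple of the recording stride")
    if abs(params.T - system.temperature) > 1e-9:
        raise ValueError("bias and system temperatures disagree")

    cv_fn, names = make_cv_evaluator(system, path)
    if cv_fn is None:
        raise ValueError("system has no biasable CV (need a path or a 1-D system)")
    n_hills_max = n_steps // pace_steps + 1
    if len(params.biased_cv_ids) == 1:
        if path is not None:
            grid_range = (0.0, float(path.n_frames) + 1.0)
        else:
            x0 = float(system.coords0[0])
            grid_range = (x0 - 8.0, x0 + 8.0)
    else:
        grid_range = None
    controller = WTMetadController(params, names, n_hills_max, pace_steps,
                                   grid_range=grid_range)

    aux_fns = []
    for prefix, aux_path in aux_paths:
        n = system.template.n_particles

        def make_fn(p):
            def fn(x):
                vals, _ = _aux_path_cv(x.reshape(n, 3), p)
                return vals
            return fn

        aux_fns.append(([f"{prefix}s", f"{prefix}z"], make_fn(aux_path)))

    rng = np.random.default_rng(system.seed if seed is None else seed)
    traj, times, cv_rec, bias_rec, aux_names = integrate(
        system, n_steps, rng, cv_fn=cv_fn, controller=controller,
        record_every=record_every, aux_fns=aux_fns)
    if system.template is not None:
        traj = traj.reshape(len(traj), system.template.n_particles, 3)
    trace = CVTrace(times=times, names=names + aux_names, values=cv_rec,
                    bias_energy=bias_rec)
    return trace, controller.to_bias_state(), traj


def _aux_path_cv(coords, path):
    from .pathcv import _sz_from_profile
    _, _, d2 = path.msd_profile(coords)
    s, z, _, _ = _sz_from_profile(d2, path.lam)
    return np.array([s, z]), None
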
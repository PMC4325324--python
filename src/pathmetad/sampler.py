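"""Langevin dynamics on analytic potentials and a synthetic two-domain model.

This module generates the study systems: a 1-D tilted double well with an
exactly designed barrier and minimum offset, and a planar two-domain bead
"protein" whose open and closed endpoint structures differ by hinge rotations
of the mobile blocks.  Both are sampled with a BAOAB-split Langevin
integrator; a metadynamics bias can be coupled to the dynamics through
collective variables (a bare coordinate, or path CVs with analytic gradients
through the optimal superposition).

Units: nm, ps, K, kJ/mol, amu.  All randomness flows from one seeded
generator per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import KB
from .geometry import Configuration
from .pathcv import ReferencePath, eval_path_cv_with_grad
from .trace import CVTrace

__all__ = [
    "ToySystem",
    "TwoDomainModel",
    "DoubleWellPotential",
    "HarmonicPotential",
    "TwoDomainPotential",
    "make_double_well",
    "make_two_domain_model",
    "run_langevin",
]


# ---------------------------------------------------------------------------
# potentials


def _solve_tilted_quartic(barrier: float, offset: float):
    """Coefficients (b, c) of U(xi) = b (xi^2-1)^2 + (c/2)(xi^3 - 3 xi).

    The cubic tilt keeps the two minima pinned at xi = +-1 while offsetting
    them by exactly ``offset`` (the xi=+1 well is the lower one); ``b`` is
    solved so the interior saddle sits exactly ``barrier`` above the lower
    minimum.  Requires barrier > offset >= 0.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if barrier <= offset:
        raise ValueError("barrier (from the lower minimum) must exceed the offset")
    c = offset / 2.0
    if c == 0.0:
        return barrier, 0.0

    def u(xi, b):
        return b * (xi ** 2 - 1.0) ** 2 + 0.5 * c * (xi ** 3 - 3.0 * xi)

    def gap(b):
        xi_s = -3.0 * c / (8.0 * b)   # interior stationary point
        return u(xi_s, b) - u(1.0, b) - barrier

    lo = 3.0 * c / 8.0 * (1.0 + 1e-9) + 1e-12
    hi = barrier + offset + 1.0
    b = brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return b, c


@dataclass
class DoubleWellPotential:
    """1-D tilted quartic double well with minima at x = +-x0.

    The saddle lies exactly ``barrier`` kJ/mol above the lower (x = +x0)
    minimum and the minima differ by exactly ``offset`` kJ/mol.
    """

    barrier: float
    offset: float = 0.0
    x0: float = 1.0
    b: float = field(init=False)
    c: float = field(init=False)

    def __post_init__(self):
        self.b, self.c = _solve_tilted_quartic(self.barrier, self.offset)

    @property
    def saddle_x(self) -> float:
        if self.c == 0.0:
            return 0.0
        return -3.0 * self.c / (8.0 * self.b) * self.x0

    def energy_scalar(self, x: float) -> float:
        xi = x / self.x0
        return self.b * (xi * xi - 1.0) ** 2 + 0.5 * self.c * (xi ** 3 - 3.0 * xi)

    def energy(self, x: np.ndarray) -> float:
        return self.energy_scalar(float(x[0]))

    def force(self, x: np.ndarray) -> np.ndarray:
        xi = float(x[0]) / self.x0
        du = (xi * xi - 1.0) * (4.0 * self.b * xi + 1.5 * self.c) / self.x0
        return np.array([-du])


@dataclass
class HarmonicPotential:
    """Isotropic harmonic well, mostly for integrator checks."""

    k: float = 1.0
    center: float = 0.0

    def energy(self, x: np.ndarray) -> float:
        return 0.5 * self.k * float(((x - self.center) ** 2).sum())

    def force(self, x: np.ndarray) -> np.ndarray:
        return -self.k * (x - self.center)


@dataclass
class _HingeTerm:
    hinge: int
    ref: int
    block: np.ndarray
    b: float
    c: float
    theta_mid: float
    theta_half: float

    def theta(self, r: np.ndarray) -> float:
        u = r[self.ref, :2] - r[self.hinge, :2]
        v = r[self.block, :2].mean(axis=0) - r[self.hinge, :2]
        return float(np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v))


@dataclass
class TwoDomainPotential:
    """Harmonic network + hinge double wells of the bead model (planar)."""

    pairs: np.ndarray          # (n_pairs, 2) int
    rest: np.ndarray           # (n_pairs,) rest lengths nm
    stiffness: float           # kJ/mol/nm^2
    hinges: list[_HingeTerm]
    n_particles: int

    def _hinge_energy(self, term: _HingeTerm, theta: float) -> float:
        xi = (theta - term.theta_mid) / term.theta_half
        return term.b * (xi * xi - 1.0) ** 2 + 0.5 * term.c * (xi ** 3 - 3.0 * xi)

    def energy(self, x: np.ndarray) -> float:
        r = x.reshape(self.n_particles, 3)
        d = r[self.pairs[:, 0]] - r[self.pairs[:, 1]]
        dist = np.sqrt((d * d).sum(axis=1))
        e = 0.5 * self.stiffness * ((dist - self.rest) ** 2).sum()
        for term in self.hinges:
            e += self._hinge_energy(term, term.theta(r))
        return float(e)

    def force(self, x: np.ndarray) -> np.ndarray:
        r = x.reshape(self.n_particles, 3)
        f = np.zeros_like(r)
        d = r[self.pairs[:, 0]] - r[self.pairs[:, 1]]
        dist = np.sqrt((d * d).sum(axis=1))
        # guard: coincident beads have zero separation direction
        dist = np.maximum(dist, 1e-12)
        mag = -self.stiffness * (dist - self.rest) / dist
        fv = mag[:, None] * d
        np.add.at(f, self.pairs[:, 0], fv)
        np.add.at(f, self.pairs[:, 1], -fv)
        for term in self.hinges:
            u = r[term.ref, :2] - r[term.hinge, :2]
            g = r[term.block, :2].mean(axis=0)
            v = g - r[term.hinge, :2]
            theta = float(np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v))
            xi = (theta - term.theta_mid) / term.theta_half
            du_dtheta = ((xi * xi - 1.0) * (4.0 * term.b * xi + 1.5 * term.c)
                         / term.theta_half)
            dth_dv = np.array([-v[1], v[0]]) / (v @ v)
            dth_du = -np.array([-u[1], u[0]]) / (u @ u)
            nb = len(term.block)
            f[term.block, :2] += -du_dtheta * dth_dv / nb
            f[term.ref, :2] += -du_dtheta * dth_du
            f[term.hinge, :2] += du_dtheta * (dth_dv + dth_du)
        return f.reshape(-1)


# ---------------------------------------------------------------------------
# systems


@dataclass
class ToySystem:
    """A sampleable system: potential + thermodynamic and integrator settings."""

    potential: object
    coords0: np.ndarray          # flat (d,)
    masses: np.ndarray           # (d,)
    temperature: float           # K
    friction: float              # ps^-1
    timestep: float              # ps
    seed: int = 0
    active: np.ndarray | None = None   # bool mask of mobile dof (None = all)
    template: Configuration | None = None  # particle layout for Cartesian systems

    def __post_init__(self):
        self.coords0 = np.asarray(self.coords0, dtype=float).reshape(-1)
        self.masses = np.broadcast_to(
            np.asarray(self.masses, dtype=float), self.coords0.shape).copy()
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.active is None:
            self.active = np.ones_like(self.coords0, dtype=bool)
        e0 = self.potential.energy(self.coords0)
        if not np.isfinite(e0):
            raise ValueError("potential is not finite at the initial coordinates")


def make_double_well(barrier_kJ: float, offset_kJ: float = 0.0, *,
                     x0: float = 1.0, temperature: float = 300.0,
                     friction: float = 5.0, timestep: float = 0.005,
                     mass: float = 1.0, seed: int = 0) -> ToySystem:
    """A 1-D double-well system with exactly designed barrier and offset.

    The particle starts in the higher (x = -x0) minimum, mimicking a run
    started from the less stable conformer.
    """
    pot = DoubleWellPotential(barrier=barrier_kJ, offset=offset_kJ, x0=x0)
    return ToySystem(potential=pot, coords0=np.array([-x0]), masses=np.array([mass]),
                     temperature=temperature, friction=friction,
                     timestep=timestep, seed=seed)


@dataclass
class TwoDomainModel:
    """Synthetic two-domain bead protein with designed hinge thermodynamics.

    A static core block carries two mobile blocks ("lid-like" and
    "nmp-like"), each hinged at a core bead.  Intra-block distances and
    block-to-hinge distances are restrained harmonically, so each hinge angle
    is the only soft degree of freedom; a tilted-quartic double well on the
    angle sets the designed barrier (above the lower, open well) and the
    open/closed free-energy offset.  The model is planar (z frozen), which
    keeps the designed hinge profile free of orientational-measure
    corrections.
    """

    closed_endpoint: Configuration
    open_endpoint: Configuration
    potential: TwoDomainPotential
    lid_barrier: float   # kJ/mol
    lid_offset: float    # kJ/mol; the closed well sits this much higher
    nmp_barrier: float
    nmp_offset: float
    temperature: float
    seed: int
    geometry: dict = field(default_factory=dict, repr=False)

    def build_at_angles(self, phi_lid: float, phi_nmp: float) -> Configuration:
        """Configuration with the mobile blocks rigidly rotated to given
        hinge placement angles (radians, same convention as the endpoints)."""
        g = self.geometry
        core = g["core"]
        gl = core[g["h_lid"]] + g["r_lid"] * np.array([np.cos(phi_lid),
                                                       np.sin(phi_lid)])
        gn = core[g["h_nmp"]] + g["r_nmp"] * np.array([np.cos(phi_nmp),
                                                       np.sin(phi_nmp)])
        lid = _block_coords(gl, phi_lid, g["lid_off"])
        nmp = _block_coords(gn, phi_nmp, g["nmp_off"])
        xy = np.vstack([core, lid, nmp])
        coords = np.hstack([xy, np.zeros((len(xy), 1))])
        t = self.closed_endpoint
        return Configuration(coords, list(t.labels),
                             {k: v.copy() for k, v in t.selections.items()})

    def path_endpoints(self, margin: float = 0.25):
        """Endpoints for the reference path, extended beyond the metastable
        states by ``margin`` of the closed-open hinge rotation on either
        side.  Keeping the wells at interior path frames avoids the softmax
        end-saturation of s, which would otherwise distort well depths."""
        g = self.geometry
        span_l = g["phi_lid"]["open"] - g["phi_lid"]["closed"]
        span_n = g["phi_nmp"]["open"] - g["phi_nmp"]["closed"]
        ext_closed = self.build_at_angles(
            g["phi_lid"]["closed"] - margin * span_l,
            g["phi_nmp"]["closed"] - margin * span_n)
        ext_open = self.build_at_angles(
            g["phi_lid"]["open"] + margin * span_l,
            g["phi_nmp"]["open"] + margin * span_n)
        return ext_closed, ext_open

    def make_system(self, *, friction: float = 5.0, timestep: float = 0.004,
                    mass: float = 1.0, seed: int | None = None,
                    start: str = "closed") -> ToySystem:
        start_cfg = self.closed_endpoint if start == "closed" else self.open_endpoint
        coords0 = start_cfg.coords.reshape(-1)
        n = start_cfg.n_particles
        active = np.ones((n, 3), dtype=bool)
        active[:, 2] = False          # planar model: z frozen
        return ToySystem(potential=self.potential, coords0=coords0,
                         masses=np.full(3 * n, mass), temperature=self.temperature,
                         friction=friction, timestep=timestep,
                         seed=self.seed if seed is None else seed,
                         active=active.reshape(-1), template=start_cfg)


def _block_coords(center, angle, offsets):
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return center + offsets @ rot.T


def make_two_domain_model(seed: int = 0, *, barrier_kbt: float = 4.0,
                          offset_kbt: float = 1.5, nmp_barrier_kbt: float = 2.0,
                          nmp_offset_kbt: float = 1.0, temperature: float = 300.0,
                          stiffness: float = 1500.0, n_core: int = 4,
                          n_lid: int = 3, n_nmp: int = 3) -> TwoDomainModel:
    """Build the planar two-domain bead model, reproducibly from a seed.

    Bead placements get a small seeded jitter (0.02 nm) so different seeds
    give genuinely different geometries; endpoints are built from the same
    jittered template, differing only by the hinge rotations (60 degrees per
    hinge, closed -> open, a protein-like domain swing for which the linear
    morph chord stays close to the rotation arc).
    """
    if min(n_core, n_lid, n_nmp) < 3:
        raise ValueError("need at least 3 beads per block")
    rng = np.random.default_rng(seed)
    kt = KB * temperature

    # core template: hinge beads at fixed sites, remaining beads on an arc
    core = [np.array([0.0, 0.0]), np.array([-0.5, 0.0])]
    for i in range(n_core - 2):
        ang = np.pi / 2 + i * 0.6
        core.append(np.array([-0.25 + 0.45 * np.cos(ang), 0.45 * np.sin(ang)]))
    core = np.stack(core)
    core[2:] += rng.normal(0.0, 0.02, size=core[2:].shape)

    def block_offsets(n, radius):
        ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        off = radius * np.stack([np.cos(ang), np.sin(ang)], axis=1)
        off += rng.normal(0.0, 0.02, size=off.shape)
        return off - off.mean(axis=0)

    lid_off = block_offsets(n_lid, 0.28)
    nmp_off = block_offsets(n_nmp, 0.25)
    r_lid, r_nmp = 1.4, 1.1
    h_lid, h_nmp = 0, 1           # hinge bead indices (core beads)
    ref_lid, ref_nmp = 1, 0       # angle reference beads
    phi_lid = {"closed": np.deg2rad(120.0), "open": np.deg2rad(60.0)}
    phi_nmp = {"closed": np.deg2rad(-120.0), "open": np.deg2rad(-60.0)}

    def build(state):
        gl = core[h_lid] + r_lid * np.array([np.cos(phi_lid[state]),
                                             np.sin(phi_lid[state])])
        gn = core[h_nmp] + r_nmp * np.array([np.cos(phi_nmp[state]),
                                             np.sin(phi_nmp[state])])
        lid = _block_coords(gl, phi_lid[state], lid_off)
        nmp = _block_coords(gn, phi_nmp[state], nmp_off)
        xy = np.vstack([core, lid, nmp])
        return np.hstack([xy, np.zeros((len(xy), 1))])

    idx_core = np.arange(n_core)
    idx_lid = np.arange(n_core, n_core + n_lid)
    idx_nmp = np.arange(n_core + n_lid, n_core + n_lid + n_nmp)
    selections = {"CORE": idx_core, "LID": idx_lid, "NMP": idx_nmp}
    labels = ([f"CORE{i}" for i in range(n_core)]
              + [f"LID{i}" for i in range(n_lid)]
              + [f"NMP{i}" for i in range(n_nmp)])

    closed = Configuration(build("closed"), labels, selections)
    opened = Configuration(build("open"), labels, selections)

    # spring network: all pairs inside each block, plus block beads to hinge
    pairs = []
    for block in (idx_core, idx_lid, idx_nmp):
        for a in range(len(block)):
            for b in range(a + 1, len(block)):
                pairs.append((block[a], block[b]))
    pairs += [(i, h_lid) for i in idx_lid]
    pairs += [(i, h_nmp) for i in idx_nmp]
    pairs = np.array(pairs)
    rc = closed.coords
    rest = np.sqrt(((rc[pairs[:, 0]] - rc[pairs[:, 1]]) ** 2).sum(axis=1))

    def hinge_term(hinge, ref, block, barrier, offset):
        b, c = _solve_tilted_quartic(barrier, offset)
        term = _HingeTerm(hinge=hinge, ref=ref, block=block, b=b, c=c,
                          theta_mid=0.0, theta_half=1.0)
        th_closed = term.theta(closed.coords)
        th_open = term.theta(opened.coords)
        term.theta_mid = 0.5 * (th_open + th_closed)
        term.theta_half = 0.5 * (th_open - th_closed)
        return term

    lid_barrier = barrier_kbt * kt
    lid_offset = offset_kbt * kt
    nmp_barrier = nmp_barrier_kbt * kt
    nmp_offset = nmp_offset_kbt * kt
    hinges = [hinge_term(h_lid, ref_lid, idx_lid, lid_barrier, lid_offset),
              hinge_term(h_nmp, ref_nmp, idx_nmp, nmp_barrier, nmp_offset)]

    pot = TwoDomainPotential(pairs=pairs, rest=rest, stiffness=stiffness,
                             hinges=hinges, n_particles=len(labels))
    geometry = {"core": core, "lid_off": lid_off, "nmp_off": nmp_off,
                "r_lid": r_lid, "r_nmp": r_nmp, "h_lid": h_lid, "h_nmp": h_nmp,
                "phi_lid": phi_lid, "phi_nmp": phi_nmp}
    return TwoDomainModel(closed_endpoint=closed, open_endpoint=opened,
                          potential=pot, lid_barrier=lid_barrier,
                          lid_offset=lid_offset, nmp_barrier=nmp_barrier,
                          nmp_offset=nmp_offset, temperature=temperature,
                          seed=seed, geometry=geometry)


# ---------------------------------------------------------------------------
# Langevin engine


def make_cv_evaluator(system: ToySystem, path: ReferencePath | None):
    """CV function (values, grads) for a system: path CVs or the bare coordinate."""
    if path is not None:
        if system.template is None:
            raise ValueError("path CVs need a Cartesian system with a template")
        n = system.template.n_particles

        def cv(x, need_grads=True):
            coords = x.reshape(n, 3)
            s, z, gs, gz = eval_path_cv_with_grad(coords, path)
            if not need_grads:
                return np.array([s, z]), None
            return np.array([s, z]), np.stack([gs.reshape(-1), gz.reshape(-1)])

        return cv, ["s", "z"]
    if system.coords0.size == 1:
        def cv(x, need_grads=True):
            return x.copy(), np.ones((1, 1))

        return cv, ["x"]
    return None, []


def integrate(system: ToySystem, n_steps: int, rng: np.random.Generator, *,
              cv_fn=None, controller=None, record_every: int = 1,
              aux_fns=()):
    """BAOAB Langevin integration with optional CV-coupled bias controller.

    ``controller`` (if given) provides ``force(values, grads) -> flat bias
    force``, ``bias_energy(values) -> kJ/mol`` and ``after_step(step, time,
    values)`` (hill deposition).  ``aux_fns`` are (names, fn(x)->values)
    pairs evaluated only at record steps.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    dt = system.timestep
    m = system.masses
    act = system.active
    kt = KB * system.temperature
    c1 = np.exp(-system.friction * dt)
    c2 = np.sqrt((1.0 - c1 * c1) * kt / m)

    x = system.coords0.copy()
    v = rng.normal(0.0, 1.0, size=x.shape) * np.sqrt(kt / m)
    v[~act] = 0.0

    def total_force(xx):
        f = system.potential.force(xx).astype(float, copy=True)
        values = grads = None
        if cv_fn is not None:
            values, grads = cv_fn(xx, controller is not None)
        if controller is not None:
            f = f + controller.force(values, grads)
        f[~act] = 0.0
        return f, values

    f, values = total_force(x)
    n_rec = n_steps // record_every
    traj = np.empty((n_rec, x.size))
    times = np.empty(n_rec)
    k_cv = len(values) if values is not None else 0
    aux_names = [nm for names, _ in aux_fns for nm in names]
    cv_rec = np.empty((n_rec, k_cv + len(aux_names)))
    bias_rec = np.zeros(n_rec)
    i_rec = 0

    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        v += half * f / m
        x += half * v
        noise = rng.normal(0.0, 1.0, size=x.shape)
        v = c1 * v + c2 * noise
        v[~act] = 0.0
        x += half * v
        f, values = total_force(x)
        v += half * f / m
        if not np.all(np.isfinite(f)) or not np.all(np.isfinite(x)):
            raise RuntimeError(f"non-finite energy/force at step {step}")
        t = step * dt
        if controller is not None:
            if values is None:
                values, _ = cv_fn(x, False)
            controller.after_step(step, t, values)
        if step % record_every == 0:
            traj[i_rec] = x
            times[i_rec] = t
            if values is None and cv_fn is not None:
                values, _ = cv_fn(x, False)
            if k_cv:
                cv_rec[i_rec, :k_cv] = values
            col = k_cv
            for names, fn in aux_fns:
                av = fn(x)
                cv_rec[i_rec, col:col + len(names)] = av
                col += len(names)
            if controller is not None:
                bias_rec[i_rec] = controller.bias_energy(values)
            i_rec += 1
    return traj, times, cv_rec, bias_rec, aux_names


def run_langevin(system: ToySystem, n_steps: int, bias=None,
                 path: ReferencePath | None = None, record_every: int = 1,
                 seed: int | None = None):
    """Sample a system, optionally under a *static* (non-growing) bias.

    Returns ``(trajectory, CVTrace)``; the trajectory has shape
    (n_records, N, 3) for Cartesian systems and (n_records, d) otherwise.
    Fully reproducible from the seed (defaults to ``system.seed``).
    """
    rng = np.random.default_rng(system.seed if seed is None else seed)
    cv_fn, names = make_cv_evaluator(system, path)
    controller = None
    if bias is not None:
        from .metad import StaticBiasController
        controller = StaticBiasController(bias)
    traj, times, cv_rec, bias_rec, _ = integrate(
        system, n_steps, rng, cv_fn=cv_fn, controller=controller,
        record_every=record_every)
    if system.template is not None:
        traj = traj.reshape(len(traj), system.template.n_particles, 3)
    trace = CVTrace(times=times, names=names, values=cv_rec,
                    bias_energy=bias_rec)
    return traj, trace
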
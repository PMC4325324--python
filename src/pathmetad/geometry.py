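"""Rigid-body superposition and the mean-square-displacement metric.

Distances between configurations are measured as the mean square displacement
(MSD, nm**2) of a *measured* atom subset after optimal rigid superposition on
an *alignment* atom subset.  The two subsets may differ: e.g. a hinge motion
is often quantified by aligning on the static core and measuring the mobile
domain.  Superpositions are unweighted and always proper rotations (no
reflections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Configuration",
    "Superposition",
    "DegenerateAlignmentError",
    "optimal_align",
    "msd_after_alignment",
    "apply_superposition",
    "NO_ALIGNMENT",
]

#: sentinel selection disabling superposition (raw-coordinate MSD); used for
#: systems whose frame of reference is fixed, e.g. single-particle paths
NO_ALIGNMENT = "none"


class DegenerateAlignmentError(ValueError):
    """Raised when an alignment subset cannot define a unique rotation."""


@dataclass
class Configuration:
    """One microscopic state: ordered particle coordinates with named selections.

    Parameters
    ----------
    coords : (N, 3) array, nm
    labels : per-particle identifiers (optional; defaults to str indices)
    selections : mapping of selection name -> integer index array
    """

    coords: np.ndarray
    labels: list[str] | None = None
    selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("a configuration needs at least one particle")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.labels is None:
            self.labels = [str(i) for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("labels length must match particle count")
        clean = {}
        for name, idx in self.selections.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise ValueError(f"selection {name!r} indexes out of range")
            clean[name] = idx
        self.selections = clean

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]

    def resolve(self, selection) -> np.ndarray:
        """Turn a selection spec (name, index array, or None=all) into indices."""
        if selection is None:
            return np.arange(self.n_particles)
        if isinstance(selection, str):
            try:
                return self.selections[selection]
            except KeyError:
                raise KeyError(f"unknown selection {selection!r}") from None
        return np.asarray(selection, dtype=int)

    def with_coords(self, coords: np.ndarray) -> "Configuration":
        """A copy of this configuration with replaced coordinates."""
        return Configuration(np.array(coords, dtype=float), list(self.labels),
                             {k: v.copy() for k, v in self.selections.items()})


@dataclass
class Superposition:
    """A proper rigid-body transform x -> R x + t with its residual MSD.

    ``rotation`` is a proper orthogonal 3x3 matrix (det = +1), ``translation``
    a 3-vector in nm, and ``msd`` the mean square displacement (nm**2) over
    the alignment subset after applying the transform to the mobile set.
    """

    rotation: np.ndarray
    translation: np.ndarray
    msd: float


def _check_alignable(points: np.ndarray, what: str) -> None:
    if points.shape[0] < 3:
        raise DegenerateAlignmentError(
            f"{what}: need at least 3 alignment points, got {points.shape[0]}")
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    # collinear (or coincident) point sets leave the rotation about the line free
    if s[1] <= 1e-10 + 1e-8 * s[0]:
        raise DegenerateAlignmentError(
            f"{what}: alignment points are (nearly) collinear; rotation not unique")


def kabsch_batch(mobile: np.ndarray, reference: np.ndarray):
    """Proper-rotation Kabsch superposition, batched over leading axes.

    Parameters
    ----------
    mobile : (..., n, 3) point sets to be moved
    reference : (..., n, 3) fixed point sets

    Returns
    -------
    rot : (..., 3, 3) proper rotations R
    trans : (..., 3) translations t such that R x + t best matches reference
    msd : (...,) residual mean square displacement over the n points
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mu_m = mobile.mean(axis=-2, keepdims=True)
    mu_r = reference.mean(axis=-2, keepdims=True)
    xm = mobile - mu_m
    xr = reference - mu_r
    # cross-covariance C = Xr^T Xm ; R = U diag(1,1,d) V^T with C = U S V^T
    cov = np.swapaxes(xr, -1, -2) @ xm
    u, s, vt = np.linalg.svd(cov)
    det = np.linalg.det(u @ vt)
    d = np.ones(u.shape[:-2] + (3,))
    d[..., 2] = np.sign(det)
    rot = (u * d[..., None, :]) @ vt
    n = mobile.shape[-2]
    ssd = (xm ** 2).sum(axis=(-1, -2)) + (xr ** 2).sum(axis=(-1, -2))
    msd = (ssd - 2.0 * (s * d).sum(axis=-1)) / n
    msd = np.maximum(msd, 0.0)
    trans = (mu_r - mu_m @ np.swapaxes(rot, -1, -2))[..., 0, :]
    return rot, trans, msd


def optimal_align(mobile: Configuration, reference: Configuration,
                  align_idx=None) -> Superposition:
    """Optimal (least-MSD) proper rigid superposition of ``mobile`` onto ``reference``.

    The transform minimizes the mean square deviation over the alignment
    subset; ``reference`` is left fixed.  Raises
    :class:`DegenerateAlignmentError` for fewer than 3 or collinear alignment
    points.
    """
    ia = mobile.resolve(align_idx)
    ib = reference.resolve(align_idx)
    if ia.shape != ib.shape:
        raise ValueError("alignment subsets differ in size between configurations")
    pm = mobile.coords[ia]
    pr = reference.coords[ib]
    _check_alignable(pm, "mobile")
    _check_alignable(pr, "reference")
    rot, trans, msd = kabsch_batch(pm, pr)
    return Superposition(rotation=rot, translation=trans, msd=float(msd))


def apply_superposition(coords: np.ndarray, sup: Superposition) -> np.ndarray:
    """Apply x -> R x + t to an (N, 3) coordinate array."""
    return coords @ sup.rotation.T + sup.translation


def msd_after_alignment(a: Configuration, b: Configuration,
                        align_idx=None, measure_idx=None) -> float:
    """MSD (nm**2) of the measured subset after superposing ``a`` onto ``b``.

    Superposes on ``align_idx`` and evaluates the mean squared deviation over
    ``measure_idx``.  Symmetric in (a, b) when the two subsets coincide.
    """
    if isinstance(measure_idx, str) and measure_idx == NO_ALIGNMENT:
        raise ValueError("measure_idx cannot be the no-alignment sentinel")
    im = a.resolve(measure_idx)
    if im.size == 0:
        raise ValueError("measure_idx must not be empty")
    if isinstance(align_idx, str) and align_idx == NO_ALIGNMENT:
        diff = a.coords[im] - b.coords[b.resolve(measure_idx)]
        return float((diff ** 2).sum() / im.size)
    sup = optimal_align(a, b, align_idx)
    moved = apply_superposition(a.coords[im], sup)
    diff = moved - b.coords[b.resolve(measure_idx)]
    return float((diff ** 2).sum() / im.size)
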
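"""Reweighting of well-tempered metadynamics trajectories.

Projects a biased trajectory onto CVs other than the biased one to obtain
unbiased free-energy surfaces.  Each record is weighted by

    w_i  propto  exp( (V(s_i, t_i) - c(t_i)) / kB T )

where V is the instantaneous bias and c(t) the time-dependent bias offset

    c(t) = (1/beta) ln [ sum_x exp(beta*gamma/(gamma-1)*V(x,t))
                       / sum_x exp(beta/(gamma-1)*V(x,t)) ],
    gamma = (T + deltaT)/T,

evaluated on a grid over the biased CV as the bias evolves.  This is the
standard time-dependent-offset estimator for well-tempered runs; weights are
normalized to mean 1 and are invariant under adding a constant to the bias
(the offset absorbs it).
"""

from __future__ import annotations

import numpy as np

from .constants import KB
from .fes import Axis, FESGrid
from .metad import BiasState, _gaussian_sum
from .trace import CVTrace

__all__ = ["CVTrace", "compute_weights", "reweighted_fes"]


def _axes(grid_spec):
    return [ax if isinstance(ax, Axis) else Axis(*ax) for ax in grid_spec]


def _offset(v_grid, beta, gamma):
    a = beta * gamma / (gamma - 1.0) * v_grid
    b = beta / (gamma - 1.0) * v_grid
    return (_lse(a) - _lse(b)) / beta


def _lse(x):
    m = x.max()
    return m + np.log(np.exp(x - m).sum())


def compute_weights(trace: CVTrace, bias: BiasState, grid_spec) -> CVTrace:
    """Fill per-record unbiasing weights from the evolving bias.

    ``grid_spec`` defines the grid over the *biased* CV(s) used to evaluate
    the offset c(t); it should cover the sampled range.  Records earlier
    than the first hill get V = 0 and c = 0.  Returns a new trace with
    weights normalized to mean 1.
    """
    axes = _axes(grid_spec)
    mesh = np.meshgrid(*[ax.centers() for ax in axes], indexing="ij")
    points = np.stack([m.reshape(-1) for m in mesh], axis=1)
    centers, sigmas, heights, times = bias.hill_arrays()
    beta = 1.0 / (KB * bias.T)
    gamma = bias.gamma

    v_grid = np.zeros(len(points))
    c_now = 0.0
    ptr = 0
    log_w = np.empty(len(trace))
    for i, t in enumerate(trace.times):
        advanced = False
        while ptr < len(times) and times[ptr] <= t:
            v_grid += _gaussian_sum(points, centers[ptr:ptr + 1],
                                    sigmas[ptr:ptr + 1], heights[ptr:ptr + 1])
            ptr += 1
            advanced = True
        if advanced:
            c_now = _offset(v_grid, beta, gamma)
        elif ptr == 0:
            c_now = 0.0
        log_w[i] = beta * (trace.bias_energy[i] - c_now)
    log_w -= log_w.max()
    w = np.exp(log_w)
    w *= len(w) / w.sum()
    return CVTrace(times=trace.times.copy(), names=list(trace.names),
                   values=trace.values.copy(),
                   bias_energy=trace.bias_energy.copy(), weights=w)


def reweighted_fes(trace: CVTrace, target_cv_columns, grid_spec,
                   temperature: float) -> FESGrid:
    """Weighted-histogram free-energy surface on chosen CV columns.

    F = -kB T ln(weighted histogram), shifted to min 0; empty bins are
    marked unvisited (NaN), not zero.  Bins are half-open [lo, hi) with
    values at bin centers.
    """
    if trace.weights is None:
        raise ValueError("trace has no weights; run compute_weights first")
    axes = _axes(grid_spec)
    data = np.stack([trace.column(c) if isinstance(c, str)
                     else trace.values[:, c] for c in target_cv_columns], axis=1)
    edges = [np.linspace(ax.lo, ax.hi, ax.n + 1) for ax in axes]
    hist, _ = np.histogramdd(data, bins=edges, weights=trace.weights)
    if not (hist > 0).any():
        raise ValueError("no samples fall inside the requested grid")
    kt = KB * temperature
    with np.errstate(divide="ignore"):
        f = np.where(hist > 0, -kt * np.log(np.where(hist > 0, hist, 1.0)), np.nan)
    f -= np.nanmin(f)
    return FESGrid(axes, f)
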
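"""Time series of collective-variable values (the COLVAR record stream)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CVTrace"]


@dataclass
class CVTrace:
    """CV values and instantaneous bias energy recorded along a trajectory.

    ``values`` has one column per CV named in ``names``; ``bias_energy`` is
    the history-dependent bias (kJ/mol, walls excluded) acting at each record.
    ``weights`` (dimensionless, mean 1) are filled by reweighting.
    """

    times: np.ndarray
    names: list[str]
    values: np.ndarray
    bias_energy: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.times.shape[0]:
            self.values = self.values.T
        self.bias_energy = np.asarray(self.bias_energy, dtype=float)
        n = len(self.times)
        if self.values.shape[0] != n or self.bias_energy.shape[0] != n:
            raise ValueError("times, values and bias_energy lengths differ")
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names must match the number of CV columns")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape[0] != n:
                raise ValueError("weights length mismatch")
            if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
                raise ValueError("weights must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no CV column named {name!r}") from None
        return self.values[:, j]
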
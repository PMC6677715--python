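"""Parameter containers for the Notch-Delta-Reporter pathway."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PathwayParams"]


@dataclass(frozen=True)
class PathwayParams:
    """Rate constants, Hill coefficients, system volume and signal weights
    of the Notch-Delta-Reporter lateral-inhibition pathway.

    Defaults are the non-dimensional parameter set of the protrusion
    model of Hadjivasiliou et al. (2016): production strengths
    ``[beta_n, beta_d, beta_r] = [100, 500, 3e5]``, half-saturation
    constants ``[k_t, k_c, k_rs] = [2, 0.5, 1e7]``, Hill coefficients
    ``m = s = 2``, system volume ``omega = 400`` molecules per unit
    concentration, and uniform signal weights.

    ``chunk_safety`` is the fraction of norm-wise state change permitted
    per frozen-signal time chunk (5% by default); ``dtau_min``/``dtau_max``
    bound the chunk at degenerate states (exact equilibrium would
    otherwise give an unbounded chunk).
    """

    beta_n: float = 100.0
    beta_d: float = 500.0
    beta_r: float = 3.0e5
    k_t: float = 2.0
    k_c: float = 0.5
    k_rs: float = 1.0e7
    m: int = 2
    s: int = 2
    omega: float = 400.0
    w_a: float = 1.0
    w_b: float = 1.0
    q_a: float = 1.0
    q_b: float = 1.0
    chunk_safety: float = 0.05
    dtau_min: float = 1.0e-6
    dtau_max: float = 0.5
    collier_const: float = 1.0

    def __post_init__(self) -> None:
        positive = {
            "beta_n": self.beta_n, "beta_d": self.beta_d, "beta_r": self.beta_r,
        }
        for name, v in positive.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        strictly = {
            "k_t": self.k_t, "k_c": self.k_c, "k_rs": self.k_rs,
            "omega": self.omega, "chunk_safety": self.chunk_safety,
            "dtau_min": self.dtau_min, "dtau_max": self.dtau_max,
        }
        for name, v in strictly.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.m < 1 or self.s < 1:
            raise ValueError("Hill coefficients m, s must be >= 1")
        for name in ("w_a", "w_b", "q_a", "q_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"signal weight {name} must be non-negative")
        if self.dtau_min > self.dtau_max:
            raise ValueError("dtau_min must not exceed dtau_max")

    @property
    def weights(self) -> tuple[float, float, float, float]:
        """Signal weights as ``(w_a, q_a, w_b, q_b)``."""
        return (self.w_a, self.q_a, self.w_b, self.q_b)

    def with_(self, **kwargs) -> "PathwayParams":
        """Copy with fields replaced."""
        return replace(self, **kwargs)
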
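"""Tunable parameters of the segmentation model.

All scalars that control the force blend, the level-set evolution and the
stopping rule live in :class:`SegmentationParams`.  Defaults follow the
global settings used throughout the method's evaluation: rho=1, eps=1.5,
sigma_reg=1, sigma1=1, sigma2=2, dt=1; alpha is image-dependent and
defaults to 20.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class SegmentationParams:
    """All tunable scalars of the segmentation pipeline.

    Parameters
    ----------
    s : float in [0, 1]
        Trade-off between the intensity-driven group (DoG edge + SPF
        region) and the saliency force.  Large ``s`` makes intensity the
        leading force; small ``s`` favours saliency.
    w : float in [0, 1]
        Within the intensity group, the weight of the DoG edge force
        versus the SPF region force.
    sigma1, sigma2 : float
        Standard deviations of the two Gaussians of the DoG edge
        detector; ``sigma1 < sigma2`` is required.  A large gap suits
        noisy images, a small gap preserves fine detail.
    sigma_reg : float
        Standard deviation of the Gaussian used to regularize the level
        set after each step (replaces curvature penalty and
        re-initialization).
    sigma_sal : float
        Standard deviation of the blur inside the saliency map.
    rho : float
        Magnitude of the binary-constant level-set initialization.
    eps : float
        Width of the regularized (arctan) Heaviside.
    alpha : float
        Force gain in the evolution equation dphi/dt = alpha * F * |grad phi|.
    dt : float
        Explicit Euler time step.
    max_iterations : int
        Hard cap on the number of evolution steps.
    tol, patience : float, int
        Stop when the fraction of mask pixels changed per iteration stays
        below ``tol`` for ``patience`` consecutive iterations.
    literal_eq2 : bool
        Use the un-grouped force blend ``s*w*DoG + (1-w)*SPF + (1-s)*SAL``
        instead of the default grouped form
        ``s*(w*DoG + (1-w)*SPF) + (1-s)*SAL``.
    """

    s: float = 0.9
    w: float = 0.5
    sigma1: float = 1.0
    sigma2: float = 2.0
    sigma_reg: float = 1.0
    sigma_sal: float = 2.0
    rho: float = 1.0
    eps: float = 1.5
    alpha: float = 20.0
    dt: float = 1.0
    max_iterations: int = 300
    tol: float = 1e-4
    patience: int = 5
    literal_eq2: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.s <= 1.0:
            raise ValueError(f"s must lie in [0, 1], got {self.s}")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w must lie in [0, 1], got {self.w}")
        for name in ("sigma1", "sigma2", "sigma_reg", "sigma_sal", "rho",
                     "eps", "dt"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not self.sigma1 < self.sigma2:
            raise ValueError(
                f"sigma1 must be strictly smaller than sigma2 "
                f"(got sigma1={self.sigma1}, sigma2={self.sigma2})")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be at least 1")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")

    def replace(self, **updates) -> "SegmentationParams":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **updates)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in dataclasses.fields(cls))

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SegmentationParams":
        """Build params from a dict, rejecting unknown keys by name."""
        valid = set(cls.field_names())
        unknown = sorted(set(mapping) - valid)
        if unknown:
            raise ValueError(
                f"unknown parameter key(s) {unknown}; "
                f"valid keys are {sorted(valid)}")
        return cls(**mapping)
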
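"""Multiplicative (speckle) noise simulation.

The degradation model is f = g·η with η i.i.d., E[η] = 1.  Two noise
families are provided:

* uniform speckle — η ~ Uniform[1 − √(3σ²), 1 + √(3σ²)], the unique uniform
  law with mean 1 and variance σ²; requires σ² < 1/3 so the support stays
  positive;
* gamma (L-look intensity speckle) — η ~ Gamma(shape L, scale 1/L), mean 1,
  variance 1/L, the standard fully-developed-speckle model of coherent
  imaging (SAR, ultrasound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image import ImageField

__all__ = ["NoiseSpec", "speckle_uniform", "speckle_gamma", "apply_noise"]


@dataclass(frozen=True)
class NoiseSpec:
    """Description of a multiplicative noise process.

    family: "uniform_speckle" (parameter sigma2) or "gamma" (parameter looks).
    """

    family: str = "uniform_speckle"
    sigma2: float = 0.1
    looks: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("uniform_speckle", "gamma"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "uniform_speckle" and not 0 <= self.sigma2 < 1.0 / 3.0:
            raise ValueError("uniform speckle requires 0 <= sigma2 < 1/3")
        if self.family == "gamma" and self.looks < 1:
            raise ValueError("gamma speckle requires looks L >= 1")


def speckle_uniform(g: ImageField, sigma2: float, seed: int = 0) -> ImageField:
    """Corrupt ``g`` with mean-1 uniform speckle of variance ``sigma2``."""
    if not 0 <= sigma2 < 1.0 / 3.0:
        raise ValueError("sigma2 must lie in [0, 1/3) so the support stays positive")
    g.require_positive("clean image")
    half = np.sqrt(3.0 * sigma2)
    rng = np.random.default_rng(seed)
    eta = rng.uniform(1.0 - half, 1.0 + half, size=g.shape)
    return g.with_values(g.values * eta)


def speckle_gamma(g: ImageField, looks: float, seed: int = 0) -> ImageField:
    """Corrupt ``g`` with L-look gamma speckle (mean 1, variance 1/L)."""
    if looks < 1:
        raise ValueError("looks L must be >= 1")
    g.require_positive("clean image")
    rng = np.random.default_rng(seed)
    eta = rng.gamma(shape=looks, scale=1.0 / looks, size=g.shape)
    return g.with_values(g.values * eta)


def apply_noise(g: ImageField, spec: NoiseSpec, seed: int | None = None) -> ImageField:
    """Apply a :class:`NoiseSpec`; ``seed`` overrides the spec's seed."""
    s = spec.seed if seed is None else seed
    if spec.family == "uniform_speckle":
        return speckle_uniform(g, spec.sigma2, seed=s)
    return speckle_gamma(g, spec.looks, seed=s)
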
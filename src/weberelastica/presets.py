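"""Named parameter presets for the elastica + Weber-TV solver.

The per-image quadruples (β₁, β₂, α₁, α₂) are the tuned experimental values
for the classic test images at σ² = 0.1 speckle; ``generic`` is the
midpoint of the admissible tuning ranges β₁ ∈ [0.0025, 0.0097],
β₂ ∈ [0.0082, 0.074], α₁ ∈ [0.29, 0.50], α₂ ∈ [1.22, 1.61]; ``shapes128``
was tuned the same way on this package's 128² shapes phantom benchmark.
"""

from __future__ import annotations

from .elastica import ElasticaParams

__all__ = ["PRESETS", "elastica_preset", "preset_names"]

PRESETS: dict[str, tuple[float, float, float, float]] = {
    "generic": (0.0061, 0.0411, 0.395, 1.415),
    "shapes128": (0.01525, 0.10275, 0.9875, 3.5375),
    "moon": (0.003, 0.05, 0.40, 1.38),
    "rose": (0.007, 0.01, 0.37, 1.41),
    "synthetic1": (0.001, 0.06, 0.34, 1.56),
    "synthetic2": (0.004, 0.03, 0.36, 1.53),
    "synthetic3": (0.002, 0.05, 0.33, 1.54),
    "synthetic4": (0.004, 0.04, 0.38, 1.30),
    "boat": (0.01, 0.008, 0.23, 1.05),
    "house": (0.01, 0.0062, 0.17, 1.04),
    "peppers": (0.01, 0.0085, 0.24, 1.05),
    "lena": (0.02, 0.005, 0.20, 1.02),
    "baboon": (0.007, 0.093, 0.23, 1.29),
}


def preset_names() -> list[str]:
    return sorted(PRESETS)


# Solver settings bundled with a preset (the classic-image quadruples were
# tuned at Δx = Δy = 10 with dt = 2e-4; the phantom benchmark runs in pixel
# units at the convergence-optimal explicit step).
PRESET_SOLVER: dict[str, dict] = {
    "shapes128": {"dt": 0.02, "spacing": 1.0, "max_iter": 3000},
}


def elastica_preset(name: str, **overrides) -> ElasticaParams:
    """Build :class:`ElasticaParams` from a named quadruple.

    Presets may bundle solver settings (dt, spacing, iteration budget);
    keyword overrides win over both.
    """
    try:
        b1, b2, a1, a2 = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}") from None
    kwargs = dict(PRESET_SOLVER.get(name, {}))
    kwargs.update(overrides)
    return ElasticaParams(beta1=b1, beta2=b2, alpha1=a1, alpha2=a2, **kwargs)
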
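"""Restoration-quality metrics: PSNR and line profiles."""

from __future__ import annotations

import numpy as np

from .image import ImageField

__all__ = ["psnr", "line_profile", "plot_line_profiles"]


def psnr(g_hat: ImageField, g: ImageField) -> float:
    """Peak signal-to-noise ratio in dB.

    PSNR = 10·log₁₀( M·N·max(ĝ)² / Σ(ĝ − g)² ), with ĝ the reference image
    (its peak sets the signal level) and g the restored image.  Identical
    images return +inf.
    """
    if g_hat.shape != g.shape:
        raise ValueError(f"shape mismatch: {g_hat.shape} vs {g.shape}")
    diff = g_hat.values - g.values
    ssd = float(np.sum(diff * diff))
    if ssd == 0.0:
        return float("inf")
    M, N = g_hat.shape
    peak = float(np.max(g_hat.values))
    return float(10.0 * np.log10(M * N * peak * peak / ssd))


def line_profile(field: ImageField, row_index: int) -> np.ndarray:
    """Return one row of the image as a 1-D intensity sequence."""
    if not 0 <= row_index < field.n_rows:
        raise IndexError(
            f"row {row_index} out of range for field with {field.n_rows} rows"
        )
    return field.values[row_index].copy()


def plot_line_profiles(
    row_index: int,
    reference: ImageField,
    others: dict[str, ImageField],
    out_path=None,
):
    """Overlay the reference row profile with restored/noisy profiles.

    Returns the matplotlib figure; saves to ``out_path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.plot(line_profile(reference, row_index), "b-", label="reference")
    for name, field in others.items():
        ax.plot(line_profile(field, row_index), label=name)
    ax.set_xlabel("column")
    ax.set_ylabel("intensity")
    ax.set_title(f"row {row_index} profile")
    ax.legend()
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
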
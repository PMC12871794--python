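"""Optional plotting helpers (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

from .interaction import LambdaProfile

__all__ = ["plot_lambda_profile"]


def plot_lambda_profile(profile: LambdaProfile, ax=None, label=None):
    """The p-versus-λ profile on a -log10 axis with the significance cutoff.

    λ=1 (no transformation) and λ=0 (log) are the reference scales a reader
    will look for first; the dashed line marks the Bonferroni threshold.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(profile.lambdas, -np.log10(profile.p_values), marker="o", ms=3, label=label)
    if profile.rint_p is not None:
        ax.scatter([profile.lambdas[-1] + 0.25], [-np.log10(profile.rint_p)],
                   marker="s", color="gray", label="RINT")
    ax.axhline(-np.log10(profile.threshold), ls="--", color="black", lw=1)
    ax.axvline(1.0, ls=":", color="gray", lw=1)
    ax.set_xlabel("Box-Cox $\\lambda$")
    ax.set_ylabel("$-\\log_{10} p$ (PGS×E interaction)")
    if label:
        ax.legend()
    return ax
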
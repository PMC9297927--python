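"""Basic plots of simulation summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402

from .pedigree import SimulationSummary  # noqa: E402

__all__ = ["plot_simulation_bands"]


def plot_simulation_bands(sim: SimulationSummary, which: str = "osr", ax=None):
    """Mean simulated sex ratio with the 95% replicate band per generation.

    ``which`` is ``"osr"`` (operational sex ratio) or ``"diploid_sr"``.
    """
    if which not in ("osr", "diploid_sr"):
        raise ValueError("which must be 'osr' or 'diploid_sr'")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    s = sim.summary
    x = range(len(s))
    mean_col = "mean_osr" if which == "osr" else "mean_diploid_sr"
    lo_col = "osr_lo" if which == "osr" else "diploid_sr_lo"
    hi_col = "osr_hi" if which == "osr" else "diploid_sr_hi"
    ax.fill_between(x, s[lo_col], s[hi_col], alpha=0.3, label="95% band")
    ax.plot(x, s[mean_col], marker="o", label="mean")
    ax.set_xticks(list(x))
    ax.set_xticklabels(s["generation"], rotation=45, ha="right")
    ax.set_ylim(-0.02, 1.02)
    ax.set_ylabel(
        "operational sex ratio" if which == "osr" else "diploid sex ratio"
    )
    ax.set_title(sim.scheme_label)
    ax.legend()
    return ax
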
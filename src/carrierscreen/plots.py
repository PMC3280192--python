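"""Diagnostic plots (matplotlib, non-interactive backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402

from .pool import DEFAULT_BAND_AFU  # noqa: E402


def pool_scatter(
    profiles: pd.DataFrame,
    path: str | Path,
    band_halfwidth: float = DEFAULT_BAND_AFU,
    ratios: tuple[float, float] = (2.0, 3.0),
    title: str = "Pool competition",
) -> Path:
    """Treated-vs-untreated AFU scatter with parity, noise-band and ratio lines.

    Transporter deletants are starred; the band lines are the parity line
    translated by +/- the noise half-width, and the ratio lines mark
    treated/untreated ratios of 2 and 3.
    """
    path = Path(path)
    fig, ax = plt.subplots(figsize=(6, 6))
    if "is_transporter" in profiles.columns:
        is_transp = profiles["is_transporter"].astype(bool)
    else:
        is_transp = pd.Series(False, index=profiles.index)
    other = profiles[~is_transp]
    transp = profiles[is_transp]
    ax.plot(other["afu_untreated"], other["afu_treated"], "d", ms=4, color="tab:blue",
            label="deletants")
    if len(transp):
        ax.plot(transp["afu_untreated"], transp["afu_treated"], "*", ms=8, color="black",
                label="transporter deletants")
    lim = max(float(profiles["afu_untreated"].max()), float(profiles["afu_treated"].max())) * 1.05
    xs = [0, lim]
    ax.plot(xs, xs, "-", color="grey", lw=1, label="parity")
    ax.plot(xs, [x + band_halfwidth for x in xs], "-", color="tab:pink", lw=1,
            label=f"parity ± {band_halfwidth:g} AFU")
    ax.plot(xs, [x - band_halfwidth for x in xs], "-", color="tab:green", lw=1)
    for ratio, color in zip(ratios, ("indigo", "tab:cyan")):
        ax.plot(xs, [ratio * x for x in xs], "--", color=color, lw=1, label=f"ratio {ratio:g}")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("AFU, untreated pool")
    ax.set_ylabel("AFU, treated pool")
    ax.set_title(title)
    ax.legend(fontsize=8, loc="upper left")
    fig.tight_layout()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
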
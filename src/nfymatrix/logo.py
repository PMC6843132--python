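"""Minimal matplotlib sequence-logo renderer.

Draws stacked per-base letters whose heights are probability times column
information content (bits), the standard information-content logo.
"""

from __future__ import annotations

from .matrix import PWM, pwm_to_logo

_COLORS = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}


def plot_logo(pwm: PWM, ax=None, title: str | None = None):
    """Render ``pwm`` as an information-content sequence logo.

    Returns the matplotlib Axes.  Letters are drawn with TextPath glyphs
    scaled to their bit heights; columns are labeled with positions
    relative to the CCAAT pentamer.
    """
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    if ax is None:
        _fig, ax = plt.subplots(figsize=(0.6 * pwm.width + 1, 2.4))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for i, column in enumerate(pwm_to_logo(pwm)):
        y = 0.0
        for base, height in sorted(column.letter_heights.items(), key=lambda kv: kv[1]):
            if height <= 0:
                continue
            path = TextPath((0, 0), base, size=1, prop=font)
            bbox = path.get_extents()
            sx = 0.9 / bbox.width
            sy = height / bbox.height
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(sx, sy)
                .translate(i + 0.05, y)
            )
            ax.add_patch(PathPatch(transform.transform_path(path),
                                   facecolor=_COLORS[base], edgecolor="none"))
            y += height
    ax.set_xlim(0, pwm.width)
    ax.set_ylim(0, 2)
    ax.set_xticks([i + 0.5 for i in range(pwm.width)])
    ax.set_xticklabels(pwm.relative_labels)
    ax.set_ylabel("bits")
    if title:
        ax.set_title(title)
    return ax


def save_logo(pwm: PWM, path, title: str | None = None) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ax = plot_logo(pwm, title=title)
    ax.figure.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(ax.figure)
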
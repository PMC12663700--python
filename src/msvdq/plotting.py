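"""Optional rendering of MSV plots and biplots (requires matplotlib)."""

from __future__ import annotations

from .msv import MSVResult


def plot_msv(result: MSVResult, ax=None, scale: float = 0.05):
    """MSV plot: one circle per source at its embedding position, radius
    proportional to case count, distance between circles ~ √JSD."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sources = result.distances.sources if result.distances else list(result.spo)
    for label, (x, y) in zip(sources, result.plot_coords[:, :2]):
        ax.add_patch(
            __import__("matplotlib.patches", fromlist=["Circle"]).Circle(
                (x, y), radius=scale * result.radii[label], alpha=0.5
            )
        )
        ax.annotate(label, (x, y), ha="center", va="center")
    ax.set_title(f"MSV plot (GPD = {result.gpd:.3f})")
    ax.set_aspect("equal")
    ax.autoscale_view()
    ax.relim()
    return ax


def plot_biplot(biplot: dict, ax=None, arrow_scale: float = 3.0):
    """Scatter of the first two reduced axes by site, with loading arrows
    for the top-contributing variables."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    scores, site = biplot["scores"], biplot["site"]
    for label in dict.fromkeys(site):
        sel = site == label
        ax.scatter(scores[sel, 0], scores[sel, 1], s=8, alpha=0.6, label=str(label))
    arrows = biplot["arrows"]
    if arrows.shape[1] >= 2:
        for name, row in arrows.iterrows():
            ax.annotate(
                str(name),
                xy=(arrow_scale * row.iloc[0], arrow_scale * row.iloc[1]),
                xytext=(0, 0),
                arrowprops={"arrowstyle": "<-", "color": "gray", "lw": 0.8},
                fontsize=7,
            )
    ax.legend(fontsize=8)
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    return ax
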
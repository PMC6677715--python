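"""Best-effort rendering of lattice states (requires matplotlib).

Draws each cell as a filled hexagon colored by a per-cell value
(typically the Delta count on a log scale), mimicking the standard way
lateral-inhibition patterns are displayed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["render_lattice"]


def render_lattice(path, positions, values, log: bool = True,
                   cmap: str = "Oranges", title: str | None = None):
    """Save a hexagon-tile rendering of per-cell ``values`` at the given
    cell ``positions`` (units of cell radius, spacing 2)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import RegularPolygon

    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    shade = np.log10(np.maximum(values, 0.5)) if log else values
    patches = [RegularPolygon((x, y), numVertices=6, radius=2 / np.sqrt(3.0))
               for x, y in positions]
    fig, ax = plt.subplots(figsize=(6, 6))
    coll = PatchCollection(patches, cmap=cmap, edgecolor="0.6",
                           linewidth=0.3)
    coll.set_array(shade)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.colorbar(coll, ax=ax, shrink=0.75,
                 label="log10 Delta" if log else "value")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path
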
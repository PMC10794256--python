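"""Simple plots: composition bars and cluster alignment tiles."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd


def plot_composition(table: pd.DataFrame, ax=None):
    """Horizontal bar chart of domain frequencies, one bar group per
    (class, role)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(table) + 1))
    labels = [
        f"{r.bgc_class}/{r.role}: {r.domain}" for r in table.itertuples(index=False)
    ]
    ax.barh(labels, table["frequency"], color="#4878a8")
    ax.set_xlabel("domain frequency (mean count per BGC)")
    ax.invert_yaxis()
    return ax


def plot_cluster_alignment(msa: Mapping[str, Sequence[str]], ax=None):
    """Tile plot of a cluster BDA alignment: rows are BGCs, columns are
    alignment positions, colors encode domain labels."""
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.5 * len(msa) + 1))
    ids = list(msa)
    tokens = sorted({t for row in msa.values() for t in row if t != "-"})
    cmap = colormaps["tab20"]
    color = {t: cmap(i % 20) for i, t in enumerate(tokens)}
    for y, bgc_id in enumerate(ids):
        for x, tok in enumerate(msa[bgc_id]):
            if tok == "-":
                continue
            ax.add_patch(
                plt.Rectangle((x, y - 0.4), 0.9, 0.8, color=color[tok], lw=0)
            )
            ax.text(x + 0.45, y, tok, ha="center", va="center", fontsize=6)
    ax.set_xlim(-0.5, max(len(r) for r in msa.values()) + 0.5)
    ax.set_ylim(-0.8, len(ids) - 0.2)
    ax.set_yticks(range(len(ids)), ids)
    ax.invert_yaxis()
    ax.set_xlabel("alignment position")
    return ax
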
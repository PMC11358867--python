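"""PMI-triangle, exit-vector and network plots.

All functions take tidy descriptor DataFrames (see :mod:`bvstereo.descriptors`
and :mod:`bvstereo.ensembles`) and write vector graphics; population-weighted
variants scale marker areas by the Boltzmann weight.
"""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd

from .ensembles import mirror_layout

__all__ = ["plot_pmi_triangle", "plot_ev_scatter", "plot_phi", "plot_network"]


def _marker_sizes(frame: pd.DataFrame, scale: float = 200.0):
    if "weight" in frame.columns:
        return np.maximum(scale * frame["weight"].to_numpy(), 2.0)
    return np.full(len(frame), 30.0)


def plot_pmi_triangle(frame: pd.DataFrame, path, title: Optional[str] = None,
                      overlay: Optional[pd.DataFrame] = None) -> None:
    """NPR1 vs NPR2 triangle with rod/disc/sphere vertices and sum-NPR isolines.

    Isolines of NPR1 + NPR2 are drawn at 0.1 increments between 1.0 and 2.0.
    ``overlay`` (columns NPR1, NPR2) draws user-supplied reference points in
    grey, e.g. a comparison ring-system library.
    """
    fig, ax = plt.subplots(figsize=(5, 4.5))
    ax.plot([0, 0.5, 1, 0], [1, 0.5, 1, 1], color="black", lw=1)
    for s in np.arange(1.0, 2.01, 0.1):
        x = np.linspace(max(0.0, s - 1.0), min(s / 2, 1.0), 2)
        ax.plot(x, s - x, color="lightgrey", lw=0.5, zorder=0)
    if overlay is not None:
        ax.scatter(overlay["NPR1"], overlay["NPR2"], s=15, color="grey",
                   alpha=0.6, label="reference")
    ax.scatter(frame["NPR1"], frame["NPR2"], s=_marker_sizes(frame),
               alpha=0.75, edgecolor="none")
    ax.annotate("rod", (0, 1)); ax.annotate("disc", (0.5, 0.5))
    ax.annotate("sphere", (1, 1))
    ax.set_xlabel("NPR1 = $I_1/I_3$"); ax.set_ylabel("NPR2 = $I_2/I_3$")
    ax.set_xlim(-0.05, 1.05); ax.set_ylim(0.45, 1.05)
    if title:
        ax.set_title(title)
    fig.tight_layout(); fig.savefig(path); plt.close(fig)


def plot_ev_scatter(frame: pd.DataFrame, path, title: Optional[str] = None,
                    theta_range: tuple = (-90.0, 90.0)) -> None:
    """Distance vs signed dihedral exit-vector plot.

    The default x-range -90..+90 deg suits the bullvalene cage, which keeps
    all pair dihedrals within +/-60 deg; pass (0, 180) for the classical
    unsigned layout.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    theta = frame["theta"]
    if theta_range[0] >= 0.0:
        theta = theta.abs()
    ax.scatter(theta, frame["r"], s=_marker_sizes(frame), alpha=0.75,
               edgecolor="none")
    ax.set_xlim(*theta_range)
    ax.set_xlabel(r"$\theta$ / deg"); ax.set_ylabel(r"$r$ / $\mathrm{\AA}$")
    if title:
        ax.set_title(title)
    fig.tight_layout(); fig.savefig(path); plt.close(fig)


def plot_phi(frame: pd.DataFrame, path, title: Optional[str] = None) -> None:
    """Plane-angle plot: phi1 vs phi2 for every substituent pair."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(frame["phi1"], frame["phi2"], s=_marker_sizes(frame),
               alpha=0.75, edgecolor="none")
    lim = (0, max(90.0, frame[["phi1", "phi2"]].to_numpy().max() + 5))
    ax.set_xlim(*lim); ax.set_ylim(*lim)
    ax.set_xlabel(r"$\varphi_1$ / deg"); ax.set_ylabel(r"$\varphi_2$ / deg")
    if title:
        ax.set_title(title)
    fig.tight_layout(); fig.savefig(path); plt.close(fig)


def plot_network(net: nx.Graph, path, title: Optional[str] = None,
                 show_self_loops: bool = False) -> None:
    """Interconversion network diagram, mirror-symmetric when populations allow.

    Achiral isomers sit on the central axis with enantiomeric pairs mirrored
    either side; node areas scale with population when annotated.
    """
    if all("layout_x" in d for _, d in net.nodes(data=True)):
        pos = {n: (d["layout_x"], d["layout_y"]) for n, d in net.nodes(data=True)}
    elif any("chirality" in d for _, d in net.nodes(data=True)):
        pos = mirror_layout(net)
    else:
        pos = nx.spring_layout(net, seed=0)
    draw = net if show_self_loops else nx.restricted_view(
        net, [], [(u, v) for u, v in net.edges if u == v]
    )
    sizes = [
        max(2000.0 * net.nodes[n].get("population", 0.05), 20.0) for n in net.nodes
    ]
    fig, ax = plt.subplots(figsize=(6, 6))
    nx.draw_networkx(draw, pos=pos, ax=ax, node_size=sizes, font_size=5,
                     width=0.5, node_color="#7fa8d9")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.tight_layout(); fig.savefig(path); plt.close(fig)
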
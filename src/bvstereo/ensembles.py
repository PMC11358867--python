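"""Boltzmann population weighting of isomer ensembles.

At equilibrium the nondegenerate isomers of a substituted bullvalene are
present in proportions set by their relative energies: each canonical
isomer (enantiomers are separate members) carries the weight

    p_i = exp(-dE_i / RT) / sum_j exp(-dE_j / RT)

with R = 8.314462618 J/(mol K), energies in kJ/mol relative to the most
stable isomer, and T in kelvin (default 298 K).  No statistical factors for
degenerate rearrangements are folded in: weights are over distinct
canonical isomers only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .barcodes import (
    barcode_string,
    canonical_form,
    classify_chirality,
    parse_barcode,
)
from .structures import StructureError

__all__ = [
    "GAS_CONSTANT_KJ",
    "PopulationTable",
    "boltzmann_weights",
    "weighted_descriptor_table",
    "weighted_network",
    "mirror_layout",
]

#: Gas constant in kJ/(mol K).
GAS_CONSTANT_KJ = 8.314462618e-3


@dataclass
class PopulationTable:
    """Per-isomer relative energies (kJ/mol), weights and chirality classes."""

    frame: pd.DataFrame  # columns: barcode, delta_e, weight, chirality
    temperature: float
    energy_kind: str = "unspecified"

    def weight(self, barcode) -> float:
        b = barcode_string(parse_barcode(barcode))
        row = self.frame.loc[self.frame["barcode"] == b, "weight"]
        if row.empty:
            raise StructureError(f"barcode {b} not in population table")
        return float(row.iloc[0])

    @property
    def weights(self) -> dict:
        return dict(zip(self.frame["barcode"], self.frame["weight"]))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def boltzmann_weights(energies: dict, temperature: float = 298.0,
                      energy_kind: str = "unspecified") -> PopulationTable:
    """Population table from relative energies (kJ/mol, min shifted to 0).

    Energies may carry an arbitrary common offset; weights are invariant
    under adding a constant.
    """
    if not energies:
        raise StructureError("empty energy map")
    if temperature <= 0:
        raise StructureError(f"temperature must be positive, got {temperature}")
    barcodes = [barcode_string(canonical_form(b)) for b in energies]
    de = np.array([float(e) for e in energies.values()])
    if not np.all(np.isfinite(de)):
        raise StructureError("non-finite energy in map")
    de = de - de.min()
    w = np.exp(-de / (GAS_CONSTANT_KJ * temperature))
    w /= w.sum()
    frame = pd.DataFrame(
        {
            "barcode": barcodes,
            "delta_e": de,
            "weight": w,
            "chirality": [classify_chirality(b).kind for b in barcodes],
        }
    ).sort_values("delta_e", kind="stable", ignore_index=True)
    return PopulationTable(frame, temperature, energy_kind)


def weighted_descriptor_table(pop: PopulationTable, descriptors: pd.DataFrame,
                              minority_threshold: float = 1e-3,
                              marker_scale: float = 200.0) -> pd.DataFrame:
    """Join Boltzmann weights onto a PMI or exit-vector descriptor table.

    Adds ``weight`` (population), ``marker_size`` (proportional to the
    population) and ``minority`` (True below the threshold, default 0.1%).
    Every populated isomer must have descriptor rows and vice versa.
    """
    desc_barcodes = set(descriptors["barcode"])
    pop_barcodes = set(pop.frame["barcode"])
    missing_desc = sorted(pop_barcodes - desc_barcodes)
    if missing_desc:
        raise StructureError(
            f"populated isomers without descriptors: {missing_desc}"
        )
    missing_pop = sorted(desc_barcodes - pop_barcodes)
    if missing_pop:
        raise StructureError(
            f"descriptor rows without populations: {missing_pop}"
        )
    out = descriptors.merge(
        pop.frame[["barcode", "delta_e", "weight", "chirality"]], on="barcode"
    )
    out["marker_size"] = marker_scale * out["weight"]
    out["minority"] = out["weight"] < minority_threshold
    return out


def weighted_network(net: nx.Graph, pop: PopulationTable) -> nx.Graph:
    """Copy of an interconversion network with node ``population`` attributes.

    Also attaches a mirror-symmetric layout hint: achiral isomers on the
    central axis, enantiomer pairs mirrored left/right.
    """
    nodes = set(net.nodes)
    pops = pop.weights
    if nodes != set(pops):
        raise StructureError(
            f"network/population node mismatch: only in network "
            f"{sorted(nodes - set(pops))[:5]}, only in populations "
            f"{sorted(set(pops) - nodes)[:5]}"
        )
    g = net.copy()
    for n in g.nodes:
        g.nodes[n]["population"] = float(pops[n])
    for n, (x, y) in mirror_layout(g).items():
        g.nodes[n]["layout_x"] = x
        g.nodes[n]["layout_y"] = y
    return g


def mirror_layout(net: nx.Graph) -> dict:
    """Layout hint grouping achiral nodes at x=0 with enantiomer pairs at +/-x.

    y orders nodes by descending population (if annotated) then barcode.
    """
    def sort_key(n):
        return (-net.nodes[n].get("population", 0.0), n)

    achiral = sorted((n for n, d in net.nodes(data=True)
                      if d.get("chirality", "achiral") == "achiral"), key=sort_key)
    pos = {}
    for i, n in enumerate(achiral):
        pos[n] = (0.0, -float(i))
    seen = set()
    row = 0
    for n in sorted(net.nodes, key=sort_key):
        d = net.nodes[n]
        if d.get("chirality") != "chiral" or n in seen:
            continue
        partner = d.get("enantiomer", "")
        pos[n] = (-1.0, -float(row))
        seen.add(n)
        if partner in net.nodes:
            pos[partner] = (1.0, -float(row))
            seen.add(partner)
        row += 1
    return pos
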
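"""Principal-moment-of-inertia and exit-vector shape descriptors.

PMI: the three principal moments I1 <= I2 <= I3 of the all-atom,
standard-atomic-mass inertia tensor about the center of mass, and the
normalized ratios NPR1 = I1/I3 and NPR2 = I2/I3.  On the (NPR1, NPR2)
triangle the vertices are rod (0, 1), disc (0.5, 0.5) and sphere (1, 1);
the sum NPR1 + NPR2 measures distance from the rod-disc axis (sphericity).

Exit vectors: for a pair of substituted scaffold carbons C1, C2 bearing
substituent attachment atoms X1, X2, the descriptors are the carbon-carbon
distance r = |C1C2|, the signed dihedral theta = X1-C1-C2-X2 (right-handed
convention, -180..180 deg; mirror images negate it), and the plane angles
phi_i between each exit vector v_i = Ci -> Xi and the internuclear axis
directed away from the partner carbon (Cj -> Ci), in 0..180 deg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .structures import Structure3D, StructureError

__all__ = [
    "PMIRecord",
    "ExitVectorRecord",
    "pmi",
    "exit_vectors",
    "all_pairs_ev",
    "pmi_table",
    "ev_table",
]


@dataclass(frozen=True)
class PMIRecord:
    """Principal moments (amu A^2, ascending) and normalized ratios."""

    I1: float
    I2: float
    I3: float
    npr1: float
    npr2: float
    collinear: bool = False

    @property
    def sum_npr(self) -> float:
        return self.npr1 + self.npr2


@dataclass(frozen=True)
class ExitVectorRecord:
    """Exit-vector geometry for one ordered pair of substituted positions."""

    barcode: str
    position_1: int
    position_2: int
    r: float          # A
    theta: float      # deg, signed, -180..180
    phi1: float       # deg, 0..180
    phi2: float       # deg, 0..180


def inertia_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Center-of-mass inertia tensor (amu A^2)."""
    com = np.average(coords, axis=0, weights=masses)
    r = coords - com
    r2 = np.sum(r * r, axis=1)
    return np.diag(np.sum(masses * r2) * np.ones(3)) - np.einsum(
        "i,ij,ik->jk", masses, r, r
    )


def pmi(st) -> PMIRecord:
    """PMI record of a structure (or of raw (coords, masses)).

    Collinear inputs have I1 = 0 and two equal nonzero moments; they are
    returned as the rod vertex (NPR1 = 0, NPR2 = 1) and flagged.
    """
    if isinstance(st, Structure3D):
        coords, masses = st.coords, st.masses
    else:
        coords, masses = (np.asarray(a, dtype=float) for a in st)
    if len(coords) < 2:
        raise StructureError("PMI needs at least two atoms")
    moments = np.linalg.eigvalsh(inertia_tensor(coords, masses))
    i1, i2, i3 = (max(float(m), 0.0) for m in moments)
    if i3 <= 0.0:
        raise StructureError("PMI undefined: all mass at a single point")
    collinear = i1 / i3 < 1e-12
    return PMIRecord(i1, i2, i3, npr1=i1 / i3, npr2=i2 / i3, collinear=collinear)


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral p0-p1-p2-p3 in degrees, right-handed convention."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))


def _angle(u, v) -> float:
    cosang = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


#: Plane-angle convention: "away" measures phi_i against the internuclear
#: axis directed away from the partner carbon (Cj -> Ci); "toward" is the
#: supplement.  One switch so the alternative convention is a config change.
PHI_CONVENTION = "away"


def exit_vectors(st: Structure3D, p: int, q: int,
                 phi_convention: Optional[str] = None) -> ExitVectorRecord:
    """Exit-vector descriptors for substituted positions p and q.

    The dihedral sign follows the lower-index -> higher-index position
    ordering; the record is symmetric under swapping p and q.
    """
    convention = phi_convention or PHI_CONVENTION
    p, q = sorted((p, q))
    for pos in (p, q):
        if pos not in st.attachment_map:
            raise StructureError(
                f"position {pos} carries no substituent in barcode {st.barcode}"
            )
    c1 = st.coords[st.position_map[p]]
    c2 = st.coords[st.position_map[q]]
    x1 = st.coords[st.attachment_map[p]]
    x2 = st.coords[st.attachment_map[q]]
    v1, v2 = x1 - c1, x2 - c2
    r = float(np.linalg.norm(c2 - c1))
    theta = _dihedral(x1, c1, c2, x2)
    phi1 = _angle(v1, c1 - c2)
    phi2 = _angle(v2, c2 - c1)
    if convention == "toward":
        phi1, phi2 = 180.0 - phi1, 180.0 - phi2
    elif convention != "away":
        raise StructureError(f"unknown phi convention {convention!r}")
    return ExitVectorRecord(st.barcode, p, q, r, theta, phi1, phi2)


def all_pairs_ev(st: Structure3D, phi_convention: Optional[str] = None) -> list:
    """One record per unordered pair of substituted positions (k choose 2)."""
    positions = sorted(st.attachment_map)
    if len(positions) < 2:
        raise StructureError(
            f"exit-vector analysis needs >= 2 substituents, barcode {st.barcode} "
            f"has {len(positions)}"
        )
    return [
        exit_vectors(st, p, q, phi_convention=phi_convention)
        for p, q in combinations(positions, 2)
    ]


# ---------------------------------------------------------------------------
# Tabulation


def pmi_table(structures: Iterable) -> pd.DataFrame:
    """One row per structure: I1..I3, NPR1, NPR2, sum."""
    rows = []
    for st in structures:
        rec = pmi(st)
        rows.append(
            {"barcode": st.barcode, "I1": rec.I1, "I2": rec.I2, "I3": rec.I3,
             "NPR1": rec.npr1, "NPR2": rec.npr2, "sum_NPR": rec.sum_npr}
        )
    return pd.DataFrame(rows)


def ev_table(structures: Iterable, phi_convention: Optional[str] = None) -> pd.DataFrame:
    """One row per (structure, substituent pair)."""
    rows = []
    for st in structures:
        for rec in all_pairs_ev(st, phi_convention=phi_convention):
            rows.append(
                {"barcode": rec.barcode, "position_1": rec.position_1,
                 "position_2": rec.position_2, "r": rec.r, "theta": rec.theta,
                 "phi1": rec.phi1, "phi2": rec.phi2}
            )
    return pd.DataFrame(rows)
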
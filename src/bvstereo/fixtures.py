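"""Synthetic test inputs: random barcodes, analytic mass distributions,
mirrored coordinate pairs, and reference energy tables.

These generators back both the test suite and the ``bvstereo fixtures``
subcommand; everything is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .barcodes import N_POSITIONS
from .ensembles import GAS_CONSTANT_KJ

__all__ = ["fixture_generator", "FIXTURE_KINDS"]


def _random_barcodes(rng: np.random.Generator, n: int = 20, k_types: int = 3):
    """Random digit tuples (not necessarily canonical) over 0..k_types."""
    return [
        tuple(int(d) for d in rng.integers(0, k_types + 1, size=N_POSITIONS))
        for _ in range(n)
    ]


def _pmi_vertices():
    """Point sets with known NPR coordinates.

    rod: two equal masses -> (0, 1); disc: regular hexagon -> (0.5, 0.5)
    (perpendicular-axis theorem); sphere: regular tetrahedron -> (1, 1).
    """
    rod = (np.array([[0.0, 0.0, -1.0], [0.0, 0.0, 1.0]]), np.ones(2))
    angles = np.arange(6) * np.pi / 3
    hexagon = (
        np.stack([np.cos(angles), np.sin(angles), np.zeros(6)], axis=1),
        np.ones(6),
    )
    tetra = (
        np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float),
        np.ones(4),
    )
    return {"rod": rod, "disc": hexagon, "sphere": tetra}


def _mirrored_pair(rng: np.random.Generator, n_atoms: int = 8):
    """A random coordinate set and its reflection through the yz plane."""
    coords = rng.normal(size=(n_atoms, 3))
    mirror = coords * np.array([-1.0, 1.0, 1.0])
    return coords, mirror


def _two_level_energies(temperature: float = 298.0):
    """Two isomers split by RT ln 2 -> populations 2/3 and 1/3."""
    rt = GAS_CONSTANT_KJ * temperature
    return {"0" * N_POSITIONS: 0.0,
            "0" * (N_POSITIONS - 1) + "1": rt * np.log(2.0)}


FIXTURE_KINDS = (
    "barcodes", "pmi-vertices", "mirrored-pair",
    "uniform-energies", "two-level-energies", "random-energies",
)


def fixture_generator(kind: str, seed: int = 0, **kw):
    """Dispatch on fixture kind; raises ValueError for unknown kinds."""
    rng = np.random.default_rng(seed)
    if kind == "barcodes":
        return _random_barcodes(rng, **kw)
    if kind == "pmi-vertices":
        return _pmi_vertices()
    if kind == "mirrored-pair":
        return _mirrored_pair(rng, **kw)
    if kind == "uniform-energies":
        n = kw.get("n", 5)
        return {f"{i:0{N_POSITIONS}d}": 0.0 for i in range(n)}
    if kind == "two-level-energies":
        return _two_level_energies(**kw)
    if kind == "random-energies":
        n = kw.get("n", 10)
        spread = kw.get("spread", 20.0)  # kJ/mol
        vals = np.sort(rng.uniform(0.0, spread, size=n))
        vals -= vals[0]
        return {f"{i:0{N_POSITIONS}d}": float(v) for i, v in enumerate(vals)}
    raise ValueError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")
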
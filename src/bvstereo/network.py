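"""Cope rearrangement steps and isomer interconversion networks.

Each Cope rearrangement takes place on one of bullvalene's three
1,5-hexadiene "faces".  A face involves two *participating* arms i and j
(its hexadiene is beta_i=gamma_i - delta_i - delta_j - gamma_j = beta_i) and
one spectator arm k.  Breaking the delta_i-delta_j sigma bond while forming
beta_i-beta_j realizes exactly four elementary positional exchanges:

    alpha(NP) <-> delta(NP)     beta(NP) <-> gamma(NP)
    beta(P)   <-> delta(P)      gamma(P) <-> gamma(P)   (degenerate)

Applying the three face permutations to every canonical barcode of a
substituent set yields the isomer interconversion network: an undirected
graph whose nodes are canonical barcodes and whose edges carry the number
of faces producing each transition.  Degenerate steps are recorded as
self-loops, so every node has exactly three outgoing faces.  Because nodes
are rotation-orbit representatives, face counts are directional in general
(count(u->v) * |orbit(u)| == count(v->u) * |orbit(v)|); edges store both
directions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

from .barcodes import (
    ARMS,
    BarcodeError,
    SubstituentSet,
    barcode_string,
    canonical_form,
    classify_chirality,
    count_isomers,
    enumerate_isomers,
    parse_barcode,
)

__all__ = [
    "CopeFace",
    "FACES",
    "face_permutation",
    "cope_step",
    "neighbors",
    "build_network",
    "build_network_bfs",
    "outgoing_multiplicities",
    "write_graphml",
    "read_graphml",
    "write_edgelist",
    "write_dot",
]

#: Default node cap for network construction; the parent cage's 1 209 600
#: degenerate isomers fit, anything larger is refused explicitly.
DEFAULT_NODE_CAP = 2_000_000


@dataclass(frozen=True)
class CopeFace:
    """One 1,5-hexadiene face: participating arms {i, j}, spectator arm k."""

    i: int
    j: int

    def __post_init__(self):
        if not (1 <= self.i < self.j <= 3):
            raise BarcodeError(f"face arms must satisfy 1 <= i < j <= 3, got {self!r}")

    @property
    def spectator(self) -> int:
        return 6 - self.i - self.j


FACES = (CopeFace(1, 2), CopeFace(1, 3), CopeFace(2, 3))


def face_permutation(face: CopeFace) -> tuple:
    """Source-index table of the position permutation for one Cope step.

    With ``src = face_permutation(f)`` the rearranged barcode is
    ``tuple(b[src[t]] for t in range(10))``.  The table is built so that the
    same face applied twice is the identity on all ten positions (the
    rearrangement is its own reverse across the newly formed delta-delta
    bond, which again spans arms {i, j}).
    """
    i, j, k = face.i, face.j, face.spectator
    bi, gi, di = ARMS[i - 1]
    bj, gj, dj = ARMS[j - 1]
    bk, gk, dk = ARMS[k - 1]
    src = [0] * 10
    src[0] = dk                    # delta(NP) -> alpha
    src[bi], src[gi], src[di] = di, gi, bi   # P arm i: beta<->delta, gamma fixed
    src[bj], src[gj], src[dj] = dj, gj, bj   # P arm j
    src[bk], src[gk], src[dk] = gk, bk, 0    # NP arm: beta<->gamma, alpha -> delta
    return tuple(src)


_FACE_PERMS = {f: face_permutation(f) for f in FACES}


def cope_step(b, face: CopeFace):
    """Canonical barcode after one Cope rearrangement on the given face."""
    d = parse_barcode(b)
    src = _FACE_PERMS.get(face)
    if src is None:
        src = face_permutation(face)
    return canonical_form(tuple(d[s] for s in src))


def neighbors(b) -> list:
    """The three single-step products (with multiplicity) of a canonical barcode."""
    return [cope_step(b, f) for f in FACES]


def _add_face_edges(g: nx.Graph, node) -> None:
    # After quotienting by the C3 rotation, face counts are directional:
    # u may reach v through more faces than v reaches u whenever their
    # rotation-orbit sizes differ (count(u->v) * |orbit(u)| ==
    # count(v->u) * |orbit(v)|).  Edges therefore carry two counts:
    # ``multiplicity`` for min(u,v) -> max(u,v) (and for self-loops) and
    # ``multiplicity_rev`` for the reverse direction.
    for product in neighbors(node):
        p = barcode_string(parse_barcode(product))
        if not g.has_edge(node, p):
            g.add_edge(node, p, multiplicity=0, multiplicity_rev=0)
        if node <= p:
            g[node][p]["multiplicity"] += 1
        else:
            g[node][p]["multiplicity_rev"] += 1


def outgoing_multiplicities(g: nx.Graph, node) -> dict:
    """Faces leaving ``node``, per product barcode; values sum to 3."""
    out = {}
    for _, v, d in g.edges(node, data=True):
        if node <= v:
            m = d["multiplicity"]
        else:
            m = d["multiplicity_rev"]
        if m:
            out[v] = m
    return out


def build_network(s: SubstituentSet, node_cap: int = DEFAULT_NODE_CAP) -> nx.Graph:
    """Interconversion network over all canonical isomers of a substituent set.

    Nodes are barcode strings; edges carry integer face counts per
    direction (``multiplicity`` for min->max and self-loops,
    ``multiplicity_rev`` for max->min; see :func:`outgoing_multiplicities`),
    with self-loops for degenerate rearrangements.  Every node is annotated with its chirality
    class.  Raises if the isomer count exceeds ``node_cap``.
    """
    n = count_isomers(s)
    if n > node_cap:
        raise BarcodeError(
            f"isomer count {n} exceeds the network node cap {node_cap}"
        )
    g = nx.Graph()
    for d in enumerate_isomers(s):
        node = barcode_string(d)
        cls = classify_chirality(d)
        g.add_node(
            node,
            chirality=cls.kind,
            enantiomer="" if cls.partner is None else barcode_string(cls.partner),
        )
    for node in list(g.nodes):
        _add_face_edges(g, node)
    return g


def build_network_bfs(start_barcode, node_cap: int = DEFAULT_NODE_CAP) -> nx.Graph:
    """Alternative constructor: breadth-first traversal from one barcode.

    Agrees with :func:`build_network` whenever the network is connected;
    used as a cross-check of enumeration against reachability.
    """
    start = barcode_string(canonical_form(start_barcode))
    g = nx.Graph()
    frontier = [start]
    g.add_node(start)
    while frontier:
        nxt = []
        for node in frontier:
            for product in neighbors(node):
                p = barcode_string(parse_barcode(product))
                if p not in g:
                    if g.number_of_nodes() >= node_cap:
                        raise BarcodeError(f"BFS network exceeded node cap {node_cap}")
                    g.add_node(p)
                    nxt.append(p)
        frontier = nxt
    for node in list(g.nodes):
        cls = classify_chirality(node)
        g.nodes[node]["chirality"] = cls.kind
        g.nodes[node]["enantiomer"] = (
            "" if cls.partner is None else barcode_string(cls.partner)
        )
        _add_face_edges(g, node)
    return g


# ---------------------------------------------------------------------------
# Export / import


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, data in g.nodes(data=True):
        out.add_node(str(n), **data)
    for u, v, data in g.edges(data=True):
        out.add_edge(str(u), str(v),
                     multiplicity=int(data.get("multiplicity", 1)),
                     multiplicity_rev=int(data.get("multiplicity_rev", 0)))
    return out


def write_edgelist(g: nx.Graph, path) -> None:
    """Plain TSV edge list: source, target, per-direction face counts."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tmultiplicity\tmultiplicity_rev\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('multiplicity', 1)}"
                     f"\t{data.get('multiplicity_rev', 0)}\n")


def write_dot(g: nx.Graph, path, show_self_loops: bool = True,
              max_nodes: int = 100) -> None:
    """DOT export for rendering small network diagrams."""
    if g.number_of_nodes() > max_nodes:
        raise BarcodeError(
            f"DOT export limited to {max_nodes} nodes, network has "
            f"{g.number_of_nodes()}"
        )
    lines = ["graph isomers {"]
    for n, data in sorted(g.nodes(data=True)):
        shape = "box" if data.get("chirality") == "achiral" else "ellipse"
        weight = data.get("population")
        label = n if weight is None else f"{n}\\np={weight:.3f}"
        lines.append(f'  "{n}" [shape={shape}, label="{label}"];')
    for u, v, data in sorted(g.edges(data=True)):
        if u == v and not show_self_loops:
            continue
        m = data.get("multiplicity", 1)
        rev = data.get("multiplicity_rev", 0)
        label = str(m) if rev in (0, m) else f"{m}/{rev}"
        attr = f' [label="{label}"]' if (m > 1 or rev > 1) else ""
        lines.append(f'  "{u}" -- "{v}"{attr};')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
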
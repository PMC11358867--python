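"""Isomer barcodes, C3 symmetry, counting and enumeration for substituted bullvalenes.

Bullvalene's ten carbons are labelled with Greek locants: the apical sp3
carbon (alpha), and three equivalent "arms" each carrying an olefinic pair
(beta, adjacent to alpha, double-bonded to gamma) and a cyclopropane carbon
(delta).  A substitution state is encoded as a ten-digit *barcode*: one
type code per scaffold position, in the fixed position order

    [alpha, beta1, gamma1, delta1, beta2, gamma2, delta2, beta3, gamma3, delta3]

with 0 = hydrogen and non-hydrogen substituent types numbered 1..k in input
order.  Because the parent cage has threefold rotational symmetry, barcodes
related by a cyclic relabelling of the three arms describe the same isomer;
the canonical representative is the lexicographic minimum over the three arm
rotations.  Reflection (swapping two arms) maps a barcode onto its
enantiomer, which is counted as a *distinct* isomer throughout.

The number of unique nondegenerate isomers for a substituent multiset with
per-type counts ``N_t`` (hydrogen included) is

    N_iso = (10! / prod_t N_t!  +  2 S) / 3

where ``S`` is the number of C3-symmetric arrangements (all three arms
identically substituted); S is always one of {0, 1, 3, 6}.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from sympy.utilities.iterables import multiset_permutations, partitions

__all__ = [
    "N_POSITIONS",
    "POSITION_LABELS",
    "RHO_SRC",
    "SIGMA_SRC",
    "Substituent",
    "SubstituentSet",
    "BarcodeError",
    "parse_barcode",
    "barcode_string",
    "rotate",
    "reflect",
    "canonical_form",
    "is_canonical",
    "compute_S",
    "count_isomers",
    "enumerate_isomers",
    "classify_chirality",
    "chirality_split",
    "Variation",
    "enumerate_substitution_variations",
    "write_variation_table",
    "reorder_barcode",
]

N_POSITIONS = 10

#: Human-readable locant for each barcode position, in barcode order.
POSITION_LABELS = (
    "alpha",
    "beta1", "gamma1", "delta1",
    "beta2", "gamma2", "delta2",
    "beta3", "gamma3", "delta3",
)

#: Arm a (1-based) occupies barcode indices ARMS[a-1] as (beta, gamma, delta).
ARMS = ((1, 2, 3), (4, 5, 6), (7, 8, 9))

# rho cycles the arms 1 -> 2 -> 3 sitewise and fixes alpha; sigma fixes
# alpha and arm 1 and swaps arms 2 <-> 3 sitewise.  Both are stored as
# source-index tables: rotate(b)[i] == b[RHO_SRC[i]].
RHO_SRC = (0, 7, 8, 9, 1, 2, 3, 4, 5, 6)
SIGMA_SRC = (0, 1, 2, 3, 7, 8, 9, 4, 5, 6)

# Digit alphabet for string barcodes; supports up to ten non-H types
# (codes 1..10 -> '1'..'9', 'A').
_ALPHABET = "0123456789A"


class BarcodeError(ValueError):
    """Raised for malformed barcodes or inconsistent substituent sets."""


Digits = tuple  # ten-tuple of small ints


def parse_barcode(b) -> Digits:
    """Coerce a barcode (string, or iterable of ints) to a validated digit tuple."""
    if isinstance(b, str):
        try:
            digits = tuple(_ALPHABET.index(c) for c in b)
        except ValueError:
            raise BarcodeError(f"barcode {b!r} contains characters outside {_ALPHABET!r}")
    else:
        digits = tuple(int(d) for d in b)
        if any(d < 0 or d > 10 for d in digits):
            raise BarcodeError(f"barcode digits out of range 0..10: {digits}")
    if len(digits) != N_POSITIONS:
        raise BarcodeError(f"barcode must have {N_POSITIONS} digits, got {len(digits)}")
    return digits


def barcode_string(digits: Digits) -> str:
    """Serialize a digit tuple as a ten-character string."""
    return "".join(_ALPHABET[d] for d in digits)


def rotate(b) -> Digits:
    """Apply the C3 rotation rho (arms 1->2->3, alpha fixed)."""
    d = parse_barcode(b)
    return tuple(d[i] for i in RHO_SRC)


def reflect(b) -> Digits:
    """Apply the mirror sigma (swap arms 2<->3 sitewise, alpha and arm 1 fixed)."""
    d = parse_barcode(b)
    return tuple(d[i] for i in SIGMA_SRC)


def canonical_form(b) -> Digits:
    """Canonical representative: lexicographic minimum over the three arm rotations.

    Only rotations are quotiented out, so enantiomeric barcodes stay distinct.
    Idempotent; constant on rho-orbits.
    """
    d = parse_barcode(b)
    r1 = tuple(d[i] for i in RHO_SRC)
    r2 = tuple(r1[i] for i in RHO_SRC)
    return min(d, r1, r2)


def is_canonical(b) -> bool:
    d = parse_barcode(b)
    return d == canonical_form(d)


def reorder_barcode(b, order: Sequence[int]) -> Digits:
    """Re-express a barcode in a user-supplied position order.

    ``order[i]`` gives the index (in this package's fixed order) of the
    position that should appear at slot ``i`` of the output.  This is the
    hook for emitting strings compatible with other digit-order conventions.
    """
    d = parse_barcode(b)
    if sorted(order) != list(range(N_POSITIONS)):
        raise BarcodeError("order must be a permutation of 0..9")
    return tuple(d[i] for i in order)


# ---------------------------------------------------------------------------
# Substituent sets


@dataclass(frozen=True)
class Substituent:
    """One substituent type: numeric code, optional SMILES, multiplicity."""

    code: int
    count: int
    smiles: Optional[str] = None


@dataclass(frozen=True)
class SubstituentSet:
    """A multiset of non-hydrogen substituent types on the bullvalene core.

    Hydrogen is implicit: it is type code 0 with count ``10 - sum(N_a)``.
    Two entries never share a structure; SMILES given in the input spec are
    canonicalized (RDKit) and identical structures merged with summed counts.
    """

    entries: tuple = field(default_factory=tuple)

    def __post_init__(self):
        total = sum(e.count for e in self.entries)
        if total > N_POSITIONS:
            raise BarcodeError(
                f"substituent counts sum to {total} > {N_POSITIONS} positions"
            )
        if any(e.count < 1 for e in self.entries):
            raise BarcodeError("substituent counts must be >= 1")
        codes = [e.code for e in self.entries]
        if codes != list(range(1, len(codes) + 1)):
            raise BarcodeError(f"type codes must be consecutive 1..k, got {codes}")
        smis = [e.smiles for e in self.entries if e.smiles is not None]
        if len(smis) != len(set(smis)):
            raise BarcodeError("two substituent entries share a structure")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_counts(cls, counts: Iterable[int]) -> "SubstituentSet":
        """Build from non-hydrogen counts only (no structures attached)."""
        entries = tuple(
            Substituent(code=i + 1, count=int(c)) for i, c in enumerate(counts)
        )
        return cls(entries)

    @classmethod
    def from_spec(cls, spec: Iterable[str]) -> "SubstituentSet":
        """Build from ``SMILES:count`` strings, canonicalizing and merging structures.

        >>> SubstituentSet.from_spec(["C:2"]).hydrogen_count
        8
        """
        from rdkit import Chem

        merged: dict[str, int] = {}
        order: list[str] = []
        for item in spec:
            smiles, sep, count_s = item.rpartition(":")
            if not sep or not smiles:
                raise BarcodeError(f"bad substituent spec {item!r}; expected SMILES:count")
            try:
                count = int(count_s)
            except ValueError:
                raise BarcodeError(f"bad count in substituent spec {item!r}")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise BarcodeError(f"unparseable substituent SMILES {smiles!r}")
            canon = Chem.MolToSmiles(mol)
            if canon not in merged:
                merged[canon] = 0
                order.append(canon)
            merged[canon] += count
        entries = tuple(
            Substituent(code=i + 1, count=merged[s], smiles=s)
            for i, s in enumerate(order)
        )
        return cls(entries)

    # -- derived quantities -------------------------------------------------

    @property
    def hydrogen_count(self) -> int:
        return N_POSITIONS - sum(e.count for e in self.entries)

    @property
    def counts(self) -> tuple:
        """Per-type counts indexed by code, hydrogen (code 0) first."""
        return (self.hydrogen_count,) + tuple(e.count for e in self.entries)

    @property
    def digit_multiset(self) -> tuple:
        """The sorted ten-digit multiset a barcode of this set must realize."""
        out = []
        for code, count in enumerate(self.counts):
            out.extend([code] * count)
        return tuple(out)

    def smiles_for(self, code: int) -> Optional[str]:
        if code == 0:
            return None
        return self.entries[code - 1].smiles

    def validate_barcode(self, b) -> Digits:
        d = parse_barcode(b)
        if tuple(sorted(d)) != self.digit_multiset:
            raise BarcodeError(
                f"barcode {barcode_string(d)} does not realize counts {self.counts}"
            )
        return d


# ---------------------------------------------------------------------------
# Counting (closed form) and enumeration (oracle)


def compute_S(s: SubstituentSet) -> int:
    """Number of C3-symmetric substituent arrangements.

    A barcode is fixed by the arm rotation iff the three arms carry identical
    (beta, gamma, delta) triples; the alpha occupant is free.  For each type x
    that can sit at alpha, the remaining counts must all be divisible by 3,
    and the per-arm triple (one third of the remainder) can be ordered over
    (beta, gamma, delta) in ``3!/prod(m_t!)`` ways.  The result is always
    0, 1, 3, or 6.
    """
    counts = s.counts
    total = 0
    for x, nx in enumerate(counts):
        if nx == 0:
            continue
        rem = list(counts)
        rem[x] -= 1
        if any(c % 3 for c in rem):
            continue
        arm = [c // 3 for c in rem]  # per-arm multiset over 3 sites
        ways = math.factorial(3)
        for m in arm:
            ways //= math.factorial(m)
        total += ways
    return total


def count_isomers(s: SubstituentSet) -> int:
    """Closed-form count of unique nondegenerate isomers (enantiomers distinct).

    N_iso = (10!/prod_t N_t! + 2 S)/3 with the product over all types
    including hydrogen.
    """
    denom = 1
    for c in s.counts:
        denom *= math.factorial(c)
    raw = math.factorial(N_POSITIONS) // denom
    numer = raw + 2 * compute_S(s)
    if numer % 3:
        raise RuntimeError(
            f"isomer count not divisible by 3 (raw={raw}, S={compute_S(s)}): "
            "internal inconsistency in the symmetry correction"
        )
    return numer // 3


def enumerate_isomers(s: SubstituentSet) -> list:
    """All canonical barcodes for a substituent set, sorted, each exactly once.

    Exhaustive oracle for :func:`count_isomers`: iterates the distinct
    multiset permutations of the ten digits and keeps the rotation-canonical
    representatives.
    """
    return sorted(iter_isomers(s))


def iter_isomers(s: SubstituentSet) -> Iterator[Digits]:
    """Unsorted generator behind :func:`enumerate_isomers`."""
    digits = list(s.digit_multiset)
    rho = RHO_SRC
    for p in multiset_permutations(digits):
        t = tuple(p)
        r1 = tuple(t[i] for i in rho)
        if t <= r1:
            r2 = tuple(r1[i] for i in rho)
            if t <= r2:
                yield t


@dataclass(frozen=True)
class Chirality:
    """Chirality class of a canonical barcode under the full C3v barcode group."""

    kind: str  # "achiral" | "chiral"
    partner: Optional[Digits]  # canonical enantiomer barcode, if chiral


def classify_chirality(b) -> Chirality:
    """Achiral iff the mirrored barcode canonicalizes back onto itself.

    For chiral barcodes the returned partner is the canonical form of the
    reflection; partnering is a fixed-point-free involution on the chiral set.
    """
    d = canonical_form(b)
    mirror = canonical_form(reflect(d))
    if mirror == d:
        return Chirality("achiral", None)
    return Chirality("chiral", mirror)


def chirality_split(isomers: Iterable) -> tuple:
    """(achiral barcodes, enantiomer pairs) partition of a canonical isomer list."""
    achiral = []
    pairs = []
    seen = set()
    for b in isomers:
        d = parse_barcode(b)
        cls = classify_chirality(d)
        if cls.kind == "achiral":
            achiral.append(d)
        elif d not in seen:
            pairs.append((d, cls.partner))
            seen.add(d)
            seen.add(cls.partner)
    return achiral, pairs


# ---------------------------------------------------------------------------
# The 42 substitution variations


@dataclass(frozen=True)
class Variation:
    """One substitution pattern: a partition of the ten positions into type counts."""

    partition: tuple  # counts, descending, hydrogen included as a type
    S: int
    n_iso: int
    n_achiral: Optional[int] = None
    n_chiral: Optional[int] = None

    @property
    def substituent_set(self) -> SubstituentSet:
        # Largest part plays the hydrogen role; the counts multiset is all
        # that N_iso and S depend on.
        return SubstituentSet.from_counts(self.partition[1:])


def enumerate_substitution_variations(with_chirality: bool = False) -> list:
    """All distinct substitution variations of the bullvalene core.

    A variation is a multiset of per-type counts over the ten positions with
    hydrogen included as a type, i.e. an integer partition of 10; there are
    42.  Each is reported with its S factor and isomer count; with
    ``with_chirality=True`` the achiral/chiral split is computed by
    exhaustive enumeration (slower: the fully heterosubstituted row has
    1 209 600 isomers).
    """
    out = []
    for part in partitions(N_POSITIONS):
        counts = tuple(sorted((k for k, v in part.items() for _ in range(v)), reverse=True))
        s = SubstituentSet.from_counts(counts[1:])
        S = compute_S(s)
        n = count_isomers(s)
        if with_chirality:
            achiral, pairs = chirality_split(iter_isomers(s))
            out.append(Variation(counts, S, n, len(achiral), 2 * len(pairs)))
        else:
            out.append(Variation(counts, S, n))
    out.sort(key=lambda v: (len(v.partition), v.partition))
    return out


def write_variation_table(path, with_chirality: bool = False) -> None:
    """CSV reference table over all 42 variations."""
    rows = enumerate_substitution_variations(with_chirality=with_chirality)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["partition", "S", "N_iso", "N_achiral", "N_chiral"])
        for v in rows:
            w.writerow(
                ["+".join(map(str, v.partition)), v.S, v.n_iso,
                 "" if v.n_achiral is None else v.n_achiral,
                 "" if v.n_chiral is None else v.n_chiral]
            )
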
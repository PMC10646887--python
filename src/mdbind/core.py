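"""Core data model: frames, topologies, trajectories, group selections.

A :class:`Frame` holds coordinates (Å) and an optional orthorhombic box;
a :class:`Topology` holds per-atom chemistry (mass, charge, LJ parameters,
donor/acceptor flags), the bond list and named atom groups; a
:class:`Trajectory` is an ordered list of frames sharing one topology.

Distances are always computed under the minimum-image convention when a
box is present.  Atom indices are 0-based everywhere in memory; file
formats keep their native 1-based serials at I/O only.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Frame",
    "Topology",
    "Trajectory",
    "SelectionError",
    "select_group",
    "center_of_mass",
    "minimum_image",
    "pair_distance",
    "counterions_needed",
    "STANDARD_MASSES",
]

#: atomic masses (amu) for the elements the toy systems use
STANDARD_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "TI": 47.867, "CL": 35.45, "NA": 22.990, "AR": 39.948,
    "X": 1.0,
}


class SelectionError(ValueError):
    """Raised when a selection expression cannot be resolved."""


@dataclass
class Frame:
    """One snapshot: per-atom positions (Å), optional box, timestamp (ps)."""

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise ValueError("box lengths must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Topology:
    """Per-atom chemistry plus bonds and named groups.

    ``epsilon`` is the LJ well depth (kcal mol⁻¹) and ``rmin_half`` the
    CHARMM-style Rmin/2 radius (Å); pair parameters follow Lorentz–Berthelot
    combination (geometric ε, additive radii).  ``donor``/``acceptor`` flags
    come from the input table; :meth:`guess_donors_acceptors` marks O/N with
    an attached hydrogen as donors and all O/N as acceptors when flags are
    absent.
    """

    elements: Sequence[str]
    masses: np.ndarray | None = None
    charges: np.ndarray | None = None
    epsilon: np.ndarray | None = None
    rmin_half: np.ndarray | None = None
    bonds: Sequence[tuple[int, int]] = field(default_factory=list)
    donor: np.ndarray | None = None
    acceptor: np.ndarray | None = None
    groups: dict[str, frozenset[int]] = field(default_factory=dict)
    resids: np.ndarray | None = None
    resnames: Sequence[str] | None = None

    def __post_init__(self) -> None:
        n = len(self.elements)
        self.elements = [str(e) for e in self.elements]
        if self.masses is None:
            self.masses = np.array(
                [STANDARD_MASSES.get(e.upper(), 1.0) for e in self.elements]
            )
        self.masses = np.asarray(self.masses, dtype=float)
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.epsilon is not None:
            self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.rmin_half is not None:
            self.rmin_half = np.asarray(self.rmin_half, dtype=float)
        if self.donor is not None:
            self.donor = np.asarray(self.donor, dtype=bool)
        if self.acceptor is not None:
            self.acceptor = np.asarray(self.acceptor, dtype=bool)
        for arr, name in ((self.masses, "masses"), (self.charges, "charges")):
            if len(arr) != n:
                raise ValueError(f"{name} length does not match atom count")
        self.bonds = [(int(i), int(j)) for i, j in self.bonds]
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) out of range for {n} atoms")
        self.groups = {
            str(k): frozenset(int(i) for i in v) for k, v in self.groups.items()
        }
        for label, idx in self.groups.items():
            if idx and (min(idx) < 0 or max(idx) >= n):
                raise ValueError(f"group {label!r} contains out-of-range indices")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def bonded(self, index: int) -> list[int]:
        """Indices covalently bonded to ``index``."""
        out = []
        for i, j in self.bonds:
            if i == index:
                out.append(j)
            elif j == index:
                out.append(i)
        return out

    def donor_hydrogens(self, donor: int) -> list[int]:
        """Hydrogens covalently bonded to a donor heavy atom."""
        return [k for k in self.bonded(donor) if self.elements[k].upper() == "H"]

    def guess_donors_acceptors(self) -> None:
        """Fill missing donor/acceptor flags from O/N chemistry."""
        heavy = np.array([e.upper() in ("O", "N") for e in self.elements])
        if self.acceptor is None:
            self.acceptor = heavy.copy()
        if self.donor is None:
            self.donor = np.array(
                [heavy[i] and bool(self.donor_hydrogens(i)) for i in range(self.n_atoms)]
            )

    def total_charge(self, group: Iterable[int] | None = None) -> float:
        idx = np.fromiter(group, dtype=int) if group is not None else slice(None)
        return float(np.sum(self.charges[idx]))


@dataclass
class Trajectory:
    """Ordered frames sharing one topology; times must strictly increase."""

    frames: list[Frame]
    topology: Topology
    dt: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {f.n_atoms} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# geometry helpers


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def pair_distance(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> float:
    d = minimum_image(np.asarray(b, float) - np.asarray(a, float), box)
    return float(np.linalg.norm(d))


def center_of_mass(
    frame: Frame, group: Iterable[int], topology: Topology
) -> np.ndarray:
    """Mass-weighted mean position of a group (Å).

    Invariant under atom reordering; raises on an empty group or
    non-positive masses.
    """
    idx = np.fromiter(group, dtype=int)
    if idx.size == 0:
        raise ValueError("center of mass of an empty group is undefined")
    m = topology.masses[idx]
    if np.any(m <= 0):
        raise ValueError("masses must be strictly positive")
    return (m[:, None] * frame.coordinates[idx]).sum(axis=0) / m.sum()


def counterions_needed(net_charge: float, ion_charge: int = -1) -> int:
    """Number of monovalent (or given-valence) counterions neutralizing a net charge.

    A receptor of net charge +3 complexed with a −1 ligand has net +2 and
    needs 2 monovalent anions.  The ion charge must oppose the net charge.
    """
    if ion_charge == 0:
        raise ValueError("ion charge must be nonzero")
    if net_charge == 0:
        return 0
    if net_charge * ion_charge > 0:
        raise ValueError("counterion charge must oppose the net charge")
    count = -net_charge / ion_charge
    if abs(count - round(count)) > 1e-9:
        warnings.warn("net charge is not an integer multiple of the ion charge")
    return int(math.ceil(count - 1e-9))


# ---------------------------------------------------------------------------
# selection language
#
# Grammar (lowest to highest precedence):
#   expr   := orterm
#   orterm := andterm ('or' andterm)*
#   andterm:= unary ('and' unary)*
#   unary  := 'not' unary | atom
#   atom   := 'group:L' | 'element:E' | 'resname:R' | 'resid:N' | 'all'
#           | '(' expr ')'

_TOKEN = re.compile(r"\(|\)|[A-Za-z_][\w:+\-*']*|\S")


def _tokenize(expression: str) -> list[str]:
    return _TOKEN.findall(expression)


class _Parser:
    def __init__(self, tokens: list[str], topology: Topology):
        self.tokens = tokens
        self.pos = 0
        self.top = topology
        self.universe = frozenset(range(topology.n_atoms))

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> frozenset[int]:
        out = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return out

    def expr(self) -> frozenset[int]:
        left = self.andterm()
        while self.peek() == "or":
            self.next()
            left = left | self.andterm()
        return left

    def andterm(self) -> frozenset[int]:
        left = self.unary()
        while self.peek() == "and":
            self.next()
            left = left & self.unary()
        return left

    def unary(self) -> frozenset[int]:
        if self.peek() == "not":
            self.next()
            return self.universe - self.unary()
        return self.atom()

    def atom(self) -> frozenset[int]:
        tok = self.next()
        if tok == "(":
            inner = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return inner
        if tok == "all":
            return self.universe
        if ":" not in tok:
            # a bare known group label reads as group:LABEL
            if tok in self.top.groups:
                return self.top.groups[tok]
            known = ", ".join(sorted(self.top.groups)) or "(none)"
            raise SelectionError(
                f"unknown selection term {tok!r}; expected key:value, 'all', "
                f"'not', 'and', 'or', or a group label ({known})"
            )
        key, _, value = tok.partition(":")
        key = key.lower()
        if key == "group":
            if value not in self.top.groups:
                known = ", ".join(sorted(self.top.groups)) or "(none)"
                raise SelectionError(
                    f"unknown group {value!r}; known groups: {known}"
                )
            return self.top.groups[value]
        if key == "element":
            return frozenset(
                i for i, e in enumerate(self.top.elements)
                if e.upper() == value.upper()
            )
        if key == "resname":
            if self.top.resnames is None:
                raise SelectionError("topology carries no residue names")
            return frozenset(
                i for i, r in enumerate(self.top.resnames)
                if str(r).upper() == value.upper()
            )
        if key == "resid":
            if self.top.resids is None:
                raise SelectionError("topology carries no residue ids")
            return frozenset(np.flatnonzero(self.top.resids == int(value)).tolist())
        raise SelectionError(f"unknown selection key {key!r}")


def select_group(topology: Topology, expression: str) -> frozenset[int]:
    """Resolve a selection expression to an atom index set.

    Supports ``group:LABEL``, ``element:SYM``, ``resname:NAME``,
    ``resid:N``, ``all``, combined with ``and`` / ``or`` / ``not`` and
    parentheses.  Deterministic and order-independent.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionError("empty selection expression")
    return _Parser(tokens, topology).parse()
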
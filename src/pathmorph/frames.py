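"""Core in-memory containers: atom records, structure frames and atom selections.

A :class:`StructureFrame` is one molecular conformation — an ordered list of
:class:`AtomRecord` plus an ``(n_atoms, 3)`` coordinate array in Ångström, with
an optional orthorhombic periodic box.  All downstream stages (morphing,
ensemble generation, annealing, membrane embedding, CV design) operate on
these frames, so the invariants enforced here (finite coordinates, one record
per coordinate row) are load-bearing for the whole pipeline.

Selections are expressed in a small boolean mini-language::

    name CA              atoms named CA
    resname ALA POPC     residue-name match (several alternatives allowed)
    resid 3-5 12         residue-number ranges and single numbers
    chain A              chain identifier
    heavy / hydrogen     element-based split
    all                  every atom

combined with ``and``, ``or``, ``not`` and parentheses.  ``select`` returns a
:class:`Selection`, a strictly increasing index vector into the frame.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "StructureFrame",
    "Selection",
    "select",
    "guess_element",
    "ATOMIC_MASSES",
]

# average atomic masses (u) for center-of-mass computations
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078, "ZN": 65.38,
    "FE": 55.845, "X": 12.011,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "SE", "MN", "CU"}


def guess_element(name: str) -> str:
    """Guess an element symbol from an atom name.

    Used when the element column of a PDB record is blank (a common malformed
    dialect).  Leading digits are stripped (``1HB`` is a hydrogen); two-letter
    elements are recognised only when the full stripped name matches, so
    ``CA`` is carbon (an alpha-carbon atom name), while ``CL`` is chlorine.
    """
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    upper = stripped.upper()
    if upper in _TWO_LETTER_ELEMENTS:
        return upper.capitalize() if len(upper) > 1 else upper
    return upper[0]


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity: serial, name, element and residue/chain context."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str = "A"

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)

    @property
    def key(self) -> tuple:
        """Correspondence key: (chain, residue number, atom name)."""
        return (self.chain, self.residue_number, self.name)


class StructureFrame:
    """One conformation: an ordered atom list plus coordinates in Å.

    Parameters
    ----------
    atoms
        Sequence of :class:`AtomRecord`, one per coordinate row.
    coords
        ``(n_atoms, 3)`` float array, Ångström.
    box
        Optional ``(3,)`` orthorhombic box lengths in Å.
    """

    def __init__(self, atoms: Sequence[AtomRecord], coords: np.ndarray,
                 box: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {coords.shape}")
        if len(atoms) != len(coords):
            raise ValueError(
                f"{len(atoms)} atom records but {len(coords)} coordinate rows")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials within one frame")
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        self.coords = coords
        self.box = None if box is None else np.asarray(box, dtype=float)

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        nres = len({(a.chain, a.residue_number) for a in self.atoms})
        return f"<StructureFrame: {len(self)} atoms, {nres} residues>"

    def copy(self) -> "StructureFrame":
        return StructureFrame(self.atoms, self.coords.copy(),
                              None if self.box is None else self.box.copy())

    def with_coords(self, coords: np.ndarray) -> "StructureFrame":
        """Same topology, new coordinates."""
        return StructureFrame(self.atoms, coords,
                              None if self.box is None else self.box.copy())

    def same_topology(self, other: "StructureFrame") -> bool:
        return self.atoms == other.atoms

    # -- convenience -------------------------------------------------------

    @property
    def heavy(self) -> "Selection":
        return Selection(np.flatnonzero([a.is_heavy for a in self.atoms]))

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    def center_of_mass(self, subset: "Selection | None" = None) -> np.ndarray:
        idx = np.arange(len(self)) if subset is None else subset.indices
        m = self.masses()[idx]
        return (self.coords[idx] * m[:, None]).sum(axis=0) / m.sum()

    def renumber_serials(self, start: int = 1) -> "StructureFrame":
        atoms = [replace(a, serial=start + i) for i, a in enumerate(self.atoms)]
        return StructureFrame(atoms, self.coords.copy(),
                              None if self.box is None else self.box.copy())


@dataclass(frozen=True)
class Selection:
    """A strictly increasing vector of atom positions into a StructureFrame."""

    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("negative atom index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, frame: StructureFrame) -> None:
        if self.indices.size and self.indices[-1] >= len(frame):
            raise IndexError("selection index beyond frame atom count")


# -- selection mini-language ----------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionError(ValueError):
    pass


class _Parser:
    """Recursive-descent parser: expr := term ('or' term)*;
    term := factor ('and' factor)*; factor := 'not' factor | '(' expr ')' | leaf.
    """

    def __init__(self, tokens: list[str], frame: StructureFrame):
        self.tokens = tokens
        self.pos = 0
        self.frame = frame

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.next()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.next()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.factor()
        if tok == "(":
            self.next()
            mask = self.expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        return self.leaf()

    def _collect_args(self) -> list[str]:
        args = []
        stop = {"and", "or", "not", "(", ")"}
        while self.peek() is not None and self.peek() not in stop:
            args.append(self.next())
        if not args:
            raise SelectionError("keyword requires at least one argument")
        return args

    def leaf(self) -> np.ndarray:
        atoms = self.frame.atoms
        n = len(atoms)
        kw = self.next()
        if kw == "all":
            return np.ones(n, dtype=bool)
        if kw == "heavy":
            return np.array([a.is_heavy for a in atoms])
        if kw == "hydrogen":
            return np.array([not a.is_heavy for a in atoms])
        if kw == "name":
            names = set(self._collect_args())
            return np.array([a.name in names for a in atoms])
        if kw == "resname":
            names = set(self._collect_args())
            return np.array([a.residue_name in names for a in atoms])
        if kw == "chain":
            chains = set(self._collect_args())
            return np.array([a.chain in chains for a in atoms])
        if kw == "resid":
            wanted: set[int] = set()
            for arg in self._collect_args():
                m = re.fullmatch(r"(-?\d+)-(-?\d+)", arg)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    wanted.update(range(lo, hi + 1))
                elif re.fullmatch(r"-?\d+", arg):
                    wanted.add(int(arg))
                else:
                    raise SelectionError(f"bad resid token {arg!r}")
            mask = np.array([a.residue_number in wanted for a in atoms])
            if not mask.any():
                warnings.warn(
                    f"resid selection {sorted(wanted)[:5]}... matched no atoms",
                    stacklevel=4)
            return mask
        raise SelectionError(f"unknown selection keyword {kw!r}")


def select(frame: StructureFrame, spec: str | Selection | Iterable[int]) -> Selection:
    """Evaluate a selection expression on a frame.

    ``spec`` may also be an existing :class:`Selection` (returned unchanged
    after validation) or an iterable of indices.  An unknown residue range
    yields an empty selection with a warning, not an error.
    """
    if isinstance(spec, Selection):
        spec.validate(frame)
        return spec
    if not isinstance(spec, str):
        sel = Selection(np.asarray(sorted(set(int(i) for i in spec)), dtype=int))
        sel.validate(frame)
        return sel
    tokens = _TOKEN_RE.findall(spec)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _Parser(tokens, frame).parse()
    return Selection(np.flatnonzero(mask))
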
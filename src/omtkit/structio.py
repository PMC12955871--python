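"""Multi-model PDB I/O and atom selection.

Conformational ensembles (e.g. frames exported from an MD trajectory) are
exchanged as standard fixed-column PDB files with one MODEL/ENDMDL block per
frame.  Every frame of an :class:`Ensemble` must share an identical atom
topology — the same atoms in the same order — which is what lets downstream
geometry code address atoms by selector once and apply it to every frame.

Conventions: coordinates are in Angstrom everywhere; for atoms with alternate
locations the first altloc encountered wins and occupancy is ignored
(ensembles here are models, not experimental density interpretations);
hydrogens are optional in inputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatOverflowError, PDBParseError, TopologyError

__all__ = [
    "Atom",
    "Frame",
    "Ensemble",
    "Selector",
    "parse_pdb",
    "write_pdb",
    "select",
]


@dataclass
class Atom:
    """One atom record: identity plus Cartesian coordinates in Angstrom."""

    serial: int
    name: str
    resname: str
    chain: str
    resseq: int
    xyz: np.ndarray
    element: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,):
            raise ValueError(f"xyz must be a 3-vector, got shape {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("atom coordinates must be finite")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.serial < 1:
            raise ValueError("atom serial must be >= 1")

    @property
    def topology_id(self) -> tuple[str, str, str, int]:
        return (self.name, self.resname, self.chain, self.resseq)


@dataclass
class Frame:
    """A single conformation: an ordered list of atoms."""

    index: int
    atoms: list[Atom]

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in frame order."""
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def topology_key(self) -> str:
        """Hash of the ordered (name, resname, chain, resseq) sequence."""
        h = hashlib.sha1()
        for a in self.atoms:
            h.update(f"{a.name}|{a.resname}|{a.chain}|{a.resseq};".encode())
        return h.hexdigest()

    def __len__(self) -> int:
        return len(self.atoms)


@dataclass
class Ensemble:
    """An ordered collection of frames with identical atom topology."""

    frames: list[Frame]
    topology_key: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("an Ensemble needs at least one frame")
        key = self.frames[0].topology_key()
        for f in self.frames[1:]:
            if f.topology_key() != key:
                raise TopologyError(
                    f"frame {f.index} has a different atom topology than frame "
                    f"{self.frames[0].index}"
                )
        indices = [f.index for f in self.frames]
        if len(set(indices)) != len(indices):
            raise ValueError("frame indices must be unique within an ensemble")
        self.topology_key = key

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)


@dataclass
class Selector:
    """Criteria for picking atoms: any combination of chain, residue number,
    residue name and atom names.  At least one criterion must be set."""

    chain: str | None = None
    resseq: int | None = None
    resname: str | None = None
    atom_names: list[str] | None = None

    def __post_init__(self) -> None:
        if (
            self.chain is None
            and self.resseq is None
            and self.resname is None
            and not self.atom_names
        ):
            raise ValueError("Selector needs at least one criterion")

    def matches(self, atom: Atom) -> bool:
        if self.chain is not None and atom.chain != self.chain:
            return False
        if self.resseq is not None and atom.resseq != self.resseq:
            return False
        if self.resname is not None and atom.resname != self.resname:
            return False
        if self.atom_names and atom.name not in self.atom_names:
            return False
        return True

    def __str__(self) -> str:
        parts = []
        if self.chain is not None:
            parts.append(f"chain={self.chain}")
        if self.resseq is not None:
            parts.append(f"resseq={self.resseq}")
        if self.resname is not None:
            parts.append(f"resname={self.resname}")
        if self.atom_names:
            parts.append(f"atom_names={','.join(self.atom_names)}")
        return "Selector(" + " ".join(parts) + ")"


def select(frame: Frame, sel: Selector) -> list[Atom]:
    """All atoms of *frame* matching every set criterion, in frame order.

    An empty result is a valid return; callers that require a unique match
    enforce that themselves.
    """
    return [a for a in frame.atoms if sel.matches(a)]


# ---------------------------------------------------------------------------
# PDB fixed-column format
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int, serial_fallback: int) -> tuple[Atom, str]:
    """Parse one ATOM/HETATM record; returns (atom, altloc)."""
    # pad so fixed-column slicing is safe on short lines
    rec = line.rstrip("\n").ljust(80)
    try:
        serial = int(rec[6:11])
    except ValueError:
        serial = serial_fallback
    name = rec[12:16].strip()
    altloc = rec[16].strip()
    resname = rec[17:20].strip()
    chain = rec[21].strip() or " "
    try:
        resseq = int(rec[22:26])
        x = float(rec[30:38])
        y = float(rec[38:46])
        z = float(rec[46:54])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-width record: {line!r}") from exc
    element = rec[76:78].strip()
    if not name:
        raise PDBParseError(f"line {lineno}: empty atom name")
    try:
        atom = Atom(serial=max(serial, 1), name=name, resname=resname, chain=chain,
                    resseq=resseq, xyz=np.array([x, y, z]), element=element)
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: {exc}") from exc
    return atom, altloc


def parse_pdb(text: str) -> Ensemble:
    """Read a (possibly multi-model) PDB character stream into an Ensemble.

    One frame per MODEL/ENDMDL block; a file without MODEL records yields a
    single frame.  Coordinates are read from the fixed columns 31-54.  For
    alternate locations the first altloc of each (chain, resseq, name) wins.

    Raises
    ------
    PDBParseError
        On a malformed fixed-width record (the message names the line).
    TopologyError
        If models do not share an identical atom topology.
    """
    frames: list[Frame] = []
    current: list[Atom] = []
    seen_altloc: set[tuple] = set()
    model_index: int | None = None
    saw_model = False
    n_serial = 0

    def _close(index: int) -> None:
        nonlocal current, seen_altloc
        if current:
            frames.append(Frame(index=index, atoms=current))
        current = []
        seen_altloc = set()

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            _close(model_index if model_index is not None else len(frames) + 1)
            try:
                model_index = int(line[6:].strip() or len(frames) + 1)
            except ValueError:
                model_index = len(frames) + 1
        elif rec == "ENDMDL":
            _close(model_index if model_index is not None else len(frames) + 1)
            model_index = None
        elif rec in ("ATOM", "HETATM"):
            n_serial += 1
            atom, altloc = _parse_atom_line(line, lineno, n_serial)
            if altloc:
                key = (atom.chain, atom.resseq, atom.name)
                if key in seen_altloc:
                    continue
                seen_altloc.add(key)
            current.append(atom)
    _close(model_index if model_index is not None else len(frames) + 1)

    if not frames:
        raise PDBParseError("no ATOM/HETATM records found")
    if not saw_model and len(frames) == 1:
        frames[0].index = 1
    return Ensemble(frames=frames)


def write_pdb(ens: Ensemble) -> str:
    """Serialize an Ensemble to fixed-column PDB text.

    Multi-frame ensembles get one MODEL/ENDMDL block per frame; a single-frame
    ensemble is written without MODEL records.  Output re-parses to the same
    topology and to coordinates equal at the 1e-3 Angstrom column precision.
    """
    lines: list[str] = []
    multi = len(ens.frames) > 1

    def _atom_line(a: Atom) -> str:
        if np.any(np.abs(a.xyz) >= 10000.0):
            raise FormatOverflowError(
                f"coordinate magnitude >= 10000 A cannot be written (atom {a.serial})"
            )
        # PDB atom-name alignment: 1-3 char names start in column 14
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        return (
            f"ATOM  {a.serial:>5d} {name:<4.4s} {a.resname:>3.3s} {a.chain:1.1s}"
            f"{a.resseq:>4d}    {a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}"
        )

    for frame in ens.frames:
        if multi:
            lines.append(f"MODEL     {frame.index:>4d}")
        for a in frame.atoms:
            lines.append(_atom_line(a))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
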
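"""Topology / frame containers and lipid atom selections."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from memtk.core_model.cell import TriclinicCell
from memtk.errors import SelectionError

#: Standard atomic masses (g/mol) for the elements the generators emit.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973761998,
    "S": 32.06,
}


def element_from_name(name: str) -> str:
    """Guess the element from an atom name (leading letters, MD convention)."""
    m = re.match(r"[A-Za-z]", name.strip())
    if not m:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    first = m.group(0).upper()
    return first


@dataclass
class Topology:
    """Per-atom metadata plus molecule grouping.

    Atom and molecule indices are 0-based.  ``molecules`` is a list of
    atom-index arrays; every atom must belong to exactly one molecule.
    """

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    molecules: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.masses = np.asarray(self.masses, dtype=float)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        n = len(self.names)
        for arr, what in (
            (self.elements, "elements"),
            (self.masses, "masses"),
            (self.resids, "resids"),
            (self.resnames, "resnames"),
        ):
            if len(arr) != n:
                raise ValueError(f"{what} has length {len(arr)}, expected {n}")
        if n and not np.all(self.masses > 0):
            bad = int(np.argmin(self.masses))
            raise ValueError(f"all masses must be > 0 (atom {bad}: {self.masses[bad]})")
        self.molecules = [np.asarray(m, dtype=int) for m in self.molecules]
        if self.molecules:
            counts = np.zeros(n, dtype=int)
            for mol in self.molecules:
                counts[mol] += 1
            if not np.all(counts == 1):
                bad = int(np.argmax(counts != 1))
                raise ValueError(
                    f"atom {bad} belongs to {counts[bad]} molecules; expected exactly 1"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    def molecule_of(self) -> np.ndarray:
        """Array mapping atom index -> molecule index."""
        out = np.full(self.n_atoms, -1, dtype=int)
        for i, mol in enumerate(self.molecules):
            out[mol] = i
        return out

    def select_resname(self, resname: str) -> np.ndarray:
        return np.nonzero(self.resnames == resname)[0]


@dataclass
class Frame:
    """One trajectory frame: time (ns), positions (nm), periodic cell."""

    time: float
    positions: np.ndarray
    cell: TriclinicCell

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")


def validate_frames(topology: Topology, frames) -> None:
    """Check atom counts and time monotonicity; raises ValueError."""
    last = -np.inf
    for k, fr in enumerate(frames):
        if len(fr.positions) != topology.n_atoms:
            raise ValueError(
                f"frame {k}: expected {topology.n_atoms} atoms, found {len(fr.positions)}"
            )
        if fr.time < last:
            raise ValueError(f"frame {k}: time {fr.time} ns decreases (previous {last} ns)")
        last = fr.time


_CARBON_RE = re.compile(r"^C(\d+)([A-Z])$")
_HYDROGEN_RE = re.compile(r"^H(\d+)([A-Z])(\d)$")


@dataclass
class LipidSelection:
    """Per-lipid atom indices needed by the membrane analyses.

    ``acyl`` holds, per lipid, a mapping chain-name -> ordered list of
    ``(carbon_index, [hydrogen_indices])`` pairs along the chain.
    """

    phosphorus: np.ndarray
    headgroups: list[np.ndarray]
    acyl: list[dict[str, list[tuple[int, list[int]]]]]
    resids: np.ndarray

    def __post_init__(self) -> None:
        self.phosphorus = np.asarray(self.phosphorus, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)

    @property
    def n_lipids(self) -> int:
        return len(self.phosphorus)

    @property
    def chain_names(self) -> list[str]:
        return sorted(self.acyl[0]) if self.acyl else []

    @classmethod
    def from_topology(
        cls,
        topology: Topology,
        resnames: tuple[str, ...] = ("POPC",),
        phosphorus_name: str = "P",
    ) -> "LipidSelection":
        """Build a selection from atom-name conventions.

        Acyl carbons are named ``C<k><chain>`` and their hydrogens
        ``H<k><chain><j>`` (e.g. ``C3A`` / ``H3A1`` / ``H3A2``); any
        atom between the phosphorus and the first carbon is treated as
        headgroup.
        """
        resnames = tuple(resnames)
        phos, heads, acyl, rids = [], [], [], []
        seen = set()
        for resid, resname in zip(topology.resids, topology.resnames):
            if resname not in resnames or resid in seen:
                continue
            seen.add(resid)
            atom_idx = np.nonzero(topology.resids == resid)[0]
            names = topology.names[atom_idx]
            p_local = np.nonzero(names == phosphorus_name)[0]
            if len(p_local) != 1:
                raise SelectionError(
                    f"lipid resid {resid}: expected exactly one {phosphorus_name!r} "
                    f"atom, found {len(p_local)}"
                )
            chains: dict[str, dict[int, tuple[int, list[int]]]] = {}
            head = []
            for ai, nm in zip(atom_idx, names):
                cm = _CARBON_RE.match(str(nm))
                hm = _HYDROGEN_RE.match(str(nm))
                if cm:
                    k, ch = int(cm.group(1)), cm.group(2)
                    chains.setdefault(ch, {})[k] = (int(ai), [])
                elif hm:
                    pass  # second pass, carbons first
                elif nm != phosphorus_name:
                    head.append(int(ai))
            for ai, nm in zip(atom_idx, names):
                hm = _HYDROGEN_RE.match(str(nm))
                if hm:
                    k, ch = int(hm.group(1)), hm.group(2)
                    if ch not in chains or k not in chains[ch]:
                        raise SelectionError(
                            f"lipid resid {resid}: hydrogen {nm} has no carbon C{k}{ch}"
                        )
                    chains[ch][k][1].append(int(ai))
            acyl_entry = {
                ch: [chains[ch][k] for k in sorted(chains[ch])] for ch in sorted(chains)
            }
            phos.append(int(atom_idx[p_local[0]]))
            heads.append(np.asarray(head, dtype=int))
            acyl.append(acyl_entry)
            rids.append(int(resid))
        if not phos:
            raise SelectionError(f"no lipids with resnames {resnames} found")
        return cls(np.asarray(phos), heads, acyl, np.asarray(rids))
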
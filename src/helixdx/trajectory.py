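"""Helix trajectory container.

Wraps an :class:`mdtraj.Trajectory` restricted to a single helical
peptide, with C99 residue numbering and uniform frame spacing.  All
feature extraction (H-bond occupancies, packing, fluctuations, geometry)
operates on this container; readers/writers live in :mod:`helixdx.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import mdtraj as md

BACKBONE_NAMES = ("N", "H", "CA", "C", "O")
HYDROXYL_O = ("OG", "OG1")


@dataclass
class HelixTrajectory:
    """Per-frame coordinates (nm) of one helical peptide.

    ``residue_numbers`` are C99 numbers of the peptide residues proper
    (terminal cap groups such as ACE/NH2 are retained in the topology but
    are not profiled).
    """

    traj: md.Trajectory
    frame_interval_ps: float = 10.0
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {}
        for atom in self.traj.topology.atoms:
            if atom.residue.name in ("ACE", "NH2", "NME"):
                continue
            self._index[(atom.residue.resSeq, atom.name)] = atom.index
        if self.n_frames == 0:
            raise ValueError("empty trajectory")

    @property
    def n_frames(self) -> int:
        return self.traj.n_frames

    @property
    def residue_numbers(self) -> list[int]:
        return sorted({r for (r, name) in self._index if name == "CA"})

    @property
    def xyz(self) -> np.ndarray:
        return self.traj.xyz

    def has_atom(self, residue_number: int, name: str) -> bool:
        return (residue_number, name) in self._index

    def atom_index(self, residue_number: int, name: str) -> int:
        try:
            return self._index[(residue_number, name)]
        except KeyError:
            raise KeyError(
                f"no atom {name!r} at residue {residue_number}"
            ) from None

    def coords(self, residue_number: int, name: str) -> np.ndarray:
        """(n_frames, 3) coordinates of one atom."""
        return self.traj.xyz[:, self.atom_index(residue_number, name)]

    def ca_coords(self, residue_numbers) -> np.ndarray:
        """(n_frames, len(residues), 3) CA coordinates."""
        idx = [self.atom_index(r, "CA") for r in residue_numbers]
        return self.traj.xyz[:, idx]

    def residue_name(self, residue_number: int) -> str:
        for res in self.traj.topology.residues:
            if res.resSeq == residue_number and res.name not in ("ACE", "NH2"):
                return res.name
        raise KeyError(residue_number)

    def hydroxyl_atoms(self, residue_number: int):
        """(O_index, H_index) of a Ser/Thr side-chain hydroxyl."""
        for oname in HYDROXYL_O:
            if self.has_atom(residue_number, oname):
                return (
                    self.atom_index(residue_number, oname),
                    self.atom_index(residue_number, "HG1"),
                )
        raise ValueError(f"residue {residue_number} carries no hydroxyl")

    def slice_frames(self, key) -> "HelixTrajectory":
        return HelixTrajectory(
            traj=self.traj[key], frame_interval_ps=self.frame_interval_ps
        )

    def sidechain_heavy_indices(self, exclude_residue: int | None = None):
        """Indices of side-chain heavy atoms (CB and beyond), optionally
        excluding one residue."""
        out = []
        for atom in self.traj.topology.atoms:
            if atom.residue.name in ("ACE", "NH2"):
                continue
            if atom.element == md.element.hydrogen:
                continue
            if atom.name in BACKBONE_NAMES:
                continue
            if exclude_residue is not None and atom.residue.resSeq == exclude_residue:
                continue
            out.append(atom.index)
        return out
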
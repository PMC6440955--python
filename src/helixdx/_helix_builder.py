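"""Constructive ideal-helix geometry.

Builds peptide backbones from internal coordinates (NeRF chain extension
with standard bond lengths/angles), including amide hydrogens, carbonyl
oxygens, C-beta atoms and Thr/Ser hydroxyls, plus acetyl/amide caps.
Geometry is constructive, not dynamical: it exists so that hydrogen-bond,
packing and hinge analyses can be tested against planted ground truth.

Internal units: nanometres (mdtraj convention).
"""

from __future__ import annotations

import numpy as np
import mdtraj as md

# standard backbone internal coordinates (nm / degrees)
B_N_CA, B_CA_C, B_C_N = 0.1458, 0.1525, 0.1329
B_N_H, B_C_O, B_CA_CB = 0.101, 0.1231, 0.153
B_CB_OG, B_OG_HG = 0.1417, 0.096
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
ALPHA_PHI, ALPHA_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -180.0, 180.0

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement: position D bonded to C with angle B-C-D and
    torsion A-B-C-D."""
    angle = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dih),
            bond * np.sin(angle) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _bisector_antipode(center, p1, p2, bond):
    u1 = (p1 - center) / np.linalg.norm(p1 - center)
    u2 = (p2 - center) / np.linalg.norm(p2 - center)
    d = -(u1 + u2)
    return center + bond * d / np.linalg.norm(d)


def build_backbone(sequence: str, phi=None, psi=None, chi1: float = -60.0):
    """Backbone + CB + Thr/Ser hydroxyl coordinates for one conformation.

    Parameters
    ----------
    sequence : one-letter string.
    phi, psi : per-residue dihedrals in degrees (scalars broadcast);
        defaults are ideal alpha-helix values (-57, -47).
    chi1 : N-CA-CB-OG torsion for hydroxyl residues; the -60 rotamer
        points the Thr/Ser hydroxyl at the i-4 backbone carbonyl.

    Returns
    -------
    atoms : list of (residue_index, atom_name) with residue_index -1 for
        the N-terminal acetyl cap and ``len(sequence)`` for the C-terminal
        amide cap.
    coords : (n_atoms, 3) array, nm.
    """
    n = len(sequence)
    phi = np.broadcast_to(np.asarray(ALPHA_PHI if phi is None else phi, float), (n,))
    psi = np.broadcast_to(np.asarray(ALPHA_PSI if psi is None else psi, float), (n,))

    # main chain including acetyl cap: CH3-C(=O)-[N-CA-C]xN-NH2
    ch3 = np.array([0.0, 0.0, 0.0])
    c_ace = np.array([0.152, 0.0, 0.0])
    n0 = place_atom(np.array([0.0, 0.1, -0.1]), ch3, c_ace, B_C_N, A_CA_C_N, 150.0)
    main = {(-1, "CH3"): ch3, (-1, "C"): c_ace}
    prev3 = (ch3, c_ace, n0)  # (a, b, c) seeds the NeRF chain
    n_atom = {0: n0}
    ca_atom, c_atom = {}, {}
    for i in range(n):
        a, b, c = prev3
        ca = place_atom(a, b, c, B_N_CA, A_C_N_CA, 180.0)
        cc = place_atom(b, c, ca, B_CA_C, A_N_CA_C, phi[i])
        nn = place_atom(c, ca, cc, B_C_N, A_CA_C_N, psi[i])
        ca_atom[i], c_atom[i] = ca, cc
        n_atom[i + 1] = nn  # residue n's successor is the cap nitrogen
        prev3 = (ca, cc, nn)

    atoms, coords = [], []

    def emit(key, xyz):
        atoms.append(key)
        coords.append(xyz)

    emit((-1, "CH3"), main[(-1, "CH3")])
    emit((-1, "C"), main[(-1, "C")])
    emit((-1, "O"), _bisector_antipode(c_ace, ch3, n_atom[0], B_C_O))
    prev_c = c_ace
    for i, aa in enumerate(sequence):
        ni, cai, ci = n_atom[i], ca_atom[i], c_atom[i]
        emit((i, "N"), ni)
        if aa != "P":
            emit((i, "H"), _bisector_antipode(ni, prev_c, cai, B_N_H))
        emit((i, "CA"), cai)
        if aa != "G":
            cb = place_atom(prev_c, ni, cai, B_CA_CB, 110.4, phi[i] + 122.6)
            emit((i, "CB"), cb)
            if aa in ("T", "S"):
                og = place_atom(ni, cai, cb, B_CB_OG, 109.5, chi1)
                name_o = "OG1" if aa == "T" else "OG"
                emit((i, name_o), og)
                hg = place_atom(cai, cb, og, B_OG_HG, 109.5, 180.0)
                emit((i, "HG1"), hg)
        emit((i, "C"), ci)
        emit((i, "O"), _bisector_antipode(ci, cai, n_atom[i + 1], B_C_O))
        prev_c = ci
    # C-terminal amide cap
    ncap = n_atom[n]
    emit((n, "N"), ncap)
    emit((n, "H"), _bisector_antipode(ncap, prev_c, ncap + np.array([0.0, 0.0, 0.1]),
                                      B_N_H))
    return atoms, np.asarray(coords)


def build_topology(sequence: str, atoms, first_residue_number: int) -> md.Topology:
    """mdtraj topology matching ``build_backbone`` output, with ACE/NH2
    caps and C99 residue numbering."""
    top = md.Topology()
    chain = top.add_chain()
    residues = {}
    residues[-1] = top.add_residue("ACE", chain, resSeq=first_residue_number - 1)
    for i, aa in enumerate(sequence):
        residues[i] = top.add_residue(
            THREE_LETTER[aa], chain, resSeq=first_residue_number + i
        )
    residues[len(sequence)] = top.add_residue(
        "NH2", chain, resSeq=first_residue_number + len(sequence)
    )
    elem = {
        "N": md.element.nitrogen, "C": md.element.carbon,
        "O": md.element.oxygen, "H": md.element.hydrogen,
    }
    for res_idx, name in atoms:
        e = elem[name[0]] if name[0] in "NCOH" else md.element.carbon
        top.add_atom(name, e, residues[res_idx])
    return top


def helix_axis_direction(ca_coords: np.ndarray) -> np.ndarray:
    """Unit axis of a (near-)helical run of CA atoms, oriented N->C.

    Uses the rotation-fit construction: successive bond-vector
    differences point at the axis centre; consecutive cross products give
    the axis direction exactly for an ideal helix.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.shape[0] < 4:
        raise ValueError("need >= 4 CA positions for an axis fit")
    v = np.diff(ca, axis=0)
    a = np.diff(v, axis=0)
    axes = []
    sines = []
    for i in range(a.shape[0] - 1):
        cr = np.cross(a[i], a[i + 1])
        nrm = np.linalg.norm(cr)
        denom = np.linalg.norm(a[i]) * np.linalg.norm(a[i + 1])
        sines.append(nrm / denom if denom > 0 else 0.0)
        if nrm < 1e-12:
            continue
        axes.append(cr / nrm)
    if axes and np.median(sines) > 0.1:
        axis = np.mean(axes, axis=0)
    else:
        # near-straight geometry (extended chain): the cross-product
        # construction degenerates; use the principal direction instead
        centered = ca - ca.mean(axis=0)
        _u, s, vt = np.linalg.svd(centered, full_matrices=False)
        if s[1] < 1e-6:
            raise ValueError(
                "degenerate (collinear) CA geometry: no helix axis"
            )
        axis = vt[0]
    axis = axis / np.linalg.norm(axis)
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.deg2rad(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)
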
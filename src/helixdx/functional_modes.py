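"""Partial-least-squares functional mode analysis (PLS-FMA).

Finds the collective backbone motion maximally correlated with a scalar
order parameter - here the summed closed-H-bond count over a residue
window (default V44-I47, the region whose H-bond dynamics differs
between wild type and the I45T mutant).  A PLS regression of the order
parameter on centered Cartesian coordinates is trained on the first half
of the trajectory and cross-validated on the second (chronological
split); the ensemble-weighted maximally correlated motion (ewMCM) is the
covariance-weighted regression direction, unit-normalized, and
conformations interpolated along it visualize the motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr
from sklearn.cross_decomposition import PLSRegression

from .helix_geometry import _rigid_transform
from .trajectory import HelixTrajectory
from .trajectory_features import hbond_closed

__all__ = [
    "OrderParameterSeries",
    "FunctionalModeModel",
    "build_order_parameter",
    "fit_pls_fma",
    "mode_overlap",
    "interpolate_along_mode",
]

BACKBONE_HEAVY = ("N", "CA", "C", "O")
DEFAULT_FIT_RANGE = (29, 52)
DEFAULT_SUPERPOSE_RANGE = (31, 35)
DEFAULT_WINDOW = (44, 47)


@dataclass
class OrderParameterSeries:
    """Per-frame summed closed helix H-bond count over a residue window."""

    values: np.ndarray
    window: tuple = DEFAULT_WINDOW
    max_value: int = 4


@dataclass
class FunctionalModeModel:
    n_components: int
    ewmcm: np.ndarray  # (n_atoms, 3), |ewmcm| = 1
    r_train: float
    r_valid: float
    r_curve: list  # (components, r_train, r_valid) triples
    atom_indices: np.ndarray
    reference: np.ndarray  # (n_atoms, 3) training-mean structure
    projections: np.ndarray  # per-frame scalar extent along the mode
    topology: object = field(repr=False, default=None)
    frame_interval_ps: float = 10.0


def build_order_parameter(
    traj: HelixTrajectory, window: tuple = DEFAULT_WINDOW
) -> OrderParameterSeries:
    """Count, per frame, residues in the window whose alpha or 3_10
    H-bond is closed."""
    residues = list(range(window[0], window[1] + 1))
    if not residues:
        raise ValueError("empty order-parameter window")
    total = np.zeros(traj.n_frames)
    for res in residues:
        closed = hbond_closed(traj, res, 4) | hbond_closed(traj, res, 3)
        total += closed
    return OrderParameterSeries(
        values=total, window=window, max_value=len(residues)
    )


def _fit_atoms(traj, fit_range, names=BACKBONE_HEAVY):
    idx = []
    for res in traj.residue_numbers:
        if fit_range[0] <= res <= fit_range[1]:
            for name in names:
                if traj.has_atom(res, name):
                    idx.append(traj.atom_index(res, name))
    return np.asarray(idx, dtype=int)


def _superpose_all(coords, fit_subset_idx, reference_fit):
    """Superpose each frame onto a reference using the fit subset;
    the transform is applied to all atoms of the frame."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot, t = _rigid_transform(coords[f, fit_subset_idx], reference_fit)
        out[f] = coords[f] @ rot.T + t
    return out


def fit_pls_fma(
    traj: HelixTrajectory,
    order: OrderParameterSeries,
    n_components: int = 6,
    fit_range: tuple = DEFAULT_FIT_RANGE,
    superpose_range: tuple = DEFAULT_SUPERPOSE_RANGE,
) -> FunctionalModeModel:
    """Fit the PLS functional-mode model.

    The first half of the trajectory trains the regression, the second
    half cross-validates it (R_m = Pearson correlation between the order
    parameter and its model reconstruction).  The returned ewMCM is
    Cov(X) @ beta, unit-normalized - the Cartesian displacement pattern
    whose motion carries the correlated variance.
    """
    y = np.asarray(order.values, dtype=float)
    if y.std() == 0:
        raise ValueError("constant order parameter: nothing to correlate")
    if n_components < 1:
        raise ValueError("need at least one PLS component")
    atoms = _fit_atoms(traj, fit_range)
    sup_atoms = _fit_atoms(traj, superpose_range)
    sup_local = np.searchsorted(atoms, sup_atoms)
    coords = traj.traj.xyz[:, atoms].astype(float)

    half = coords.shape[0] // 2
    ref_fit = coords[:half, sup_local.tolist()].mean(axis=0)
    aligned = _superpose_all(coords, sup_local.tolist(), ref_fit)
    x = aligned.reshape(aligned.shape[0], -1)
    x_mean = x[:half].mean(axis=0)
    xc = x - x_mean
    y_train, y_valid = y[:half], y[half:]

    def fit(nc):
        pls = PLSRegression(n_components=nc, scale=False)
        pls.fit(xc[:half], y_train - y_train.mean())
        yhat = pls.predict(xc).ravel() + y_train.mean()
        rt = pearsonr(y_train, yhat[:half]).statistic
        rv = pearsonr(y_valid, yhat[half:]).statistic
        return pls, rt, rv

    curve = []
    for nc in range(1, n_components + 1):
        _, rt, rv = fit(nc)
        curve.append((nc, float(rt), float(rv)))
    pls, r_train, r_valid = fit(n_components)

    beta = np.asarray(pls.coef_).reshape(-1)
    xt = xc[:half]
    v = xt.T @ (xt @ beta) / (half - 1)  # Cov(X) beta without forming Cov
    v /= np.linalg.norm(v)
    projections = xc @ v
    reference = (x_mean).reshape(-1, 3)
    return FunctionalModeModel(
        n_components=n_components,
        ewmcm=v.reshape(-1, 3),
        r_train=float(r_train),
        r_valid=float(r_valid),
        r_curve=curve,
        atom_indices=atoms,
        reference=reference,
        projections=projections,
        topology=traj.traj.topology.subset(atoms),
        frame_interval_ps=traj.frame_interval_ps,
    )


def mode_overlap(v1: np.ndarray, v2: np.ndarray) -> float:
    """Inner-product similarity |v1 . v2| of two unit mode vectors."""
    a = np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"mode dimensions differ: {a.shape} vs {b.shape}")
    for v, name in ((a, "v1"), (b, "v2")):
        n = np.linalg.norm(v)
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError(f"{name} is not unit-normalized (|{name}|={n:.4g})")
    return float(abs(np.dot(a, b)))


def interpolate_along_mode(
    model: FunctionalModeModel,
    n_steps: int = 11,
    amplitude_range: tuple | None = None,
):
    """Conformations reference + a * ewMCM on a linear amplitude grid.

    By default the grid spans the observed projection extremes.  Returns
    a :class:`HelixTrajectory` of ``n_steps`` conformations ordered from
    low to high amplitude (endpoints feed the hinge classification).
    """
    import mdtraj as md

    if amplitude_range is None:
        amplitude_range = (
            float(model.projections.min()), float(model.projections.max())
        )
    if n_steps == 1:
        amps = np.array([0.5 * (amplitude_range[0] + amplitude_range[1])])
    else:
        amps = np.linspace(amplitude_range[0], amplitude_range[1], n_steps)
    frames = np.array(
        [model.reference + a * model.ewmcm for a in amps], dtype=np.float32
    )
    traj = md.Trajectory(xyz=frames, topology=model.topology)
    return HelixTrajectory(
        traj=traj, frame_interval_ps=model.frame_interval_ps
    )
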
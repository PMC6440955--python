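"""Synthetic exchange datasets and helix trajectories with known truth.

Two generators emulate the statistical structure of the measured inputs:

* :func:`gen_exchange_dataset` - multi-exponential EX2 exchange with the
  5% residual-deuterium floor, ETD c/z fragment ladders with Gaussian
  replicate noise, on the experiment's 13-point time grid (0.1 min-7 d).
* :func:`gen_helix_trajectory` - an ideal alpha-helix with a planted
  hinge bend, per-residue H-bond open probabilities realized by carbonyl
  displacement, Thr/Ser back-bond planting, AR(1) frame correlation and
  an optional planted linear mode.

Geometry is constructive, not dynamical; every generator can record its
ground truth and outputs to disk in the public formats the analysis
readers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import mdtraj as md

from . import _helix_builder as hb
from ._rate_tables import R_KCAL
from .chem_rates import ExchangeConditions, compute_intrinsic_rates
from .exchange_kinetics import (
    AMPLITUDE,
    BASELINE,
    FragmentIonSeries,
    OverallExchangeCurve,
)
from .peptides import A26_55_WT, PeptideSpec
from .trajectory import HelixTrajectory

__all__ = [
    "ExchangeTruth",
    "TrajectoryTruth",
    "ASSAY_TIME_GRID_MIN",
    "step_delta_g_profile",
    "default_open_probabilities",
    "gen_exchange_dataset",
    "gen_helix_trajectory",
    "bend_mode_vector",
]

# 13 incubation periods spanning 0.1 min to 7 days (minutes)
ASSAY_TIME_GRID_MIN = np.array(
    [0.1, 0.5, 1.0, 5.0, 10.0, 30.0, 60.0, 180.0, 480.0,
     1440.0, 2880.0, 4320.0, 10080.0]
)


def step_delta_g_profile(peptide: PeptideSpec = A26_55_WT) -> dict:
    """A step-shaped H-bond stability truth profile: a flexible,
    Gly-rich N-terminal helix half (< 2 kcal/mol) joined to a rigid
    C-terminal half (~5 kcal/mol) that carries the cleavage sites."""
    out = {}
    for n in peptide.amide_residue_numbers():
        if n <= 35:
            out[n] = 1.0
        elif n <= 40:  # hinge region, intermediate
            out[n] = 1.0 + (n - 35) * 0.6
        elif n <= 51:
            out[n] = 5.0
        else:  # C-terminal lysine tail
            out[n] = 2.0
    return out


@dataclass
class ExchangeTruth:
    """Ground truth for an exchange dataset.

    ``delta_g`` maps residue number -> kcal/mol; the generated
    k_exp = k_ch / (1 + exp(dG/RT)) is always below k_ch.
    """

    delta_g: dict
    conditions: ExchangeConditions = field(default_factory=ExchangeConditions)
    noise_sd: float = 0.05  # deuterons, per fragment content
    n_replicates: int = 3
    times_min: np.ndarray = field(
        default_factory=lambda: ASSAY_TIME_GRID_MIN.copy()
    )
    seed: int = 0


def gen_exchange_dataset(
    truth: ExchangeTruth,
    peptide: PeptideSpec = A26_55_WT,
    out_dir: str | Path | None = None,
):
    """Generate fragment ladders, the overall curve and a truth record.

    Per-residue retention y_i(t) = 0.95 exp(-k_i t) + 0.05; c/z fragment
    deuteron contents are cumulative sums over the amides each fragment
    carries, with Gaussian noise per replicate.  Returns
    ``(fragments, overall_curve, record)``; with ``out_dir`` the dataset
    is also written as CSV/JSON (see :mod:`helixdx.io`).
    """
    rng = np.random.default_rng(truth.seed)
    chem = compute_intrinsic_rates(peptide, truth.conditions)
    amides = list(chem.residue_numbers)
    rt = R_KCAL * truth.conditions.temperature
    t = np.asarray(truth.times_min, dtype=float)

    k_exp, flags = {}, {}
    for n in amides:
        dg = truth.delta_g.get(n)
        if dg is None:
            raise ValueError(f"truth has no dG for amide {n}")
        k = chem.rate_at(n) / (1.0 + np.exp(dg / rt))
        k_exp[n] = k
        if k < 1.0 / (10.0 * t.max()):
            flags[n] = "unidentifiable-by-design: k below 1/(10 max time)"

    retention = {n: AMPLITUDE * np.exp(-k_exp[n] * t) + BASELINE for n in amides}

    from .exchange_kinetics import _amides_covered  # shared convention

    fragments = []
    nres = peptide.n_residues
    for rep in range(truth.n_replicates):
        for ion in ("c", "z"):
            for length in range(1, nres):
                covered = _amides_covered(ion, length, peptide)
                clean = sum(retention[n] for n in covered) if covered else 0.0 * t
                noisy = clean + rng.normal(0.0, truth.noise_sd, size=t.shape)
                fragments.append(
                    FragmentIonSeries(
                        ion_type=ion, fragment_length=length, times=t,
                        deuterons=noisy, replicate_id=rep,
                    )
                )

    overall_clean = sum(retention[n] for n in amides)
    reps = overall_clean + rng.normal(
        0.0, truth.noise_sd, size=(truth.n_replicates, t.size)
    )
    overall = OverallExchangeCurve(
        times=t,
        remaining_deuterons=reps.mean(axis=0),
        sem=reps.std(axis=0, ddof=1) / np.sqrt(truth.n_replicates),
        n_replicates=truth.n_replicates,
    )
    record = {
        "peptide": peptide.name,
        "delta_g": {int(k): float(v) for k, v in truth.delta_g.items()},
        "k_exp": {int(k): float(v) for k, v in k_exp.items()},
        "k_ch": {int(n): chem.rate_at(n) for n in amides},
        "flags": {int(k): v for k, v in flags.items()},
        "noise_sd": truth.noise_sd,
        "n_replicates": truth.n_replicates,
        "seed": truth.seed,
        "conditions": asdict(truth.conditions),
    }
    if out_dir is not None:
        from . import io as hio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hio.write_fragments(out / "fragments.csv", fragments)
        hio.write_overall_curve(out / "overall.csv", overall)
        (out / "truth.json").write_text(json.dumps(record, indent=1))
    return fragments, overall, record


# ------------------------------------------------------------- trajectories


def default_open_probabilities(peptide: PeptideSpec = A26_55_WT) -> dict:
    """Per-residue H-bond open probabilities shaped like the simulated
    occupancy profile: a flexible N-terminal half and a weak-occupancy
    stretch around the G37/G38 hinge joined to a tight C-terminal half."""
    out = {}
    for n in peptide.residue_numbers:
        if n <= 32:
            out[n] = 0.35
        elif n <= 37:
            out[n] = 0.25
        elif n <= 41:  # low-occupancy hinge stretch
            out[n] = 0.5
        elif n <= 52:
            out[n] = 0.05
        else:
            out[n] = 0.3
    return out


@dataclass
class TrajectoryTruth:
    """Ground truth and knobs for a synthetic helix trajectory."""

    peptide: PeptideSpec = field(default_factory=lambda: A26_55_WT)
    n_frames: int = 5000
    frame_interval_ps: float = 10.0
    hinge_residue: int = 38  # bend applied after this residue's CA
    bend_mean_deg: float = 25.0
    bend_sd_deg: float = 10.0
    bend_direction_deg: float = 0.0
    twist_mean_deg: float = 0.0  # rotation of the C-part about the helix axis
    twist_sd_deg: float = 0.0
    open_probabilities: dict | None = None  # residue -> p(open); None: default profile
    rho: float = 0.9  # AR(1) lag-1 correlation of states and amplitudes
    backbond_occupancy: float = 0.98  # Thr/Ser hydroxyl -> O(i-4)
    jitter_nm: float = 0.004
    jitter_overrides: dict = field(default_factory=dict)  # residue -> sigma
    planted_mode: np.ndarray | None = None  # (n_atoms, 3) displacement
    mode_sd: float = 1.0  # SD of the planted-mode scalar series
    seed: int = 0

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ValueError("AR(1) coefficient must satisfy |rho| < 1")
        if self.open_probabilities is None:
            self.open_probabilities = default_open_probabilities(self.peptide)
        if any(not 0.0 <= p <= 1.0 for p in self.open_probabilities.values()):
            raise ValueError("open probabilities must lie in [0, 1]")


def static_conformation_trajectory(
    peptide: PeptideSpec = A26_55_WT,
    n_frames: int = 1,
    phi=None,
    psi=None,
    frame_interval_ps: float = 10.0,
) -> HelixTrajectory:
    """Identical frames of one constructed conformation (ideal helix by
    default; pass phi/psi 180 for an extended chain)."""
    atoms, coords = hb.build_backbone(peptide.sequence, phi=phi, psi=psi)
    top = hb.build_topology(peptide.sequence, atoms,
                            peptide.first_residue_number)
    xyz = np.repeat(coords[None].astype(np.float32), n_frames, axis=0)
    traj = md.Trajectory(xyz=xyz, topology=top,
                         time=np.arange(n_frames) * frame_interval_ps)
    return HelixTrajectory(traj=traj, frame_interval_ps=frame_interval_ps)


def _markov_states(rng, n, p, rho):
    """Binary chain with stationary P(open)=p and lag-1 correlation rho."""
    if p in (0.0, 1.0):
        return np.full(n, bool(p))
    stay_open = p + rho * (1 - p)
    go_open = p * (1 - rho)
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < p
    u = rng.random(n)
    for i in range(1, n):
        states[i] = u[i] < (stay_open if states[i - 1] else go_open)
    return states


def _ar1_series(rng, n, mean, sd, rho):
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0)
    eps = rng.normal(0.0, np.sqrt(1 - rho**2), size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    return mean + sd * x


def bend_mode_vector(
    atoms, coords, hinge_residue_index: int, angle_deg: float = 1.0,
    direction_deg: float = 0.0,
) -> np.ndarray:
    """Unit-normalized displacement field of a small hinge bend, for use
    as a planted linear mode."""
    ca = np.array(
        [coords[i] for i, (r, n) in enumerate(atoms) if n == "CA" and r >= 0]
    )
    axis = hb.helix_axis_direction(ca)
    pivot = ca[hinge_residue_index]
    ref = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(ref) < 1e-6:
        ref = np.cross(axis, [0.0, 1.0, 0.0])
    ref /= np.linalg.norm(ref)
    bend_axis = hb.rotation_matrix(axis, direction_deg) @ ref
    rot = hb.rotation_matrix(bend_axis, angle_deg)
    disp = np.zeros_like(coords)
    for i, (r, _name) in enumerate(atoms):
        if r > hinge_residue_index:
            disp[i] = (rot @ (coords[i] - pivot)) + pivot - coords[i]
    return disp / np.linalg.norm(disp)


def gen_helix_trajectory(
    truth: TrajectoryTruth, out_dir: str | Path | None = None,
    coordinate_format: str = "xtc",
):
    """Build a synthetic helix trajectory with planted dynamics.

    Per frame, on the ideal straight helix: H-bond open states (Markov,
    AR(1)-correlated) displace the acceptor carbonyl O radially until the
    donor's 0.26 nm criterion fails; Thr/Ser back-bonds are planted by
    swinging the hydroxyl onto the i-4 carbonyl; then the C-terminal part
    is rotated about the hinge by an AR(1) bend amplitude; an optional
    planted linear mode and Gaussian jitter are added last.

    Returns ``(HelixTrajectory, record)`` where the record carries the
    generated truth (bend series, open fractions, mode scalar series).
    """
    rng = np.random.default_rng(truth.seed)
    pep = truth.peptide
    atoms, base = hb.build_backbone(pep.sequence)
    top = hb.build_topology(pep.sequence, atoms, pep.first_residue_number)
    first = pep.first_residue_number
    aidx = {key: i for i, key in enumerate(atoms)}
    n_res = pep.n_residues
    nf = truth.n_frames

    ca = np.array([base[aidx[(i, "CA")]] for i in range(n_res)])
    axis = hb.helix_axis_direction(ca)
    centroid = ca.mean(axis=0)

    def radial_out(point):
        rel = point - centroid
        rad = rel - np.dot(rel, axis) * axis
        nrm = np.linalg.norm(rad)
        if nrm < 1e-9:
            raise ValueError("point on the helix axis: no radial direction")
        return rad / nrm

    # per-donor open-state chains (donor i uses acceptor O at i-4)
    donors = [
        i for i in range(4, n_res)
        if (i, "H") in aidx and (i - 4, "O") in aidx
    ]
    open_states = {}
    for i in donors:
        p = truth.open_probabilities.get(first + i, 0.0)
        open_states[i] = _markov_states(rng, nf, p, truth.rho)

    hydroxyls = [
        i for i, a in enumerate(pep.sequence)
        if a in ("T", "S") and i >= 4 and (i, "OG1" if a == "T" else "OG") in aidx
    ]
    backbond_states = {
        i: _markov_states(rng, nf, truth.backbond_occupancy, truth.rho)
        for i in hydroxyls
    }

    bend_series = _ar1_series(
        rng, nf, truth.bend_mean_deg, truth.bend_sd_deg, truth.rho
    )
    twist_series = _ar1_series(
        rng, nf, truth.twist_mean_deg, truth.twist_sd_deg, truth.rho
    )
    mode_series = (
        _ar1_series(rng, nf, 0.0, truth.mode_sd, truth.rho)
        if truth.planted_mode is not None
        else None
    )
    if truth.planted_mode is not None and truth.planted_mode.shape != base.shape:
        raise ValueError("planted mode shape must match the atom array")

    # displacement that reliably opens a donor's H-bond (checked below)
    open_shift = 0.15
    pivot = base[aidx[(truth.hinge_residue - first, "CA")]]
    ref = np.cross(axis, [1.0, 0.0, 0.0])
    ref /= np.linalg.norm(ref)
    moving = np.array(
        [r > (truth.hinge_residue - first) for (r, _n) in atoms]
    )

    sigma = np.full(len(atoms), truth.jitter_nm)
    for res_number, s in truth.jitter_overrides.items():
        for j, (r, _n) in enumerate(atoms):
            if r == res_number - first:
                sigma[j] = s

    xyz = np.empty((nf, len(atoms), 3), dtype=np.float32)
    for f in range(nf):
        frame = base.copy()
        for i in donors:
            if open_states[i][f]:
                o = aidx[(i - 4, "O")]
                frame[o] = frame[o] + open_shift * radial_out(frame[o])
        for i in hydroxyls:
            oname = "OG1" if pep.sequence[i] == "T" else "OG"
            og, hg = aidx[(i, oname)], aidx[(i, "HG1")]
            if backbond_states[i][f]:
                acc = frame[aidx[(i - 4, "O")]]
                u = acc - frame[og]
                u /= np.linalg.norm(u)
                new_og = acc - 0.285 * u
                frame[og] = new_og
                frame[hg] = new_og + hb.B_OG_HG * u
        twist = twist_series[f]
        if abs(twist) > 1e-9:
            rot = hb.rotation_matrix(axis, twist)
            frame[moving] = (frame[moving] - pivot) @ rot.T + pivot
        angle = bend_series[f]
        if abs(angle) > 1e-9:
            bend_axis = hb.rotation_matrix(axis, truth.bend_direction_deg) @ ref
            rot = hb.rotation_matrix(bend_axis, angle)
            frame[moving] = (frame[moving] - pivot) @ rot.T + pivot
        if mode_series is not None:
            frame = frame + mode_series[f] * truth.planted_mode
        frame = frame + rng.normal(0.0, 1.0, frame.shape) * sigma[:, None]
        xyz[f] = frame

    traj = md.Trajectory(
        xyz=xyz, topology=top,
        time=np.arange(nf) * truth.frame_interval_ps,
    )
    htraj = HelixTrajectory(traj=traj, frame_interval_ps=truth.frame_interval_ps)

    # verify the opening displacement actually violates the criterion
    from .trajectory_features import hbond_closed

    probe = [i for i in donors if truth.open_probabilities.get(first + i, 0) > 0]
    if probe and truth.bend_mean_deg == 0 and truth.bend_sd_deg == 0:
        i = probe[0]
        frames_open = np.flatnonzero(open_states[i])
        if frames_open.size:
            closed = hbond_closed(htraj, first + i, 4, frames=frames_open[:10])
            if closed.any():
                raise ValueError(
                    "opening displacement too small to break the H-bond criterion"
                )

    record = {
        "peptide": pep.name,
        "n_frames": nf,
        "frame_interval_ps": truth.frame_interval_ps,
        "hinge_residue": truth.hinge_residue,
        "bend_mean_deg": truth.bend_mean_deg,
        "bend_sd_deg": truth.bend_sd_deg,
        "bend_direction_deg": truth.bend_direction_deg,
        "twist_mean_deg": truth.twist_mean_deg,
        "twist_sd_deg": truth.twist_sd_deg,
        "rho": truth.rho,
        "seed": truth.seed,
        "open_probabilities": {
            int(k): float(v) for k, v in truth.open_probabilities.items()
        },
        "backbond_occupancy": truth.backbond_occupancy,
        "bend_series_deg": bend_series.tolist(),
        "planted_open_fraction": {
            int(first + i): float(open_states[i].mean()) for i in donors
        },
        "mode_series": None if mode_series is None else mode_series.tolist(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        traj[0].save_pdb(str(out / "topology.pdb"))
        if coordinate_format == "xtc":
            traj.save_xtc(str(out / "trajectory.xtc"))
        elif coordinate_format == "dcd":
            traj.save_dcd(str(out / "trajectory.dcd"))
        else:
            raise ValueError(f"unknown coordinate format {coordinate_format!r}")
        slim = {k: v for k, v in record.items() if k != "bend_series_deg"}
        slim["bend_series_mean_deg"] = float(np.mean(bend_series))
        (out / "truth.json").write_text(json.dumps(slim, indent=1))
    return htraj, record
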
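"""Segment-axis geometry of a bent helix.

Bending (theta) and swivel (Phi) angles describe the orientation of the
C-terminal helix segment (default I47-M51, carrying the epsilon-cleavage
sites) relative to the N-terminal segment (default I31-M35, centred on
G33 of the GxxxG motif).  The swivel angle is measured about the
N-segment axis from a reference vector anchored at the G33 CA - an
arbitrary but fixed convention.  Additional operations: local
rise-per-residue, K-means clustering of the angle distribution,
free-energy surfaces from angle probabilities, and a simplified
hinge-motion classification in the DynDom spirit (rotation-axis
decomposition between quasi-rigid segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from ._helix_builder import helix_axis_direction
from ._rate_tables import R_KCAL
from .trajectory import HelixTrajectory

__all__ = [
    "SegmentDefinition",
    "BendSwivelSeries",
    "HingeClassification",
    "fit_segment_axis",
    "bend_swivel",
    "rise_per_residue",
    "cluster_angles",
    "angle_free_energy",
    "classify_hinge_motion",
]


@dataclass(frozen=True)
class SegmentDefinition:
    """Two disjoint quasi-rigid helix segments (C99 numbering)."""

    tm_n_range: tuple = (31, 35)
    tm_c_range: tuple = (47, 51)
    swivel_anchor: int = 33  # CA fixing the Phi = 0 reference

    def __post_init__(self):
        for lo, hi in (self.tm_n_range, self.tm_c_range):
            if hi - lo + 1 < 4:
                raise ValueError("each segment needs >= 4 residues")
        n = set(range(*self.tm_n_range)) | {self.tm_n_range[1]}
        c = set(range(*self.tm_c_range)) | {self.tm_c_range[1]}
        if n & c:
            raise ValueError("segments must be disjoint")

    def residues_n(self):
        return list(range(self.tm_n_range[0], self.tm_n_range[1] + 1))

    def residues_c(self):
        return list(range(self.tm_c_range[0], self.tm_c_range[1] + 1))


@dataclass
class BendSwivelSeries:
    """Per-frame bending theta [0, 180] and swivel Phi (-180, 180] in
    degrees; excluded frames carry NaN."""

    theta: np.ndarray
    phi: np.ndarray
    n_excluded: int = 0


@dataclass
class HingeClassification:
    motion_type: str  # B, T, BB, BT, TB, TT or "none"
    hinge_residues: list = field(default_factory=list)
    percent_closure: list = field(default_factory=list)
    rotation_angle_deg: float = 0.0


def fit_segment_axis(ca_coords) -> tuple[np.ndarray, np.ndarray]:
    """Unit helix axis (oriented N->C) and centroid of one segment's CA
    run.  Wraps the rotation-fit axis construction, which is exact on
    ideal helices."""
    ca = np.asarray(ca_coords, dtype=float)
    axis = helix_axis_direction(ca)
    return axis, ca.mean(axis=0)


def bend_swivel(
    traj: HelixTrajectory, segments: SegmentDefinition = SegmentDefinition()
) -> BendSwivelSeries:
    """Bending and swivel angle series between the two segments.

    theta is the angle between segment axes.  Phi is the azimuth of the
    C-segment axis about the N-segment axis, measured from the component
    of (CA(anchor) - N-segment centroid) perpendicular to the N axis;
    positive sense right-handed about the N axis.  Frames whose axis fit
    fails are excluded (NaN) and counted.
    """
    ca_n = traj.ca_coords(segments.residues_n())
    ca_c = traj.ca_coords(segments.residues_c())
    anchor = traj.coords(segments.swivel_anchor, "CA")
    nf = traj.n_frames
    theta = np.full(nf, np.nan)
    phi = np.full(nf, np.nan)
    excluded = 0
    for f in range(nf):
        try:
            ax_n, cen_n = fit_segment_axis(ca_n[f])
            ax_c, _ = fit_segment_axis(ca_c[f])
        except ValueError:
            excluded += 1
            continue
        cosb = np.clip(np.dot(ax_n, ax_c), -1.0, 1.0)
        theta[f] = np.degrees(np.arccos(cosb))
        ref = anchor[f] - cen_n
        ref -= np.dot(ref, ax_n) * ax_n
        nrm = np.linalg.norm(ref)
        if nrm < 1e-9:
            excluded += 1
            theta[f] = np.nan
            continue
        ref /= nrm
        w = np.cross(ax_n, ref)
        q = ax_c - np.dot(ax_c, ax_n) * ax_n
        phi[f] = np.degrees(np.arctan2(np.dot(q, w), np.dot(q, ref)))
    return BendSwivelSeries(theta=theta, phi=phi, n_excluded=excluded)


def rise_per_residue(
    traj: HelixTrajectory, position: int, window: int = 3
) -> np.ndarray:
    """Per-frame rise (nm) of the CA(i)->CA(i+1) step, projected onto
    the local helix axis fitted over i-window+1..i+window residues."""
    numbers = traj.residue_numbers
    lo = max(numbers[0], position - window + 1)
    hi = min(numbers[-1], position + window)
    local = [n for n in numbers if lo <= n <= hi]
    if position not in numbers or position + 1 not in numbers:
        raise ValueError(f"position {position} or successor not in trajectory")
    if len(local) < 4:
        raise ValueError("axis window truncated below 4 residues at terminus")
    ca_local = traj.ca_coords(local)
    step = traj.coords(position + 1, "CA") - traj.coords(position, "CA")
    rise = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        axis, _ = fit_segment_axis(ca_local[f])
        rise[f] = np.dot(step[f], axis)
    return rise


def cluster_angles(
    series: BendSwivelSeries, k: int, seed: int = 0
) -> dict:
    """K-means clustering of (theta, Phi) on the planar embedding
    (theta cos Phi, theta sin Phi), which respects swivel periodicity.

    Returns centroids mapped back to angle space, member counts and the
    frame index nearest each centroid.
    """
    ok = np.isfinite(series.theta) & np.isfinite(series.phi)
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        raise ValueError("no valid frames to cluster")
    if k < 1 or k > idx.size:
        raise ValueError(f"k={k} outside [1, {idx.size}]")
    phi_r = np.radians(series.phi[idx])
    x = np.column_stack(
        [series.theta[idx] * np.cos(phi_r), series.theta[idx] * np.sin(phi_r)]
    )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    centroids = []
    representative = []
    counts = []
    for c in range(k):
        cx, cy = km.cluster_centers_[c]
        centroids.append(
            (float(np.hypot(cx, cy)), float(np.degrees(np.arctan2(cy, cx))))
        )
        members = np.flatnonzero(km.labels_ == c)
        counts.append(int(members.size))
        d = np.linalg.norm(x[members] - km.cluster_centers_[c], axis=1)
        representative.append(int(idx[members[np.argmin(d)]]))
    return {
        "centroids_theta_phi": centroids,
        "counts": counts,
        "representative_frames": representative,
        "labels": km.labels_,
        "frame_indices": idx,
    }


def angle_free_energy(
    series: BendSwivelSeries,
    temperature: float = 293.0,
    theta_bins=None,
    phi_bins=None,
) -> dict:
    """2-D free-energy surface G(theta, Phi) = -RT ln p, min-shifted to
    zero; empty bins are NaN (undefined), never infinite."""
    ok = np.isfinite(series.theta) & np.isfinite(series.phi)
    theta_bins = theta_bins if theta_bins is not None else np.arange(0, 62, 2.0)
    phi_bins = phi_bins if phi_bins is not None else np.arange(-180, 190, 10.0)
    hist, te, pe = np.histogram2d(
        series.theta[ok], series.phi[ok], bins=[theta_bins, phi_bins]
    )
    p = hist / hist.sum()
    rt = R_KCAL * temperature
    with np.errstate(divide="ignore"):
        g = -rt * np.log(p)
    g[p == 0] = np.nan
    g -= np.nanmin(g)
    return {"free_energy": g, "theta_edges": te, "phi_edges": pe,
            "probability": p}


def _rigid_transform(a, b):
    """Rotation R, translation t with b ~ a @ R.T + t (least squares)."""
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (a - ca).T @ (b - cb)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, cb - rot @ ca


def _rotation_axis_angle(rot):
    angle = np.degrees(
        np.arccos(np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0))
    )
    w, v = np.linalg.eig(rot)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    return axis / np.linalg.norm(axis), angle


def classify_hinge_motion(
    traj_a: HelixTrajectory,
    traj_b: HelixTrajectory,
    segments: SegmentDefinition = SegmentDefinition(),
    frame_a: int = 0,
    frame_b: int = 0,
    min_angle_deg: float = 2.0,
    closure_threshold: float = 50.0,
) -> HingeClassification:
    """Simplified DynDom-concept classification of the motion between two
    conformations.

    After superposing conformation B onto A on the N segment, the
    rotation taking A's C segment onto B's is decomposed: percent closure
    = 100 sin^2 of the angle between the rotation axis and the
    inter-segment axis.  Closure > ``closure_threshold`` labels the
    motion B (bending), otherwise T (twisting).  Hinge residues are the
    contiguous inter-segment positions whose local deformation exceeds
    the rigid-segment baseline; two disjoint deformed regions yield a
    double-hinge label (each hinge classified from the rotation between
    the segments flanking it).
    """
    numbers = [n for n in traj_a.residue_numbers if n in traj_b.residue_numbers]
    a = traj_a.ca_coords(numbers)[frame_a]
    b = traj_b.ca_coords(numbers)[frame_b]
    seg_n = [numbers.index(n) for n in segments.residues_n()]
    seg_c = [numbers.index(n) for n in segments.residues_c()]

    rot, t = _rigid_transform(b[seg_n], a[seg_n])
    b_al = b @ rot.T + t

    def rotation_between(idx):
        r, _ = _rigid_transform(a[idx], b_al[idx])
        return _rotation_axis_angle(r)

    axis_rot, angle = rotation_between(seg_c)
    if angle < min_angle_deg:
        return HingeClassification(motion_type="none", rotation_angle_deg=angle)

    inter = a[seg_c].mean(axis=0) - a[seg_n].mean(axis=0)
    inter /= np.linalg.norm(inter)

    def closure(axis):
        c = 100.0 * (1.0 - np.dot(axis, inter) ** 2)
        return float(c)

    # local deformation: residual of a 5-residue window after its own
    # rigid fit; rigid-segment windows set the baseline
    def window_residual(center):
        lo = max(0, center - 2)
        hi = min(len(numbers), center + 3)
        idx = list(range(lo, hi))
        r, tt = _rigid_transform(a[idx], b_al[idx])
        return float(
            np.sqrt(np.mean(np.sum((a[idx] @ r.T + tt - b_al[idx]) ** 2, -1)))
        )

    resid = np.array([window_residual(i) for i in range(len(numbers))])
    baseline = max(resid[seg_n + seg_c].max() * 3.0, 1e-4)
    between = list(range(seg_n[-1] + 1, seg_c[0]))
    deformed = [i for i in between if resid[i] > baseline]

    regions = []
    for i in deformed:
        if regions and i == regions[-1][-1] + 1:
            regions[-1].append(i)
        else:
            regions.append([i])

    pc = closure(axis_rot)
    if len(regions) <= 1:
        label = "B" if pc > closure_threshold else "T"
        hinge = [numbers[i] for i in (regions[0] if regions else between)]
        return HingeClassification(
            motion_type=label, hinge_residues=hinge,
            percent_closure=[pc], rotation_angle_deg=angle,
        )
    # double hinge: classify each joint from the rotation of the segment
    # just C-terminal of it relative to the segment just N-terminal
    labels = []
    closures = []
    hinges = []
    boundaries = [seg_n] + [
        list(range(regions[i][-1] + 1, regions[i + 1][0]))
        for i in range(len(regions) - 1)
    ] + [seg_c]
    for j, region in enumerate(regions[:2]):
        before, after = boundaries[j], boundaries[j + 1]
        if len(before) < 3 or len(after) < 3:
            labels.append("B" if pc > closure_threshold else "T")
            closures.append(pc)
        else:
            r_before, _ = _rigid_transform(b_al[before], a[before])
            moved = b_al @ r_before.T  # into 'before' frame
            r, _ = _rigid_transform(a[after], moved[after] + (
                a[before].mean(0) - moved[before].mean(0)))
            axis_j, ang_j = _rotation_axis_angle(r)
            inter_j = a[after].mean(axis=0) - a[before].mean(axis=0)
            inter_j /= np.linalg.norm(inter_j)
            cj = 100.0 * (1.0 - np.dot(axis_j, inter_j) ** 2)
            labels.append("B" if cj > closure_threshold else "T")
            closures.append(float(cj))
        hinges.append([numbers[i] for i in region])
    return HingeClassification(
        motion_type="".join(labels), hinge_residues=hinges,
        percent_closure=closures, rotation_angle_deg=angle,
    )
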
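import numpy as np
import pytest

from helixdx.chem_rates import ExchangeConditions, compute_intrinsic_rates
from helixdx.exchange_kinetics import OverallExchangeCurve, reconstruct_overall
from helixdx.peptides import A26_55_WT, A26_55_I45T
from helixdx.synthetic_data import (
    TrajectoryTruth,
    gen_helix_trajectory,
    static_conformation_trajectory,
)
from helixdx.trajectory_features import (
    _closed_geometry,
    backbonding_occupancy,
    hbond_closed,
    md_to_dhx,
    msf_profile,
    occupancy_profile,
    packing_scores,
)


# ------------------------------------------------------- closure criterion


def test_constructed_geometries():
    n = np.array([0.101, 0.0, 0.0])
    h = np.zeros(3)
    o_close = np.array([-0.20, 0.0, 0.0])  # linear O...H-N, 0.20 nm
    assert _closed_geometry(o_close, h, n)
    o_boundary = np.array([-0.26, 0.0, 0.0])
    assert not _closed_geometry(o_boundary, h, n)  # strict inequality
    # 0.20 nm but bent 70 degrees past linear -> open
    ang = np.radians(180 - 70)
    o_bent = 0.20 * np.array([np.cos(ang), np.sin(ang), 0.0])
    assert not _closed_geometry(o_bent, h, n)
    # exactly 60 degrees from linear is inclusive
    ang = np.radians(180 - 60)
    o_edge = 0.20 * np.array([np.cos(ang), np.sin(ang), 0.0])
    assert _closed_geometry(o_edge, h, n)


def test_ideal_helix_alpha_closed_310_open():
    traj = static_conformation_trajectory(A26_55_WT, n_frames=3)
    prof = occupancy_profile(traj)
    assert np.allclose(prof.alpha, 1.0)
    assert np.allclose(prof.three_ten, 0.0)
    assert np.allclose(prof.helix, 1.0)
    # donors without an i-4 partner inside the peptide are skipped
    skipped = {r for r, _ in prof.skipped}
    assert skipped == {26, 27, 28, 29}


def test_extended_chain_all_open():
    traj = static_conformation_trajectory(A26_55_WT, n_frames=2,
                                          phi=-180.0, psi=180.0)
    prof = occupancy_profile(traj)
    assert np.allclose(prof.helix, 0.0)


def test_brute_force_agreement_on_random_frames(straight_open_traj):
    """Every donor/offset pair on 100 frames, against a plain-math
    checker independent of the vectorized path."""
    import math

    traj, _ = straight_open_traj
    frames = np.arange(0, traj.n_frames, traj.n_frames // 100)[:100]
    residues = traj.residue_numbers
    for res in residues:
        for off in (3, 4):
            try:
                fast = hbond_closed(traj, res, off, frames=frames)
            except KeyError:
                continue
            for fi, f in enumerate(frames):
                o = traj.coords(res - off, "O")[f]
                h = traj.coords(res, "H")[f]
                n = traj.coords(res, "N")[f]
                d = math.dist(o, h)
                vo = o - h
                vn = n - h
                cosang = float(np.dot(vo, vn)
                               / (np.linalg.norm(vo) * np.linalg.norm(vn)))
                ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                slow = (d < 0.26) and (ang >= 120.0)
                assert slow == fast[fi]


def test_bad_offset_and_missing_atoms():
    traj = static_conformation_trajectory(A26_55_WT)
    with pytest.raises(ValueError, match="offset"):
        hbond_closed(traj, 40, 2)
    with pytest.raises(KeyError):
        hbond_closed(traj, 26, 4)  # acceptor would sit in the acetyl cap


# ----------------------------------------------------------- occupancies


def test_planted_open_probability_recovered(straight_open_traj):
    traj, record = straight_open_traj
    prof = occupancy_profile(traj)
    planted = record["planted_open_fraction"]
    for i, res in enumerate(prof.residue_numbers):
        if res in planted:
            assert abs(prof.helix[i] - (1.0 - planted[res])) < 0.01


def test_occupancy_convergence_rate():
    """Monte-Carlo error of occupancies shrinks roughly as 1/sqrt(n)."""

    def rms_err(n_frames, seed):
        truth = TrajectoryTruth(
            n_frames=n_frames, bend_mean_deg=0.0, bend_sd_deg=0.0, rho=0.0,
            seed=seed,
        )
        traj, rec = gen_helix_trajectory(truth)
        prof = occupancy_profile(traj)
        errs = [
            prof.helix[i] - (1.0 - truth.open_probabilities[res])
            for i, res in enumerate(prof.residue_numbers)
            if truth.open_probabilities.get(res, 0) > 0
        ]
        return np.sqrt(np.mean(np.square(errs)))

    e500 = np.mean([rms_err(500, s) for s in range(3)])
    e5000 = np.mean([rms_err(5000, 10 + s) for s in range(3)])
    assert 1.5 < e500 / e5000 < 6.0  # ~sqrt(10) = 3.2 expected


def test_occupancy_ci_attached_with_blocks(straight_open_traj):
    traj, _ = straight_open_traj
    prof = occupancy_profile(traj, block_frames=100, n_boot=200, seed=0)
    lo, hi = prof.ci["helix"]
    assert np.all(lo <= prof.helix + 1e-9)
    assert np.all(prof.helix <= hi + 1e-9)


# ----------------------------------------------------------- back-bonding


def test_backbond_occupancy_planted(straight_open_traj):
    traj, record = straight_open_traj
    occ = backbonding_occupancy(traj, [43, 48])
    for res in (43, 48):
        assert abs(occ[res][4] - record["backbond_occupancy"]) < 0.02
        assert occ[res][3] < 0.05


def test_backbond_absent_when_rotated_away():
    truth = TrajectoryTruth(
        n_frames=100, bend_mean_deg=0.0, bend_sd_deg=0.0, rho=0.0,
        open_probabilities={}, backbond_occupancy=0.0, seed=3,
    )
    traj, _ = gen_helix_trajectory(truth)
    occ = backbonding_occupancy(traj, [43])
    assert occ[43][4] == 0.0


def test_backbond_rejects_non_hydroxyl():
    traj = static_conformation_trajectory(A26_55_WT)
    with pytest.raises(ValueError, match="no hydroxyl"):
        backbonding_occupancy(traj, [45])  # I45 in WT


# --------------------------------------------------------------- packing


def test_switching_function_limits():
    from helixdx.trajectory_features import _switching

    d = np.array([0.10, 0.30, 0.349, 0.425, 0.50, 0.80])
    w = _switching(d)
    assert w[0] == w[1] == w[2] == 1.0
    assert 0.0 < w[3] < 1.0
    assert w[4] == 0.0 and w[5] == 0.0


def test_backbond_raises_packing_at_acceptor():
    """The planted Thr back-bond packs the hydroxyl against the i-4
    carbonyl, so S_i at the acceptor rises relative to the same helix
    without the back-bond."""
    common = dict(n_frames=100, bend_mean_deg=0.0, bend_sd_deg=0.0, rho=0.0,
                  open_probabilities={}, jitter_nm=0.001)
    with_bb, _ = gen_helix_trajectory(
        TrajectoryTruth(backbond_occupancy=1.0, seed=4, **common)
    )
    without_bb, _ = gen_helix_trajectory(
        TrajectoryTruth(backbond_occupancy=0.0, seed=4, **common)
    )
    s_with = packing_scores(with_bb)
    s_without = packing_scores(without_bb)
    for acceptor in (39, 44):  # O(43-4), O(48-4)
        i = list(s_with.residue_numbers).index(acceptor)
        assert s_with.scores[i] > s_without.scores[i] + 0.3


def test_i45t_adds_packing_peak_at_41():
    """The mutant's extra T45 back-bond packs onto the I41 carbonyl."""
    common = dict(n_frames=50, bend_mean_deg=0.0, bend_sd_deg=0.0, rho=0.0,
                  open_probabilities={}, jitter_nm=0.001,
                  backbond_occupancy=1.0, seed=5)
    wt, _ = gen_helix_trajectory(TrajectoryTruth(peptide=A26_55_WT, **common))
    mut, _ = gen_helix_trajectory(
        TrajectoryTruth(peptide=A26_55_I45T, **common)
    )
    s_wt = packing_scores(wt)
    s_mut = packing_scores(mut)
    i41 = list(s_wt.residue_numbers).index(41)
    assert s_mut.scores[i41] > s_wt.scores[i41] + 0.3


# ------------------------------------------------------------------ MSF


def test_static_trajectory_msf_zero_and_normalization_undefined():
    traj = static_conformation_trajectory(A26_55_WT, n_frames=40)
    prof = msf_profile(traj, block_frames=20)
    assert np.allclose(prof.msf, 0.0, atol=1e-10)
    assert prof.normalized is None


def test_rigid_body_motion_removed_by_superposition():
    from helixdx._helix_builder import rotation_matrix

    base = static_conformation_trajectory(A26_55_WT, n_frames=40)
    xyz = base.traj.xyz.copy()
    rng = np.random.default_rng(0)
    for f in range(xyz.shape[0]):
        rot = rotation_matrix(rng.normal(size=3), rng.uniform(0, 180))
        xyz[f] = xyz[f] @ rot.T + rng.normal(size=3)
    base.traj.xyz = xyz
    prof = msf_profile(base, block_frames=20)
    assert np.all(prof.msf < 1e-10)


def test_high_variance_residue_tops_normalized_profile():
    truth = TrajectoryTruth(
        n_frames=400, bend_mean_deg=0.0, bend_sd_deg=0.0, rho=0.0,
        open_probabilities={}, jitter_nm=0.002,
        jitter_overrides={37: 0.02}, seed=6,
    )
    traj, _ = gen_helix_trajectory(truth)
    prof = msf_profile(traj, block_frames=100)
    top = prof.residue_numbers[int(np.argmax(prof.normalized))]
    assert top == 37
    assert abs(prof.normalized.mean()) < 1e-9
    assert abs(prof.normalized.var() - 1.0) < 1e-9


def test_msf_needs_two_blocks():
    traj = static_conformation_trajectory(A26_55_WT, n_frames=10)
    with pytest.raises(ValueError, match="two blocks"):
        msf_profile(traj, block_frames=10)


# --------------------------------------------------------------- MD->DHX


@pytest.fixture(scope="module")
def chem_profile():
    return compute_intrinsic_rates(
        A26_55_WT, ExchangeConditions(ph=5.0, direction="DHX")
    )


def test_open_limit_reduces_to_chemical_reconstruction(chem_profile):
    traj = static_conformation_trajectory(A26_55_WT, n_frames=5,
                                          phi=-180.0, psi=180.0)
    occ = occupancy_profile(traj)  # all open
    times = np.geomspace(1e-4, 10.0, 20)
    from helixdx.exchange_kinetics import ResidueRateProfile

    common = np.intersect1d(occ.residue_numbers, chem_profile.residue_numbers)
    k = np.array([chem_profile.rate_at(r) for r in common])
    expected = reconstruct_overall(
        ResidueRateProfile(residue_numbers=common, k_exp=k,
                           standard_error=np.zeros(k.size)),
        times,
    )
    exp_curve = OverallExchangeCurve(
        times=times, remaining_deuterons=expected.remaining_deuterons
    )
    fit = md_to_dhx(occ, chem_profile, exp_curve)
    assert abs(fit.f - 1.0) < 1e-3
    assert abs(fit.t0) < 1e-3
    assert fit.chi2 < 1e-10


def test_self_consistency_roundtrip(straight_open_traj, chem_profile):
    traj, _ = straight_open_traj
    occ = occupancy_profile(traj)
    common = [
        r for r in occ.residue_numbers if r in chem_profile.residue_numbers
    ]
    k = np.array([
        chem_profile.rate_at(r)
        * (1 - occ.helix[list(occ.residue_numbers).index(r)])
        for r in common
    ])
    times = np.geomspace(0.1, 10080, 25)
    d = (0.95 * np.exp(-np.outer(k, times)) + 0.05).sum(axis=0)
    fit = md_to_dhx(occ, chem_profile,
                    OverallExchangeCurve(times=times, remaining_deuterons=d))
    assert abs(fit.f - 1.0) < 0.01
    assert abs(fit.t0) < 0.1
    assert fit.chi2 < 1e-6


def test_scale_degeneracy_documented(chem_profile, straight_open_traj):
    """Doubling chemical rates and halving f leaves the curve unchanged."""
    traj, _ = straight_open_traj
    occ = occupancy_profile(traj)
    times = np.geomspace(0.1, 10080, 25)
    common = [
        r for r in occ.residue_numbers if r in chem_profile.residue_numbers
    ]
    k = np.array([
        chem_profile.rate_at(r)
        * (1 - occ.helix[list(occ.residue_numbers).index(r)])
        for r in common
    ])
    d1 = (0.95 * np.exp(-np.outer(2 * k, 0.5 * times)) + 0.05).sum(axis=0)
    d2 = (0.95 * np.exp(-np.outer(k, times)) + 0.05).sum(axis=0)
    assert np.allclose(d1, d2)


def test_all_closed_against_decaying_curve_rejected(chem_profile):
    traj = static_conformation_trajectory(A26_55_WT, n_frames=5)
    occ = occupancy_profile(traj)  # all closed -> zero rates
    times = np.geomspace(0.1, 100, 10)
    decaying = OverallExchangeCurve(
        times=times, remaining_deuterons=np.linspace(25, 3, 10)
    )
    with pytest.raises(ValueError, match="closed"):
        md_to_dhx(occ, chem_profile, decaying)
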
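import numpy as np
import pytest
from hypothesis import given, strategies as st

from helixdx._rate_tables import R_KCAL
from helixdx.chem_rates import ExchangeConditions, compute_intrinsic_rates
from helixdx.exchange_kinetics import (
    FragmentIonSeries,
    OverallExchangeCurve,
    ResidueRateProfile,
    delta_g,
    fit_rate_profile,
    fit_site_rate,
    isotope_ratio_profile,
    map_ph_time,
    overall_curve_from_centroids,
    reconstruct_overall,
    residue_content_from_fragments,
    superpose_scale,
)
from helixdx.peptides import A26_55_WT, A28_55_WT
from helixdx.synthetic_data import (
    ExchangeTruth,
    ASSAY_TIME_GRID_MIN,
    gen_exchange_dataset,
    step_delta_g_profile,
)

RT = R_KCAL * 293.15


# ------------------------------------------------------------ curves


def test_centroid_arithmetic_identity_and_inversion():
    t = np.array([0.0, 1.0, 10.0])
    flat = overall_curve_from_centroids([3000.0] * 3, t, all_h_mass=3000.0)
    assert np.allclose(flat.remaining_deuterons, 0.0)
    d_true = np.array([25.0, 12.0, 1.5])
    curve = overall_curve_from_centroids(
        3000.0 + 1.00628 * d_true, t, all_h_mass=3000.0
    )
    assert np.allclose(curve.remaining_deuterons, d_true, atol=1e-9)


def test_centroid_plateau_anchoring():
    t = np.array([1.0, 10.0, 1e6, 2e6])
    n_amides = 28
    # raw plateau off by a miscalibration factor of 1.2
    d_raw = np.array([20.0, 10.0, 0.05 * n_amides, 0.05 * n_amides]) * 1.2
    curve = overall_curve_from_centroids(
        3000.0 + 1.00628 * d_raw, t, all_h_mass=3000.0, n_amides=n_amides,
        anchor_plateau=True,
    )
    assert np.isclose(curve.remaining_deuterons[-1], 0.05 * n_amides)


def test_centroid_below_reference_rejected():
    with pytest.raises(ValueError, match="negative content"):
        overall_curve_from_centroids([2999.0], [1.0], all_h_mass=3000.0)


def test_constant_increment_ladder_gives_constant_content():
    t = np.array([1.0, 10.0, 100.0])
    d = 0.4
    frags = [
        FragmentIonSeries("c", n, t, np.full(3, (n + 1) * d))
        for n in range(1, 30)
    ]
    contents = residue_content_from_fragments(frags, A28_55_WT)
    assert np.allclose(contents.content, d)


def test_noiseless_fragments_invert_exactly(exchange_dataset):
    pep, truth, _, _, record = exchange_dataset
    clean = ExchangeTruth(delta_g=truth.delta_g, noise_sd=0.0, n_replicates=1,
                          seed=0)
    frags, _, rec = gen_exchange_dataset(clean, pep)
    contents = residue_content_from_fragments(frags, pep)
    for i, res in enumerate(contents.residue_numbers):
        k = rec["k_exp"][str(res)] if str(res) in rec["k_exp"] else rec["k_exp"][res]
        expected = 0.95 * np.exp(-k * contents.times) + 0.05
        assert np.allclose(contents.content[i], expected, atol=1e-9)


def test_noisy_recovery_rmse_over_seeds():
    pep = A28_55_WT
    dg = step_delta_g_profile(pep)
    errs = []
    probe_times = slice(3, 9)
    for seed in range(100):
        truth = ExchangeTruth(delta_g=dg, noise_sd=0.05, n_replicates=3,
                              seed=seed)
        frags, _, rec = gen_exchange_dataset(truth, pep)
        contents = residue_content_from_fragments(frags, pep)
        for i, res in enumerate(contents.residue_numbers):
            k = rec["k_exp"][res]
            y = 0.95 * np.exp(-k * contents.times) + 0.05
            errs.append(contents.content[i, probe_times] - y[probe_times])
    rmse = np.sqrt(np.mean(np.concatenate(errs) ** 2))
    assert rmse < 0.05


# ------------------------------------------------------------ pH mapping


def test_ph_time_mapping_rules():
    assert np.isclose(map_ph_time(10.0, 4.0, 5.0), 1.0)
    assert np.isclose(map_ph_time(7 * 1440.0, 6.45, 5.0),
                      7 * 1440.0 * 10 ** 1.45)
    assert np.isclose(map_ph_time(42.0, 5.0, 5.0), 42.0)


def test_ph_time_mapping_requires_base_dominance():
    with pytest.raises(ValueError, match="base catalysis"):
        map_ph_time(10.0, 3.0, 5.0, peptide=A26_55_WT)


# ------------------------------------------------------------ site fits


def test_site_fit_roundtrip_noiseless():
    t = ASSAY_TIME_GRID_MIN
    k_true = 0.01
    y = 0.95 * np.exp(-k_true * t) + 0.05
    k, se, resid = fit_site_rate(t, y)
    assert abs(k - k_true) / k_true < 1e-6
    assert resid < 1e-9


def test_site_fit_rejects_floor_and_short_series():
    t = ASSAY_TIME_GRID_MIN
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_site_rate(t, np.full(t.size, 0.05))
    with pytest.raises(ValueError, match="4 points"):
        fit_site_rate([1.0, 2.0, 3.0], [1.0, 0.9, 0.8])


# ------------------------------------------------------------ free energy


def _rates(numbers, k, se=None):
    k = np.asarray(k, dtype=float)
    return ResidueRateProfile(
        residue_numbers=np.asarray(numbers, int),
        k_exp=k,
        standard_error=np.asarray(se, float) if se is not None
        else np.full(k.size, np.nan),
    )


def test_delta_g_symmetry_point_and_closed_form():
    chem = compute_intrinsic_rates(A26_55_WT, ExchangeConditions(ph=5.0))
    res = chem.residue_numbers[:2]
    kch = np.array([chem.rate_at(r) for r in res])
    prof = delta_g(_rates(res, kch / 2), chem, n_mc=10)
    assert np.allclose(prof.delta_g, 0.0, atol=1e-12)
    prof2 = delta_g(_rates(res, kch / 1001.0), chem, n_mc=10)
    expected = -RT * np.log(1.0 / 1000.0)
    assert np.allclose(prof2.delta_g, expected, rtol=1e-12)
    assert 4.0 < expected < 4.05  # ~4.02 kcal/mol


def test_delta_g_undefined_when_kexp_exceeds_kch():
    chem = compute_intrinsic_rates(A26_55_WT, ExchangeConditions(ph=5.0))
    res = chem.residue_numbers[:3]
    kch = np.array([chem.rate_at(r) for r in res])
    prof = delta_g(_rates(res, kch * np.array([2.0, 1.0, 0.5])), chem, n_mc=10)
    assert not np.isfinite(prof.delta_g[0]) and int(res[0]) in prof.flags
    assert not np.isfinite(prof.delta_g[1])
    assert np.isfinite(prof.delta_g[2])


@given(x=st.floats(min_value=0.01, max_value=0.97))
def test_delta_g_monotone_decreasing_in_kexp(x):
    kch = 3.0
    g1 = -RT * np.log((x * kch) / (kch - x * kch))
    g2 = -RT * np.log(((x + 0.02) * kch) / (kch - (x + 0.02) * kch))
    assert g2 < g1


# ------------------------------------------------------------ overall


def test_reconstruct_overall_identities():
    t = np.geomspace(0.01, 1000, 30)
    rates = _rates([1, 2, 3], [0.1, 0.1, 0.1])
    curve = reconstruct_overall(rates, t)
    assert np.allclose(
        curve.remaining_deuterons, 3 * (0.95 * np.exp(-0.1 * t) + 0.05)
    )
    d0 = reconstruct_overall(rates, np.array([0.0, 1.0]))
    assert np.isclose(d0.remaining_deuterons[0], 3.0)


def test_reconstruct_requires_bounds_for_undefined():
    rates = _rates([1, 2], [0.1, np.nan])
    with pytest.raises(ValueError, match="undefined"):
        reconstruct_overall(rates, np.array([1.0, 2.0]))
    curve = reconstruct_overall(rates, np.array([1.0, 2.0]),
                                undefined_rate=1e-9)
    assert curve.remaining_deuterons.size == 2


def test_superpose_scale_identity_and_construction():
    t = np.geomspace(0.1, 1e4, 40)
    chem = compute_intrinsic_rates(A26_55_WT, ExchangeConditions(ph=5.0))
    k = np.array([chem.rate_at(r) for r in chem.residue_numbers]) * 1e-3
    fast = reconstruct_overall(_rates(chem.residue_numbers, k), t)
    slow = reconstruct_overall(_rates(chem.residue_numbers, 0.2 * k), t)
    assert abs(superpose_scale(fast, fast)[0] - 1.0) < 1e-3
    s, _ = superpose_scale(fast, slow)
    assert abs(s - 0.2) < 0.01


def test_isotope_ratio_tracks_chemical_ratio():
    from helixdx.chem_rates import hdx_dhx_chemical_ratio

    chem_d = compute_intrinsic_rates(
        A26_55_WT, ExchangeConditions(ph=5.0, direction="DHX")
    )
    chem_h = compute_intrinsic_rates(
        A26_55_WT,
        ExchangeConditions(ph=5.0, direction="HDX", pd_correction=0.4),
    )
    dg = step_delta_g_profile(A26_55_WT)
    open_frac = {n: 1.0 / (1.0 + np.exp(dg[n] / RT)) for n in dg}
    kd = [chem_d.rate_at(n) * open_frac[n] for n in chem_d.residue_numbers]
    kh = [chem_h.rate_at(n) * open_frac[n] for n in chem_h.residue_numbers]
    prof = isotope_ratio_profile(
        _rates(chem_d.residue_numbers, kd), _rates(chem_h.residue_numbers, kh),
        n_mc=10,
    )
    _, chem_mean = hdx_dhx_chemical_ratio(A26_55_WT)
    assert np.isclose(np.nanmean(prof.ratio), chem_mean, rtol=0.02)
    equal = isotope_ratio_profile(
        _rates([1, 2], [0.1, 0.2]), _rates([1, 2], [0.1, 0.2]), n_mc=10
    )
    assert np.allclose(equal.ratio, 1.0)


def test_isotope_ratio_flags_undefined_instead_of_nan_propagating():
    prof = isotope_ratio_profile(
        _rates([1, 2], [0.1, np.nan]), _rates([1, 2], [0.1, 0.2]), n_mc=10
    )
    assert 2 in prof.flags and np.isfinite(prof.ratio[0])


# ------------------------------------------------------- full round trip


def test_full_roundtrip_recovers_truth(exchange_dataset):
    """Generator -> files -> readers -> differencing -> site fits -> dG
    recovers the planted step profile; reconstructed kinetics agree with
    the directly generated curve beyond the fastest decade."""
    import warnings

    pep, truth, fragments, overall, record = exchange_dataset
    contents = residue_content_from_fragments(fragments, pep)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rates = fit_rate_profile(contents)
    chem = compute_intrinsic_rates(pep, truth.conditions)
    prof = delta_g(rates, chem, n_mc=300, seed=1)
    errors = [
        abs(prof.delta_g[i] - truth.delta_g[int(res)])
        for i, res in enumerate(prof.residue_numbers)
        if np.isfinite(prof.delta_g[i])
    ]
    assert len(errors) >= 20
    assert np.mean(errors) < 0.15

    recon = reconstruct_overall(rates, overall.times, undefined_rate=1e-9)
    truth_rates = _rates(
        sorted(int(k) for k in record["k_exp"]),
        [record["k_exp"][k] for k in sorted(record["k_exp"], key=int)],
    )
    direct = reconstruct_overall(truth_rates, overall.times)
    beyond = overall.times > 10 * overall.times[0]
    assert np.max(
        np.abs(recon.remaining_deuterons[beyond]
               - direct.remaining_deuterons[beyond])
    ) < 1.0


def test_curve_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        OverallExchangeCurve(times=[1.0, 1.0], remaining_deuterons=[1, 1])
    with pytest.raises(ValueError, match="negative"):
        OverallExchangeCurve(times=[1.0, 2.0], remaining_deuterons=[1, -2])
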
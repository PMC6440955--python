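"""Residue-resolved amide exchange kinetics and EX2 free energies.

Measured (or synthetic) deuterium exchange series are reduced in stages:

1. overall remaining-deuteron curves from centroid masses;
2. per-residue deuteron content from ETD c/z fragment-ion ladders
   (adjacent-fragment differencing);
3. single-exponential site fits y(t) = 0.95 exp(-k t) + 0.05, whose
   amplitude/baseline encode the 5% residual deuterated solvent;
4. Linderstroem-Lang EX2 free energies
   dG = -RT ln(k_exp / (k_ch - k_exp)), defined only where the observed
   rate is below the intrinsic chemical rate.

All profiles are indexed by C99 residue number.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .chem_rates import (
    ExchangeConditions,
    IntrinsicRateProfile,
    base_catalysis_fraction,
    compute_intrinsic_rates,
)
from .peptides import PeptideSpec
from .stats_boot import mc_propagate
from ._rate_tables import R_KCAL

__all__ = [
    "OverallExchangeCurve",
    "FragmentIonSeries",
    "ResidueContentSeries",
    "ResidueRateProfile",
    "DeltaGProfile",
    "IsotopeRatioProfile",
    "overall_curve_from_centroids",
    "residue_content_from_fragments",
    "map_ph_time",
    "fit_site_rate",
    "fit_rate_profile",
    "delta_g",
    "reconstruct_overall",
    "superpose_scale",
    "isotope_ratio_profile",
]

AMPLITUDE = 0.95
BASELINE = 0.05


@dataclass
class OverallExchangeCurve:
    """Remaining deuterons vs incubation time (minutes)."""

    times: np.ndarray
    remaining_deuterons: np.ndarray
    sem: np.ndarray | None = None
    n_replicates: int = 1

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.remaining_deuterons = np.asarray(self.remaining_deuterons, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.remaining_deuterons < -1e-9):
            raise ValueError("negative deuteron content")


@dataclass
class FragmentIonSeries:
    """Deuteron content of one ETD fragment ion over time."""

    ion_type: str  # "c" or "z"
    fragment_length: int
    times: np.ndarray
    deuterons: np.ndarray
    replicate_id: int = 0

    def __post_init__(self):
        if self.ion_type not in ("c", "z"):
            raise ValueError(f"ion_type must be 'c' or 'z', got {self.ion_type!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.deuterons = np.asarray(self.deuterons, dtype=float)


@dataclass
class ResidueContentSeries:
    """Per-residue deuteron fraction vs time, with uncertainty."""

    residue_numbers: np.ndarray
    times: np.ndarray
    content: np.ndarray  # (n_residues, n_times)
    se: np.ndarray  # same shape
    coverage: dict = field(default_factory=dict)  # residue -> ladder sources


@dataclass
class ResidueRateProfile:
    """Fitted per-residue exchange rate constants (1/min)."""

    residue_numbers: np.ndarray
    k_exp: np.ndarray  # nan where undefined
    standard_error: np.ndarray
    direction: str = "DHX"
    flags: dict = field(default_factory=dict)  # residue -> reason

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.k_exp)


@dataclass
class DeltaGProfile:
    """EX2 H-bond opening free energies (kcal/mol)."""

    residue_numbers: np.ndarray
    delta_g: np.ndarray  # nan where undefined
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    temperature: float
    gas_constant: float = R_KCAL
    flags: dict = field(default_factory=dict)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.delta_g)


@dataclass
class IsotopeRatioProfile:
    """Per-residue k_exp,HDX / k_exp,DHX with propagated errors."""

    residue_numbers: np.ndarray
    ratio: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------- curves


def overall_curve_from_centroids(
    centroid_masses,
    times,
    all_h_mass: float,
    per_deuteron_shift: float = 1.00628,
    n_amides: int | None = None,
    residual_label_fraction: float = BASELINE,
    anchor_plateau: bool = False,
) -> OverallExchangeCurve:
    """Remaining-deuteron curve from centroid masses.

    D(t) = (centroid(t) - all_H_mass) / per_deuteron_shift.  With
    ``anchor_plateau`` the curve is rescaled multiplicatively so that its
    terminal level (mean of the last two points) equals the theoretical
    equilibrium ``residual_label_fraction * n_amides`` set by the
    deuterated-solvent carry-over of the 1:20 dilution.
    """
    centroids = np.asarray(centroid_masses, dtype=float)
    d = (centroids - all_h_mass) / per_deuteron_shift
    if np.any(d < -1e-9):
        raise ValueError("centroid below the all-H reference: negative content")
    if anchor_plateau:
        if n_amides is None:
            raise ValueError("anchor_plateau requires n_amides")
        plateau = d[-2:].mean()
        if plateau <= 0:
            raise ValueError("cannot anchor plateau: terminal content <= 0")
        d = d * (residual_label_fraction * n_amides / plateau)
    return OverallExchangeCurve(times=np.asarray(times, float), remaining_deuterons=d)


def _amides_covered(ion_type, length, peptide):
    """Amide positions (C99 numbers) whose deuterons a fragment carries.

    A c_n ion keeps the backbone amides of residues 2..n+1 (the amide N-H
    of residue n+1 travels with the c ion); a z_m ion keeps the amides of
    the last m-1 residues.  Residue 1's amide exists only for a blocked
    N-terminus and is carried by every c ion.
    """
    first, last = peptide.first_residue_number, peptide.last_residue_number
    observable = set(peptide.amide_residue_numbers())
    if ion_type == "c":
        covered = set(range(first, first + length + 1))
    else:
        covered = set(range(last - length + 2, last + 1))
    return covered & observable


def residue_content_from_fragments(
    fragments, peptide: PeptideSpec, consistency_tol: float = 0.2
) -> ResidueContentSeries:
    """Per-residue deuteron content by adjacent-fragment differencing.

    The deuteron difference c_n - c_(n-1) is assigned to the backbone
    amide of residue n+1; z ladders are differenced independently and,
    where both ladders resolve a residue, the two estimates are combined
    with inverse-variance weights.  Replicates are averaged first; the
    replicate scatter provides the variance for weighting.
    """
    by_key: dict = {}
    times = None
    for f in fragments:
        if times is None:
            times = f.times
        elif not np.array_equal(times, f.times):
            raise ValueError("all fragment series must share one time grid")
        by_key.setdefault((f.ion_type, f.fragment_length), []).append(f.deuterons)
    if times is None:
        raise ValueError("no fragments supplied")

    stats = {}
    for key, reps in by_key.items():
        arr = np.stack(reps)
        mean = arr.mean(axis=0)
        # replicate SEM; a floor avoids zero-variance degeneracies
        if arr.shape[0] > 1:
            se = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
        else:
            se = np.full_like(mean, np.nan)
        stats[key] = (mean, se)

    estimates: dict = {}
    for ion in ("c", "z"):
        lengths = sorted(l for (t, l) in stats if t == ion)
        for l0, l1 in zip(lengths, lengths[1:]):
            if l1 - l0 != 1:
                continue  # ladder gap: no single-residue difference
            covered0 = _amides_covered(ion, l0, peptide)
            covered1 = _amides_covered(ion, l1, peptide)
            diff_res = covered1 - covered0
            if len(diff_res) != 1:
                continue
            res = diff_res.pop()
            m1, s1 = stats[(ion, l1)]
            m0, s0 = stats[(ion, l0)]
            content = m1 - m0
            se = np.sqrt(np.nan_to_num(s1, nan=0.0) ** 2
                         + np.nan_to_num(s0, nan=0.0) ** 2)
            estimates.setdefault(res, []).append((ion, content, se))

    residues = np.array(sorted(estimates), dtype=int)
    n_t = times.size
    content = np.full((residues.size, n_t), np.nan)
    se_out = np.full((residues.size, n_t), np.nan)
    coverage = {}
    se_floor = 1e-3
    for i, res in enumerate(residues):
        entries = estimates[res]
        coverage[int(res)] = sorted({ion for ion, _, _ in entries})
        if len(entries) == 1:
            _, c, s = entries[0]
            content[i], se_out[i] = c, s
        else:
            cs = np.stack([c for _, c, _ in entries])
            ws = 1.0 / (np.stack([s for _, _, s in entries]) ** 2 + se_floor**2)
            spread = np.abs(cs.max(axis=0) - cs.min(axis=0))
            if np.any(spread > consistency_tol):
                warnings.warn(
                    f"residue {res}: c/z ladder estimates differ by up to "
                    f"{spread.max():.3f} D (tol {consistency_tol}); both retained",
                    stacklevel=2,
                )
            content[i] = (cs * ws).sum(axis=0) / ws.sum(axis=0)
            se_out[i] = 1.0 / np.sqrt(ws.sum(axis=0))
    return ResidueContentSeries(
        residue_numbers=residues, times=times, content=content, se=se_out,
        coverage=coverage,
    )


def map_ph_time(
    t,
    ph_actual: float,
    ph_reference: float,
    peptide: PeptideSpec | None = None,
    temperature: float = 293.15,
    direction: str = "DHX",
) -> np.ndarray:
    """Equivalent incubation time at a reference pH.

    Under base-dominated catalysis the rate scales as 10^pH, so incubating
    for t at ph_actual is equivalent to t * 10^(ph_actual - ph_reference)
    at the reference.  If a peptide is given, base-catalysis dominance
    (>= 95% at both pH values) is verified first.
    """
    if peptide is not None:
        for ph in (ph_actual, ph_reference):
            prof = compute_intrinsic_rates(
                peptide,
                ExchangeConditions(ph=ph, temperature=temperature,
                                   direction=direction),
            )
            if base_catalysis_fraction(prof).min() < 0.95:
                raise ValueError(
                    f"base catalysis not dominant at pH {ph}; "
                    "map each catalysis component separately"
                )
    return np.asarray(t, dtype=float) * 10.0 ** (ph_actual - ph_reference)


# ---------------------------------------------------------------- fitting


def _site_model(t, k):
    return AMPLITUDE * np.exp(-k * t) + BASELINE


def fit_site_rate(times, content, se=None):
    """Fit y(t) = 0.95 exp(-k t) + 0.05 for one residue.

    Weighted least squares (inverse-variance when replicate errors are
    available).  Returns (k, standard_error, residual_norm).

    Raises
    ------
    ValueError
        For unidentifiable data (at the 0.05 floor throughout, or fewer
        than 4 points / less than a decade of time span).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(content, dtype=float)
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if se is not None:
        se = np.asarray(se, dtype=float)[ok]
        if not np.all(np.isfinite(se)) or np.any(se <= 0):
            se = None
    tpos = t[t > 0]
    if t.size < 4 or tpos.size < 2 or tpos.max() / tpos.min() < 10:
        raise ValueError("need >= 4 points spanning at least a decade of time")
    if np.all(np.abs(y - BASELINE) < 0.02):
        raise ValueError("content at the residual floor: rate unidentifiable")

    # initial k from the time where y first drops below the half-amplitude
    below = np.flatnonzero(y < BASELINE + AMPLITUDE / 2)
    k0 = np.log(2.0) / t[below[0]] if below.size and t[below[0]] > 0 else 1.0 / t[-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            popt, pcov = curve_fit(
                _site_model, t, y, p0=[k0], sigma=se,
                absolute_sigma=se is not None,
                bounds=(0.0, np.inf), maxfev=10_000,
            )
        except RuntimeError as err:
            raise ValueError(f"site fit did not converge: {err}") from None
    k = float(popt[0])
    k_se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    resid = float(np.linalg.norm(_site_model(t, k) - y))
    return k, k_se, resid


def fit_rate_profile(
    contents: ResidueContentSeries, direction: str = "DHX"
) -> ResidueRateProfile:
    """Site fits for every covered residue; failures are flagged, never
    silently defaulted."""
    n = contents.residue_numbers.size
    k = np.full(n, np.nan)
    se = np.full(n, np.nan)
    flags = {}
    for i, res in enumerate(contents.residue_numbers):
        try:
            k[i], se[i], _ = fit_site_rate(
                contents.times, contents.content[i], contents.se[i]
            )
        except ValueError as err:
            flags[int(res)] = str(err)
    return ResidueRateProfile(
        residue_numbers=contents.residue_numbers.copy(),
        k_exp=k, standard_error=se, direction=direction, flags=flags,
    )


# ---------------------------------------------------------------- energetics


def delta_g(
    rates: ResidueRateProfile,
    chem: IntrinsicRateProfile,
    temperature: float = 293.15,
    n_mc: int = 10_000,
    seed: int | None = 0,
    lower_bound_se_factor: float = 2.0,
) -> DeltaGProfile:
    """Linderstroem-Lang EX2 free energies with Monte-Carlo intervals.

    dG = -RT ln(k_exp / (k_ch - k_exp)) where k_exp < k_ch.  Positions
    with k_exp >= k_ch are flagged undefined; positions within
    ``lower_bound_se_factor`` standard errors of k_ch are flagged as
    lower bounds (the point estimate is still reported).
    """
    common = np.intersect1d(rates.residue_numbers, chem.residue_numbers)
    if common.size == 0:
        raise ValueError("rate and chemical profiles share no residues")
    rt = R_KCAL * temperature
    n = common.size
    dg = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    flags = {}
    for i, res in enumerate(common):
        ir = int(np.flatnonzero(rates.residue_numbers == res)[0])
        kexp, kse = rates.k_exp[ir], rates.standard_error[ir]
        kch = chem.rate_at(res)
        if not np.isfinite(kexp):
            flags[int(res)] = rates.flags.get(int(res), "rate undefined")
            continue
        if kexp >= kch:
            flags[int(res)] = (
                f"k_exp ({kexp:.3g}) >= k_ch ({kch:.3g}): EX2 dG undefined"
            )
            continue
        dg[i] = -rt * np.log(kexp / (kch - kexp))
        if np.isfinite(kse) and kse > 0:
            res_mc = mc_propagate(
                lambda k, kch=kch: -rt * np.log(k / (kch - k)) if 0 < k < kch
                else np.nan,
                [kexp], [kse], n=n_mc, seed=seed,
            )
            lo[i], hi[i] = res_mc.ci_lower, res_mc.ci_upper
            if kexp + lower_bound_se_factor * kse >= kch:
                flags[int(res)] = "lower bound: k_exp within 2 SE of k_ch"
    return DeltaGProfile(
        residue_numbers=common, delta_g=dg, ci_lower=lo, ci_upper=hi,
        temperature=temperature, flags=flags,
    )


def reconstruct_overall(
    rates: ResidueRateProfile,
    times,
    undefined_rate: float | None = None,
) -> OverallExchangeCurve:
    """Overall kinetics summed from site rates:
    D(t) = sum_i [0.95 exp(-k_i t) + 0.05].

    Residues with undefined rates contribute via ``undefined_rate`` if
    given, otherwise raise.
    """
    t = np.asarray(times, dtype=float)
    k = rates.k_exp.copy()
    if np.any(~np.isfinite(k)):
        if undefined_rate is None:
            raise ValueError(
                f"rates undefined at residues "
                f"{rates.residue_numbers[~np.isfinite(k)].tolist()}; "
                "supply undefined_rate bounds"
            )
        k[~np.isfinite(k)] = undefined_rate
    d = (AMPLITUDE * np.exp(-np.outer(k, t)) + BASELINE).sum(axis=0)
    return OverallExchangeCurve(times=t, remaining_deuterons=d)


def superpose_scale(
    curve_a: OverallExchangeCurve,
    curve_b: OverallExchangeCurve,
    n_grid: int = 200,
) -> tuple[float, float]:
    """Time-axis scale s minimizing sum_t [D_a(t) - D_b(t/s)]^2.

    Curves are compared on a logarithmic time grid spanning the shared
    positive time range; both curves are interpolated in log time.
    Returns (s, residual).
    """
    ta = curve_a.times[curve_a.times > 0]
    tb = curve_b.times[curve_b.times > 0]
    if ta.size < 2 or tb.size < 2:
        raise ValueError("need positive time ranges in both curves")

    def interp(curve, t):
        src = curve.times[curve.times > 0]
        vals = curve.remaining_deuterons[curve.times > 0]
        return np.interp(np.log(t), np.log(src), vals)

    def objective(log_s):
        s = np.exp(log_s)
        lo = max(ta.min(), tb.min() * s)
        hi = min(ta.max(), tb.max() * s)
        if hi <= lo:
            return 1e12
        grid = np.geomspace(lo, hi, n_grid)
        return float(np.mean((interp(curve_a, grid) - interp(curve_b, grid / s)) ** 2))

    if objective(0.0) >= 1e12:
        raise ValueError("curves have non-overlapping time ranges")
    res = minimize_scalar(objective, bounds=(-np.log(1e4), np.log(1e4)),
                          method="bounded", options={"xatol": 1e-6})
    return float(np.exp(res.x)), float(res.fun)


def isotope_ratio_profile(
    dhx: ResidueRateProfile,
    hdx: ResidueRateProfile,
    n_mc: int = 10_000,
    seed: int | None = 0,
) -> IsotopeRatioProfile:
    """Per-residue k_exp,HDX / k_exp,DHX with Monte-Carlo errors."""
    common = np.intersect1d(dhx.residue_numbers, hdx.residue_numbers)
    n = common.size
    ratio = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    flags = {}
    for i, res in enumerate(common):
        id_ = int(np.flatnonzero(dhx.residue_numbers == res)[0])
        ih = int(np.flatnonzero(hdx.residue_numbers == res)[0])
        kd, kh = dhx.k_exp[id_], hdx.k_exp[ih]
        if not (np.isfinite(kd) and np.isfinite(kh)):
            flags[int(res)] = "one or both rates undefined"
            continue
        ratio[i] = kh / kd
        sed, seh = dhx.standard_error[id_], hdx.standard_error[ih]
        if np.isfinite(sed) and np.isfinite(seh):
            res_mc = mc_propagate(
                lambda x: x[1] / x[0] if x[0] > 0 else np.nan,
                [kd, kh], [sed, seh], n=n_mc, seed=seed,
            )
            lo[i], hi[i] = res_mc.ci_lower, res_mc.ci_upper
    return IsotopeRatioProfile(
        residue_numbers=common, ratio=ratio, ci_lower=lo, ci_upper=hi, flags=flags
    )
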
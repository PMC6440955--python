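"""Sequence-based intrinsic (chemical) amide exchange rate constants.

For a fully solvent-exposed backbone amide, the exchange rate constant is
the sum of acid-, base- and water-catalysed contributions,

    k_ch = k_A * [L3O+] + k_B * [OL-] + k_W            (L = H or D)

with poly-DL-alanine reference constants modified by nearest-neighbour
side-chain factors (Bai-style left/right corrections) and Arrhenius
temperature scaling per term.  Two directions are supported:

* ``DHX`` - deuterated amide exchanging into protonated solvent (H2O);
* ``HDX`` - protonated amide exchanging into deuterated solvent (D2O).

The pH argument is the instrument-read value.  For D2O solvent the true
pD exceeds the glass-electrode reading by ~0.4 units; this correction is
opt-in (``pd_correction``) per the operational-pH convention used for the
underlying measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _rate_tables as tables
from .peptides import PeptideSpec

__all__ = [
    "ExchangeConditions",
    "IntrinsicRateProfile",
    "compute_intrinsic_rates",
    "base_catalysis_fraction",
    "hdx_dhx_chemical_ratio",
]

PH_RANGE = (2.0, 9.0)


@dataclass(frozen=True)
class ExchangeConditions:
    """Solution conditions of an exchange experiment."""

    ph: float = 5.0
    temperature: float = 293.15  # K
    direction: str = "DHX"
    residual_label_fraction: float = 0.05
    dilution_factor: float = 20.0
    pd_correction: float = 0.0  # add to ph for D2O solvent (0.4 is standard)
    reduced_cys: bool = True

    def __post_init__(self):
        if self.direction not in ("DHX", "HDX"):
            raise ValueError(f"direction must be DHX or HDX, got {self.direction!r}")
        if not 0.0 <= self.residual_label_fraction < 1.0:
            raise ValueError("residual_label_fraction must be in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def operational_ph(self) -> float:
        """pH/pD on the concentration scale used by the rate law."""
        return self.ph + (self.pd_correction if self.direction == "HDX" else 0.0)


@dataclass
class IntrinsicRateProfile:
    """Per-residue chemical exchange rates with catalysis components.

    Rates are in 1/min, indexed by C99 residue number (one entry per
    observable backbone amide).
    """

    peptide_name: str
    residue_numbers: np.ndarray  # int, C99 numbering
    residues: list  # one-letter codes
    k_acid: np.ndarray
    k_base: np.ndarray
    k_water: np.ndarray
    conditions: ExchangeConditions = field(repr=False, default=None)

    @property
    def k_ch(self) -> np.ndarray:
        return self.k_acid + self.k_base + self.k_water

    def rate_at(self, residue_number: int) -> float:
        idx = np.flatnonzero(self.residue_numbers == residue_number)
        if idx.size == 0:
            raise KeyError(f"no amide at residue {residue_number}")
        return float(self.k_ch[idx[0]])


def _left_right_factors(peptide: PeptideSpec, number: int, ph: float):
    """Summed (acid, base) log10 factors for the amide of ``number``.

    The amide of residue i is corrected by its own side chain ("left"
    columns) and by the side chain of residue i-1 ("right" columns);
    terminal groups substitute for the missing neighbours.
    """
    al, _, bl, _ = tables.blended_factors(peptide.residue_at(number), ph)
    acid, base = al, bl
    if number > peptide.first_residue_number:
        _, ar, _, br = tables.blended_factors(peptide.residue_at(number - 1), ph)
        acid += ar
        base += br
    elif peptide.n_terminal == "free":
        acid += tables.NTERM_FREE["acid_right"]
        base += tables.NTERM_FREE["base_right"]
    # acetylated N-terminus: Ala-like neighbour, factor 0
    if number == peptide.last_residue_number and peptide.c_terminal == "free":
        f_dep = 1.0 / (1.0 + 10 ** (tables.CTERM_PKA - ph))
        acid += (
            f_dep * tables.CTERM_FREE["acid_left"]
            + (1 - f_dep) * tables.CTERM_FREE_PROTONATED_ACID_LEFT
        )
        base += tables.CTERM_FREE["base_left"]
    return acid, base


def compute_intrinsic_rates(
    peptide: PeptideSpec, conditions: ExchangeConditions
) -> IntrinsicRateProfile:
    """Intrinsic exchange rate constants for every observable amide.

    Raises
    ------
    ValueError
        If pH is outside the validated [2, 9] window or the sequence
        contains an unsupported residue.
    """
    ph = conditions.operational_ph
    if not PH_RANGE[0] <= ph <= PH_RANGE[1]:
        raise ValueError(f"pH {ph} outside validated range {PH_RANGE}")
    T = conditions.temperature
    ref = tables.REFERENCE_RATES[conditions.direction]
    lg_ka = tables.arrhenius(ref["lgkA"], tables.ACTIVATION_ENERGY["acid"], T)
    lg_kb = tables.arrhenius(ref["lgkB"], tables.ACTIVATION_ENERGY["base"], T)
    lg_kw = tables.arrhenius(ref["lgkW"], tables.ACTIVATION_ENERGY["water"], T)
    pk = tables.solvent_pk(conditions.direction, T)

    numbers = peptide.amide_residue_numbers()
    k_acid = np.empty(len(numbers))
    k_base = np.empty(len(numbers))
    k_water = np.empty(len(numbers))
    for j, n in enumerate(numbers):
        fa, fb = _left_right_factors(peptide, n, ph)
        k_acid[j] = 10 ** (lg_ka + fa - ph)
        k_base[j] = 10 ** (lg_kb + fb + ph - pk)
        k_water[j] = 10 ** (lg_kw + fb)
    return IntrinsicRateProfile(
        peptide_name=peptide.name,
        residue_numbers=np.array(numbers, dtype=int),
        residues=[peptide.residue_at(n) for n in numbers],
        k_acid=k_acid,
        k_base=k_base,
        k_water=k_water,
        conditions=conditions,
    )


def base_catalysis_fraction(profile: IntrinsicRateProfile) -> np.ndarray:
    """Per-residue fraction of the total rate carried by the OL- term."""
    total = profile.k_ch
    if np.any(total <= 0):
        raise ValueError("zero total rate; base fraction undefined")
    return profile.k_base / total


def hdx_dhx_chemical_ratio(
    peptide: PeptideSpec,
    ph: float = 5.0,
    temperature: float = 293.15,
    pd_correction: float = 0.4,
):
    """Per-residue k_ch,HDX / k_ch,DHX ratios and their sequence average.

    Both directions are evaluated at the same instrument pH reading; the
    D2O side is put on the pD scale with the standard glass-electrode
    offset (``pd_correction``, default +0.4), which is how the two
    experiments are actually matched.

    Returns
    -------
    (ratios, mean) : (ndarray, float)
    """
    dhx = compute_intrinsic_rates(
        peptide, ExchangeConditions(ph=ph, temperature=temperature, direction="DHX")
    )
    hdx = compute_intrinsic_rates(
        peptide,
        ExchangeConditions(
            ph=ph,
            temperature=temperature,
            direction="HDX",
            pd_correction=pd_correction,
        ),
    )
    ratios = hdx.k_ch / dhx.k_ch
    return ratios, float(np.mean(ratios))
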
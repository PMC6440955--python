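"""Reference parameters for intrinsic (chemical) amide exchange rates.

Transcription of the poly-DL-alanine reference rate constants and
side-chain (nearest-neighbour) correction factors of the SPHERE lineage:

* Bai, Milne, Mayne & Englander, Proteins 17, 75-86 (1993) - H-to-D
  reference rates, side-chain factors, activation energies.
* Connelly, Bai, Jeng & Englander, Proteins 17, 87-92 (1993) - D-to-H
  (back-exchange) reference rates.

All factors are log10 multipliers relative to poly-DL-alanine.  The
"left" factor of a residue applies to that residue's own backbone amide
(the NH sits to the left of the side chain in conventional N-to-C
drawing); the "right" factor applies to the amide of the following
residue.  The water-catalysis term is scaled with the base-catalysis
factors, following the Englander reference spreadsheet convention.

Reference temperature 293.15 K.  Rate units: k_A in 1/(M min), k_B in
1/(M min), k_W in 1/min.
"""

from __future__ import annotations

import numpy as np

T_REF = 293.15  # K
R_KCAL = 1.987204e-3  # kcal/(mol K)

# log10 reference rates for poly-DL-alanine at 293.15 K.
# DHX: deuterated amide exchanging into H2O (catalysts H3O+/OH-).
# HDX: protonated amide exchanging into D2O (catalysts D3O+/OD-).
REFERENCE_RATES = {
    "DHX": {"lgkA": 2.04, "lgkB": 10.36, "lgkW": -1.5},
    "HDX": {"lgkA": 1.62, "lgkB": 10.05, "lgkW": -1.5},
}

# Solvent autoionization constants (pK) at 293.15 K and van't Hoff
# ionization enthalpies (kcal/mol) for temperature adjustment.
SOLVENT_PK = {"DHX": 14.17, "HDX": 15.05}  # H2O / D2O at 20 C
SOLVENT_DH_ION = {"DHX": 13.34, "HDX": 14.30}

# Arrhenius activation energies (kcal/mol) per catalysis term.
ACTIVATION_ENERGY = {"acid": 14.0, "base": 17.0, "water": 19.0}

# Side-chain factors: residue -> (acid_left, acid_right, base_left, base_right).
# Ionizable residues carry charged-state variants resolved at run time from pH.
SIDE_CHAIN_FACTORS = {
    "A": (0.00, 0.00, 0.00, 0.00),
    "R": (-0.59, -0.32, 0.08, 0.22),
    "N": (-0.58, -0.13, 0.49, 0.32),
    "D-": (0.90, 0.58, 0.10, -0.18),
    "D0": (-0.90, -0.12, 0.69, 0.60),
    "C": (-0.54, -0.46, 0.62, 0.55),
    "G": (-0.22, 0.22, 0.27, 0.17),
    "Q": (-0.47, -0.27, 0.06, 0.20),
    "E-": (-0.90, 0.31, -0.11, -0.15),
    "E0": (-0.60, -0.27, 0.24, 0.39),
    "H+": (-0.80, -0.51, 0.80, 0.83),
    "H0": (0.00, 0.00, -0.10, 0.14),
    "I": (-0.91, -0.59, -0.73, -0.23),
    "L": (-0.57, -0.13, -0.58, -0.21),
    "K": (-0.56, -0.29, -0.04, 0.12),
    "M": (-0.64, -0.28, -0.01, 0.11),
    "F": (-0.52, -0.43, -0.24, 0.06),
    "P": (0.00, -0.19, 0.00, -0.24),
    "S": (-0.44, -0.39, 0.37, 0.30),
    "T": (-0.79, -0.47, -0.07, 0.20),
    "W": (-0.40, -0.44, -0.41, -0.11),
    "Y": (-0.41, -0.37, -0.27, 0.05),
    "V": (-0.74, -0.30, -0.70, -0.14),
}

# Approximate side-chain pKa values used to blend charged/neutral factors.
SIDE_CHAIN_PKA = {"D": 3.9, "E": 4.3, "H": 7.0}

# Terminal group factors.  A free protonated N-terminal amine strongly
# perturbs the amide of residue 2 (right factor); a free C-terminal
# carboxylate perturbs the last residue's own amide (left factor).
# Blocked termini (acetyl / carboxamide) are treated as Ala-like peptide
# neighbours, i.e. factor 0.
NTERM_FREE = {"acid_right": -1.32, "base_right": 1.62}
CTERM_FREE = {"acid_left": 0.96, "base_left": -1.80}
CTERM_FREE_PROTONATED_ACID_LEFT = 0.05
CTERM_PKA = 3.6


def blended_factors(residue: str, ph: float) -> tuple[float, float, float, float]:
    """Side-chain factors for one residue at a given pH.

    For Asp/Glu/His the charged- and neutral-state factors are mixed
    according to the Henderson-Hasselbalch charged fraction; all other
    residues are pH independent.
    """
    if residue in ("D", "E", "H"):
        pka = SIDE_CHAIN_PKA[residue]
        if residue == "H":
            f_charged = 1.0 / (1.0 + 10 ** (ph - pka))
            charged, neutral = SIDE_CHAIN_FACTORS["H+"], SIDE_CHAIN_FACTORS["H0"]
        else:
            f_charged = 1.0 / (1.0 + 10 ** (pka - ph))
            charged = SIDE_CHAIN_FACTORS[residue + "-"]
            neutral = SIDE_CHAIN_FACTORS[residue + "0"]
        return tuple(
            f_charged * c + (1.0 - f_charged) * n
            for c, n in zip(charged, neutral)
        )
    try:
        return SIDE_CHAIN_FACTORS[residue]
    except KeyError:
        raise ValueError(f"unsupported residue letter: {residue!r}") from None


def arrhenius(log10_k_ref: float, ea_kcal: float, temperature: float) -> float:
    """Scale a reference log10 rate from T_REF to ``temperature``."""
    return log10_k_ref - (ea_kcal / (R_KCAL * np.log(10))) * (
        1.0 / temperature - 1.0 / T_REF
    )


def solvent_pk(direction: str, temperature: float) -> float:
    """Autoionization pK of the exchange solvent at ``temperature``."""
    pk_ref = SOLVENT_PK[direction]
    dh = SOLVENT_DH_ION[direction]
    return pk_ref + (dh / (R_KCAL * np.log(10))) * (
        1.0 / temperature - 1.0 / T_REF
    )
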
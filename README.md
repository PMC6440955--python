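# helixdx

Backbone dynamics of a transmembrane helix, quantified from amide
exchange and from trajectories — built around the C99 fragment of the
amyloid precursor protein (residues 26–55, C99 numbering), whose
cleavage by γ-secretase depends on how flexibly the helix presents its
ε-cleavage sites. The package is for structural biophysicists who want
residue-resolved H-bond stabilities from deuterium/hydrogen exchange
mass spectrometry, the matching observables from MD trajectories, and a
quantitative bridge between the two.

## What it computes

**From exchange data.** Sequence-based intrinsic rates
k_ch = k_A[L₃O⁺] + k_B[OL⁻] + k_W (poly-DL-alanine reference constants
with Bai-style neighbour corrections, DHX and HDX directions),
residue-resolved rate constants from ETD c/z fragment ladders
(adjacent-fragment differencing, site fits y(t) = 0.95·e^(−kt) + 0.05),
and EX2 Linderstrøm-Lang free energies of H-bond opening

ΔG = −RT·ln( k_exp / (k_ch − k_exp) )

with Monte-Carlo confidence intervals, overall-curve reconstruction and
isotope-ratio profiles.

**From trajectories.** α/3₁₀/helix H-bond occupancies (O···H < 0.26 nm,
O···H–N within 60° of linear), Thr/Ser back-bonding, carbonyl packing
scores, block-averaged normalized Cα fluctuations, bend θ / swivel Φ
between helix segments I31–M35 and I47–M51, K-means conformer
clustering, angle free-energy surfaces, bending-vs-twisting hinge
classification, and PLS functional mode analysis (ewMCM) against a
summed H-bond order parameter.

**The bridge.** EX2 open-state rates k_i = k_ch,i·(1 − occupancy_i)
predict overall exchange kinetics, fitted to experiment with a time
scaling f and offset t₀ and scored by normalized χ².

**Synthetic data.** Generators with recorded ground truth emulate the
assay's inputs — multi-exponential EX2 exchange with a 5% residual
floor on the 13-point 0.1 min–7 d grid, and ideal-helix trajectories
with a planted hinge, per-residue H-bond open probabilities and AR(1)
frame correlation — so the full pipeline is testable without any
measured data. See `docs/methods.md` for models, conventions and
limitations.

## Worked example

```python
import numpy as np
from helixdx import (A26_55_WT, A28_55_WT, ExchangeConditions,
                     compute_intrinsic_rates, base_catalysis_fraction,
                     hdx_dhx_chemical_ratio)

prof = compute_intrinsic_rates(A26_55_WT, ExchangeConditions(ph=5.0, direction="DHX"))
print(f"k_ch at G33: {prof.rate_at(33):.2f} 1/min")
ratios, mean = hdx_dhx_chemical_ratio(A26_55_WT)
print(f"mean k_ch,HDX/k_ch,DHX: {mean:.3f}  (DHX faster {1/mean:.1f}-fold)")
p4 = compute_intrinsic_rates(A26_55_WT, ExchangeConditions(ph=4.0))
print(f"min base-catalysed fraction at pH 4: {100*base_catalysis_fraction(p4).min():.1f}%")

# synthetic exchange experiment -> residue-resolved dG recovery
from helixdx.synthetic_data import ExchangeTruth, gen_exchange_dataset, step_delta_g_profile
from helixdx.exchange_kinetics import (residue_content_from_fragments,
                                       fit_rate_profile, delta_g)
truth = ExchangeTruth(delta_g=step_delta_g_profile(A28_55_WT), seed=7)
frags, overall, rec = gen_exchange_dataset(truth, A28_55_WT)
rates = fit_rate_profile(residue_content_from_fragments(frags, A28_55_WT))
dg = delta_g(rates, compute_intrinsic_rates(A28_55_WT, truth.conditions), seed=1)
for r in (33, 38, 45, 49):
    i = list(dg.residue_numbers).index(r)
    print(f"residue {r}: dG = {dg.delta_g[i]:.2f} kcal/mol (truth {truth.delta_g[r]:.2f})")
```

prints

```
k_ch at G33: 17.02 1/min
mean k_ch,HDX/k_ch,DHX: 0.164  (DHX faster 6.1-fold)
min base-catalysed fraction at pH 4: 97.2%
residue 33: dG = 1.02 kcal/mol (truth 1.00)
residue 38: dG = 2.88 kcal/mol (truth 2.80)
residue 45: dG = 5.01 kcal/mol (truth 5.00)
residue 49: dG = 5.19 kcal/mol (truth 5.00)
```

The intrinsic-rate lines say that at pH 5 an exposed amide in the
Gly-rich helix half exchanges in seconds, that the deuterium-out
direction runs ~6-fold faster than hydrogen-in at matched meter
readings, and that above pH 4 essentially all exchange is
hydroxide-catalysed (which is what licenses mapping incubation times
across pH as t·10^ΔpH). The ΔG lines show the pipeline recovering a
planted stability profile — a flexible N-terminal half near 1 kcal/mol
against a rigid cleavage-site-bearing half at 5 kcal/mol — to ≈0.05
kcal/mol mean absolute error from noisy three-replicate fragment data.

A command-line interface mirrors the library:
`helixdx chemrates`, `fit-exchange`, `deltag`, `reconstruct`, `hbonds`,
`packing`, `msf`, `md2dhx`, `geometry`, `hinges`, `fma` and
`helixdx synth exchange|trajectory` (every run echoes its configuration
and seed into the output directory).

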
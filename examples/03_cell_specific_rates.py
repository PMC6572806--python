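"""From bulk reaction rates to per-cell metabolism and biomass turnover.

Dividing the modeled volumetric nitrification rate by the abundance of
ammonia-oxidizer marker genes gives the average substrate turnover of a single
cell, which converts to electrons per day (energy) and to carbon-specific
metabolic rate and turnover time (growth potential).
"""

import numpy as np

from sednit import (
    carbon_metabolic_rate,
    cell_specific_rate,
    copies_to_cell_density,
    detect_transition_zones,
    electron_normalize,
    electrons_per_day,
    generate_abundances,
    solve_steady_state,
)
from sednit.fluxes import DepthProfile
from sednit.io import northpond_like

spec = northpond_like()
sol = solve_steady_state(spec.column, spec.kinetics)
zones = detect_transition_zones(
    DepthProfile(sol.z, sol.concentrations["O2"], species="O2"))
abund = {a.marker: a for a in generate_abundances(spec, zones)}

depths = abund["amoA_AOA"].depth
copies = abund["amoA_AOA"].copies + abund["amoA_AOB"].copies
cells = copies_to_cell_density(copies, wet_bulk_density=1.7)
r4 = np.interp(depths, sol.z, sol.rates["R4"])

sub = cell_specific_rate(r4, cells)          # fmol NH4+ per cell per day
ele = electron_normalize(sub, "nitrification")  # 8 e- per NH4+ oxidized
ok = np.isfinite(ele) & (ele > 0)
print(f"cell-specific nitrification: 10^{np.log10(ele[ok]).min():.1f} to "
      f"10^{np.log10(ele[ok]).max():.1f} fmol e- cell-1 d-1 across {ok.sum()} depths")

electrons, order = electrons_per_day(1e-5)
print(f"at the basal power requirement (1e-5 fmol e-/cell/d) a cell transfers "
      f"{electrons:.3g} electrons per day — order 10^{order}")

met = carbon_metabolic_rate(0.01)  # 0.01 fmol NH4+/cell/d, 10 NH4 : 1 C, 14 fg C
print(f"a cell oxidizing 0.01 fmol NH4+/d fixes carbon at "
      f"{met.rate:.2e} gC (gC cell)-1 hr-1, turning its biomass over every "
      f"{met.turnover_yr:.1f} years")
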
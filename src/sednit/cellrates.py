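"""Cell-specific metabolic rates, electron-normalized power and biomass
turnover for subseafloor functional groups.

Volumetric reaction rates from the column model (mol m⁻³ sediment yr⁻¹) are
divided by cell densities derived from qPCR gene-copy abundances to give
per-cell substrate turnover (fmol cell⁻¹ d⁻¹), normalized to electrons
transferred, and converted into carbon-specific metabolic rates
(g C (g C cell)⁻¹ hr⁻¹) and biomass turnover times.  Because marker genes may
occur in multiple copies per genome, cell densities are upper bounds and the
derived cell-specific rates are minimum estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AVOGADRO = 6.02214076e23
DAYS_PER_YEAR = 365.25
CARBON_MOLAR_MASS = 12.011  # g/mol

#: Electrons transferred per mole of substrate for each process.
ELECTRONS_PER_SUBSTRATE: dict[str, float] = {
    "O2_respiration": 4.0,        # per mol O2
    "nitrification": 8.0,         # NH4+ -> NO3-, per mol NH4+
    "nitrification_aoa": 6.0,     # NH4+ -> NO2- (ammonia oxidation only)
    "denitrification": 5.0,       # NO3- -> N2, per mol NO3-
    "nitrate_reduction": 2.0,     # NO3- -> NO2-, per mol NO3-
}

MARKERS = ("16S_bac", "16S_arc", "amoA_AOA", "amoA_AOB", "nxrB", "narG", "nirK", "nirS")
QPCR_DETECTION_LIMIT = 1e2  # copies per g wet sediment

#: Which marker genes proxy each modeled process (config-overridable).
DEFAULT_GROUP_MARKERS: dict[str, tuple[str, ...]] = {
    "nitrification": ("amoA_AOA", "amoA_AOB"),
    "denitrification": ("nirK", "nirS"),
    "O2_respiration": ("16S_bac", "16S_arc"),
}


@dataclass
class AbundanceProfile:
    """qPCR gene-copy abundances for one marker along depth.

    ``copies`` per g wet sediment with standard deviation ``sd``;
    ``below_detection`` flags values at or below ~10² copies g⁻¹.
    """

    depth: np.ndarray
    marker: str
    copies: np.ndarray
    sd: np.ndarray | None = None
    below_detection: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.copies = np.asarray(self.copies, dtype=float)
        if np.any(self.copies < 0):
            raise ValueError("gene-copy abundances must be nonnegative")
        if self.below_detection is None:
            self.below_detection = self.copies <= QPCR_DETECTION_LIMIT
        else:
            self.below_detection = np.asarray(self.below_detection, dtype=bool)


@dataclass
class CellRate:
    depth: float
    process: str
    rate_substrate: float  # fmol substrate cell-1 d-1
    rate_electrons: float  # fmol e- cell-1 d-1
    flagged: bool = False


@dataclass
class MetabolicRate:
    rate: float  # g C (g C cell)-1 hr-1
    turnover_hr: float
    state: str | None = None

    @property
    def turnover_yr(self) -> float:
        return self.turnover_hr / (24.0 * DAYS_PER_YEAR)


def copies_to_cell_density(
    copies_per_g_wet: np.ndarray | float,
    wet_bulk_density: float = 1.7,
    copies_per_cell: float = 1.0,
) -> np.ndarray | float:
    """Convert copies per g wet sediment to cells per m³ of sediment.

    cells m⁻³ = copies g⁻¹ × ρ (g cm⁻³) × 10⁶ cm³ m⁻³ / copies-per-cell.
    With one copy per cell the result is an upper bound on the cell density.
    """
    if wet_bulk_density <= 0:
        raise ValueError("wet bulk density must be positive")
    if copies_per_cell < 1:
        raise ValueError("copies_per_cell must be >= 1")
    return np.asarray(copies_per_g_wet, dtype=float) * wet_bulk_density * 1e6 / copies_per_cell


def cell_specific_rate(
    volumetric_rate: np.ndarray | float,
    cell_density: np.ndarray | float,
) -> np.ndarray | float:
    """Per-cell substrate turnover, fmol cell⁻¹ d⁻¹, from a volumetric rate in
    mol m⁻³ yr⁻¹ and a cell density in cells m⁻³.  Zero density yields NaN
    (flagged missing), never infinity."""
    rate = np.asarray(volumetric_rate, dtype=float)
    dens = np.asarray(cell_density, dtype=float)
    out = np.full(np.broadcast(rate, dens).shape, np.nan)
    ok = dens > 0
    out[ok] = (rate / np.where(ok, dens, 1.0))[ok] / DAYS_PER_YEAR * 1e15
    if out.ndim == 0:
        return float(out)
    return out


def electron_normalize(rate_substrate: np.ndarray | float, process: str) -> np.ndarray | float:
    """Substrate rate × electrons transferred per mole of substrate."""
    try:
        ne = ELECTRONS_PER_SUBSTRATE[process]
    except KeyError:
        valid = ", ".join(sorted(ELECTRONS_PER_SUBSTRATE))
        raise ValueError(f"unknown process {process!r}; valid: {valid}") from None
    return np.asarray(rate_substrate, dtype=float) * ne


def electrons_per_day(rate_electrons: float) -> tuple[float, int | None]:
    """Absolute electrons transferred per cell per day and its order of
    magnitude (``floor(log10)``); a zero rate returns (0.0, None)."""
    if rate_electrons < 0:
        raise ValueError("electron rate must be nonnegative")
    electrons = rate_electrons * 1e-15 * AVOGADRO
    if electrons == 0:
        return 0.0, None
    return electrons, int(math.floor(math.log10(electrons)))


def carbon_metabolic_rate(
    rate_nh4: float,
    mol_nh4_per_mol_c: float = 10.0,
    cell_carbon_fg: float = 14.0,
) -> MetabolicRate:
    """Carbon-specific metabolic rate of a chemolithoautotrophic nitrifier.

    One mole of carbon is fixed per ``mol_nh4_per_mol_c`` moles of ammonium
    oxidized; each cell carries ``cell_carbon_fg`` fg of carbon.  Returns the
    rate in g C (g C cell)⁻¹ hr⁻¹ and the biomass turnover time (its inverse).
    A zero rate yields an infinite turnover, flagged by ``state='inactive'``.
    """
    if mol_nh4_per_mol_c <= 0 or cell_carbon_fg <= 0:
        raise ValueError("conversion parameters must be positive")
    if rate_nh4 < 0:
        raise ValueError("rate must be nonnegative")
    if rate_nh4 == 0:
        return MetabolicRate(0.0, math.inf, state="inactive")
    rate_gc = (rate_nh4 * 1e-15 / mol_nh4_per_mol_c) * CARBON_MOLAR_MASS \
        / (cell_carbon_fg * 1e-15) / 24.0
    return MetabolicRate(rate_gc, 1.0 / rate_gc)


@dataclass
class ThresholdCurves:
    """Metabolic-state threshold lines, log10(rate) = intercept + slope·T(°C).

    The survival and growth lines bound the maintenance regime; coefficients
    are user-supplied (e.g. digitized from published temperature-dependent
    survival/growth energy requirements).
    """

    survival: tuple[float, float]  # (intercept, slope)
    growth: tuple[float, float]

    def log_rate(self, which: str, temperature: float) -> float:
        a, b = getattr(self, which)
        return a + b * temperature


def classify_metabolic_state(
    rate: MetabolicRate,
    temperature: float,
    curves: ThresholdCurves | None,
) -> str | None:
    """Classify a carbon metabolic rate as survival / maintenance / growth.

    Boundaries are assigned upward: a rate exactly on the survival line counts
    as maintenance, exactly on the growth line as growth.  Without curves the
    state is omitted (None), never guessed.
    """
    if curves is None:
        return None
    if rate.rate <= 0:
        return "survival"
    lr = math.log10(rate.rate)
    if lr < curves.log_rate("survival", temperature):
        return "survival"
    if lr < curves.log_rate("growth", temperature):
        return "maintenance"
    return "growth"


def rates_table(
    volumetric: pd.DataFrame,
    abundances: list[AbundanceProfile],
    wet_bulk_density: float = 1.7,
    group_markers: dict[str, tuple[str, ...]] | None = None,
    temperature: float = 1.5,
    curves: ThresholdCurves | None = None,
    mol_nh4_per_mol_c: float = 10.0,
    cell_carbon_fg: float = 14.0,
) -> pd.DataFrame:
    """Full conversion pipeline on tabular inputs.

    ``volumetric`` must carry ``depth_m`` and rate columns named by process
    (``nitrification``, ``denitrification``, ``O2_respiration``) in
    mol m⁻³ yr⁻¹.  For each process the rate at each abundance depth is divided
    by the summed cell density of that group's marker genes.  Returns one row
    per (depth, process) with substrate, electron, carbon rates and turnover.
    """
    group_markers = group_markers or DEFAULT_GROUP_MARKERS
    by_marker = {a.marker: a for a in abundances}
    rows = []
    for process, markers in group_markers.items():
        if process not in volumetric.columns:
            continue
        present = [by_marker[m] for m in markers if m in by_marker]
        if not present:
            continue
        depths = present[0].depth
        copies = np.zeros_like(depths)
        flagged = np.zeros(depths.size, dtype=bool)
        for a in present:
            copies = copies + np.interp(depths, a.depth, a.copies)
            flagged |= np.asarray(a.below_detection, dtype=bool)
        dens = copies_to_cell_density(copies, wet_bulk_density)
        vol = np.interp(depths, volumetric["depth_m"], volumetric[process])
        sub = cell_specific_rate(vol, dens)
        ele = electron_normalize(sub, process)
        for i, d in enumerate(depths):
            row = {
                "depth_m": float(d),
                "process": process,
                "fmol_substrate_cell_d": float(sub[i]),
                "fmol_e_cell_d": float(ele[i]),
                "below_detection": bool(flagged[i]),
            }
            if process == "nitrification" and np.isfinite(sub[i]):
                met = carbon_metabolic_rate(float(sub[i]), mol_nh4_per_mol_c, cell_carbon_fg)
                row["gC_per_gC_hr"] = met.rate
                row["turnover_yr"] = met.turnover_yr
                row["state"] = classify_metabolic_state(met, temperature, curves)
            rows.append(row)
    return pd.DataFrame(rows)
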
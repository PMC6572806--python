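"""Table and configuration I/O plus the orchestrating pipeline.

All tabular formats are plain delimited text:

* depth profiles — CSV ``depth_m, species, value, unit[, sd, below_detection]``;
* solver output — CSV ``depth_m, <species...>, R1..R5``;
* abundances — CSV ``depth_m, marker, copies_per_g, sd, below_detection``;
* OTU tables — classic TSV (first column OTU id, one column per sample, last
  column taxonomy) with a companion sample-metadata CSV.

Configuration is a single YAML file mirroring :class:`ScenarioSpec`; every
package default appears explicitly in the shipped ``northpond_like.yaml``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cellrates import AbundanceProfile, rates_table
from .column_model import ColumnConfig, KineticParams, SolutionField, solve_steady_state
from .community import OtuTable, reappearance_fraction, richness_profile
from .fluxes import DepthProfile, RedoxZone, detect_transition_zones, fick_flux
from .synthetic_data import (
    AbundanceModel,
    CommunityModel,
    ScenarioSpec,
    default_zones,
    generate_abundances,
    generate_otu_table,
    generate_profiles,
)

log = logging.getLogger(__name__)

VALID_UNITS = {"uM", "µM", "mol m-3", "mmol m-2 yr-1"}
FLOAT_FORMAT = "%.10g"  # round-trip precision for all writers


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

def write_profiles(profiles: dict[str, DepthProfile] | list[DepthProfile],
                   path: str | Path) -> None:
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    frames = []
    for p in profiles:
        frames.append(pd.DataFrame({
            "depth_m": p.depth,
            "species": p.species,
            "value": p.value,
            "unit": p.unit,
            "below_detection": p.below_detection.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=FLOAT_FORMAT)


def read_profiles(path: str | Path) -> dict[str, DepthProfile]:
    df = pd.read_csv(path)
    required = {"depth_m", "species", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"profile file {path} lacks columns {sorted(missing)}")
    bad_units = df.loc[~df["unit"].isin(VALID_UNITS)]
    if len(bad_units):
        row = bad_units.index[0]
        raise ValueError(
            f"unknown unit {bad_units['unit'].iloc[0]!r} at row {row + 2} of {path}"
        )
    out = {}
    for sp, grp in df.groupby("species", sort=False):
        depths = grp["depth_m"].to_numpy(dtype=float)
        dup = np.flatnonzero(np.diff(depths) == 0)
        if dup.size:
            raise ValueError(
                f"duplicate (depth, species) for {sp} at row {grp.index[dup[0] + 1] + 2}"
            )
        if np.any(np.diff(depths) < 0):
            row = grp.index[int(np.flatnonzero(np.diff(depths) < 0)[0]) + 1]
            raise ValueError(f"non-increasing depth for {sp} at row {row + 2}")
        below = (grp["below_detection"].to_numpy(dtype=bool)
                 if "below_detection" in grp.columns
                 else np.zeros(len(grp), dtype=bool))
        out[str(sp)] = DepthProfile(depths, grp["value"].to_numpy(dtype=float),
                                    species=str(sp), unit=str(grp["unit"].iloc[0]),
                                    below_detection=below)
    return out


# ---------------------------------------------------------------------------
# solutions, abundances, zones, OTU tables
# ---------------------------------------------------------------------------

def write_solution(solution: SolutionField, path: str | Path) -> None:
    solution.to_frame().to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_solution(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_abundances(profiles: list[AbundanceProfile], path: str | Path) -> None:
    frames = []
    for a in profiles:
        frames.append(pd.DataFrame({
            "depth_m": a.depth,
            "marker": a.marker,
            "copies_per_g": a.copies,
            "sd": a.sd if a.sd is not None else np.nan,
            "below_detection": np.asarray(a.below_detection, dtype=int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format=FLOAT_FORMAT)


def read_abundances(path: str | Path) -> list[AbundanceProfile]:
    df = pd.read_csv(path)
    out = []
    for marker, grp in df.groupby("marker", sort=False):
        out.append(AbundanceProfile(
            grp["depth_m"].to_numpy(dtype=float),
            str(marker),
            grp["copies_per_g"].to_numpy(dtype=float),
            sd=grp["sd"].to_numpy(dtype=float) if "sd" in grp.columns else None,
            below_detection=grp["below_detection"].to_numpy(dtype=bool)
            if "below_detection" in grp.columns else None,
        ))
    return out


def write_zones(zones: list[RedoxZone], path: str | Path, site: str = "synthetic") -> None:
    pd.DataFrame(
        [{"site": site, "kind": z.kind, "top_m": z.top, "bottom_m": z.bottom}
         for z in zones]
    ).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_zones(path: str | Path) -> list[RedoxZone]:
    df = pd.read_csv(path)
    return [RedoxZone(r.kind, r.top_m, r.bottom_m) for r in df.itertuples()]


def write_otu_table(table: OtuTable, counts_path: str | Path,
                    metadata_path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(len(out.columns), "taxonomy", table.taxonomy)
    out.index.name = "OTU_ID"
    out.to_csv(counts_path, sep="\t")
    table.metadata.rename_axis("sample").to_csv(metadata_path,
                                                float_format=FLOAT_FORMAT)


def read_otu_table(counts_path: str | Path, metadata_path: str | Path) -> OtuTable:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "taxonomy" not in df.columns:
        raise ValueError(f"{counts_path} lacks a trailing taxonomy column")
    taxonomy = df.pop("taxonomy")
    meta = pd.read_csv(metadata_path, index_col=0)
    return OtuTable(df.astype(np.int64), meta, taxonomy)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _build(cls, data: dict):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def scenario_from_dict(data: dict) -> ScenarioSpec:
    data = dict(data)
    column = _build(ColumnConfig, data.pop("column", {}))
    kinetics = _build(KineticParams, data.pop("kinetics", {}))
    abundance = _build(AbundanceModel, data.pop("abundance", {}))
    community = _build(CommunityModel, data.pop("community", {}))
    for key in ("markers",):
        if isinstance(getattr(abundance, key, None), list):
            setattr(abundance, key, tuple(getattr(abundance, key)))
    return _build(ScenarioSpec, {
        "column": column, "kinetics": kinetics, "abundance": abundance,
        "community": community, **data,
    })


def load_scenario(path: str | Path) -> ScenarioSpec:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    def undata(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: undata(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: undata(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [undata(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return undata(spec)


def save_scenario(spec: ScenarioSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(spec), fh, sort_keys=False)


def northpond_like() -> ScenarioSpec:
    """The shipped example scenario calibrated to a two-sided oxygenated,
    nitrate-accumulating oligotrophic column."""
    with resources.files("sednit.data").joinpath("northpond_like.yaml").open() as fh:
        return scenario_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# pipeline + manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config_digest: str
    seed: int
    version: str
    stages: list[str]
    outputs: dict[str, str]  # path -> sha256
    wallclock_s: float

    def write(self, path: str | Path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        tmp.replace(path)  # atomic on POSIX


ALL_STAGES = ("synth", "simulate", "zones", "fluxes", "cellrates", "community")


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> RunManifest:
    """Run the requested stages in dependency order and write a manifest.

    Stage outputs are CSV/TSV files in ``out_dir``; every paper-gap default in
    use (density, electron counts, thresholds) is logged at INFO level.  A
    stage failure aborts with the stage name after persisting partial outputs.
    """
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_path = Path(config_path)
    spec = load_scenario(config_path)
    if seed is not None:
        spec = dataclasses.replace(spec, seed=int(seed))
    outputs: dict[str, Path] = {}
    done: list[str] = []

    state: dict[str, object] = {}

    def persist_manifest() -> RunManifest:
        manifest = RunManifest(
            config_digest=_sha256(config_path),
            seed=spec.seed,
            version=__version__,
            stages=done,
            outputs={str(p): _sha256(p) for p in outputs.values()},
            wallclock_s=time.perf_counter() - t0,
        )
        manifest.write(out / "manifest.json")
        return manifest

    try:
        for stage in stages:
            log.info("stage %s starting", stage)
            if stage == "synth":
                observed, truth = generate_profiles(spec, species=("O2", "NO3", "NH4", "Mn2"))
                zones = default_zones(spec)
                abund = generate_abundances(spec, zones)
                table, planted = generate_otu_table(spec, zones)
                write_profiles(observed, out / "observed_profiles.csv")
                write_solution(truth, out / "true_solution.csv")
                write_abundances(abund, out / "abundances.csv")
                write_otu_table(table, out / "otu_table.tsv", out / "otu_metadata.csv")
                (out / "planted_truth.json").write_text(json.dumps({
                    "resurrected_otus": planted.resurrected_otus,
                    "resurrection_probability": planted.resurrection_probability,
                }, indent=2))
                for name in ("observed_profiles.csv", "true_solution.csv",
                             "abundances.csv", "otu_table.tsv", "otu_metadata.csv",
                             "planted_truth.json"):
                    outputs[name] = out / name
                state.update(observed=observed, truth=truth, zones=zones,
                             abund=abund, table=table)
            elif stage == "simulate":
                sol = solve_steady_state(spec.column, spec.kinetics)
                write_solution(sol, out / "solution.csv")
                outputs["solution.csv"] = out / "solution.csv"
                state["solution"] = sol
            elif stage == "zones":
                sol: SolutionField = state.get("solution") or state["truth"]  # type: ignore
                o2 = DepthProfile(sol.z, sol.concentrations["O2"], species="O2")
                zones = detect_transition_zones(o2)
                write_zones(zones, out / "zones.csv")
                outputs["zones.csv"] = out / "zones.csv"
                state["zones"] = zones
            elif stage == "fluxes":
                sol = state.get("solution") or state["truth"]  # type: ignore
                phi = float(np.mean(spec.column.porosity_profile()))
                rows = []
                for sp in ("O2", "NO3"):
                    prof = DepthProfile(sol.z, sol.concentrations[sp], species=sp)
                    for iface, side in (("top", "below"), ("bottom", "above")):
                        depth = 0.0 if iface == "top" else spec.column.depth_max
                        est = fick_flux(prof, depth, phi, spec.column.D0[sp],
                                        n_points=3, side=side)
                        rows.append({"interface": iface, "species": sp,
                                     "flux_mmol_m2_yr": est.value,
                                     "window": "|".join(f"{d:g}" for d in est.window)})
                pd.DataFrame(rows).to_csv(out / "fluxes.csv", index=False,
                                          float_format=FLOAT_FORMAT)
                outputs["fluxes.csv"] = out / "fluxes.csv"
            elif stage == "cellrates":
                sol = state.get("solution") or state["truth"]  # type: ignore
                abund = state.get("abund")
                if abund is None:
                    abund = read_abundances(out / "abundances.csv")
                log.info("cellrates defaults: wet bulk density 1.7 g/cm3, "
                         "8 e-/NH4 nitrification, 365.25 d/yr, 14 fg C/cell")
                vol = pd.DataFrame({
                    "depth_m": sol.z,
                    "nitrification": sol.rates["R4"],
                    "denitrification": sol.rates["R2"],
                    "O2_respiration": sol.rates["R1"] + 2 * sol.rates["R4"]
                    + 0.5 * sol.rates["R5"],
                })
                tbl = rates_table(vol, abund, temperature=spec.column.temperature)
                tbl.to_csv(out / "cell_rates.csv", index=False, float_format=FLOAT_FORMAT)
                outputs["cell_rates.csv"] = out / "cell_rates.csv"
            elif stage == "community":
                table = state.get("table")
                if table is None:
                    table = read_otu_table(out / "otu_table.tsv", out / "otu_metadata.csv")
                rich = richness_profile(table)
                rich.to_csv(out / "richness.csv", index=False, float_format=FLOAT_FORMAT)
                res = reappearance_fraction(table, taxon_filter=None)
                (out / "reappearance.json").write_text(json.dumps({
                    "fraction": res.fraction,
                    "n_surface": res.n_surface,
                    "n_reappearing": res.n_reappearing,
                }, indent=2))
                outputs["richness.csv"] = out / "richness.csv"
                outputs["reappearance.json"] = out / "reappearance.json"
            else:
                raise ValueError(f"unknown stage {stage!r}")
            done.append(stage)
    except Exception as exc:
        persist_manifest()
        raise RuntimeError(f"stage {stages[len(done)]!r} failed: {exc}") from exc
    return persist_manifest()
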
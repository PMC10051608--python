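"""Synthetic study-data generation with known ground truth.

The physical study deposited no raw data, so every pipeline input is
emulated here: GIS per-compartment dissolution curves come from the
mechanistic simulator, and plasma curves are built by convolving a known
biexponential UIR with an absorption curve derived from a known Weibull
dissolution model through a known Levy time scaling.  Multiplicative
lognormal noise (CV-parameterized, mean 1) is added, since concentrations
are strictly positive.  Fixing the seed makes the output byte-identical.

The module also packages the published summary values used as fixtures:
equilibrium solubility tables, per-formulation Weibull parameters, the UIR
macro constants, and the observed PK summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .gis import FormulationScenario, GISConfig, GISResult, GISSimulator, default_scenarios
from .ivivc import AbsorptionProfile, LevyModel, PlasmaProfile, UIRParameters, convolve
from .metrics import WeibullParams, weibull_cdf
from .solubility import SolubilityRecord

__all__ = [
    "REFERENCE_UIR",
    "SyntheticStudySpec",
    "default_study_spec",
    "load_table",
    "fixture",
    "solubility_records",
    "solubility_map",
    "make_gis_profiles",
    "make_plasma_profiles",
]

#: Fitted unit-impulse-response macro constants of the reference 400 mg
#: (2 x 200 mg) conventional-tablet plasma curve; used verbatim as the
#: study's disposition model.
REFERENCE_UIR = UIRParameters(
    A1=50.32, A2=0.007514, alpha1=0.004773, alpha2=0.004006, reference_dose=400.0
)

_TABLES = {
    "br_solubility": "br_solubility.csv",
    "biorelevant_solubility": "biorelevant_solubility.csv",
    "weibull_params": "weibull_params.csv",
    "observed_pk": "observed_pk.csv",
}


def load_table(name: str) -> pd.DataFrame:
    """Load a packaged fixture table by content name.

    Names: ``br_solubility`` (pH-solubility in Britton-Robinson buffers),
    ``biorelevant_solubility``, ``weibull_params``, ``observed_pk``.
    """
    try:
        fname = _TABLES[name]
    except KeyError as exc:
        raise KeyError(f"unknown table {name!r}; options: {sorted(_TABLES)}") from exc
    with resources.files("gisivivc.data").joinpath(fname).open("rb") as fh:
        return pd.read_csv(fh)


def fixture(name: str, key: str | None = None):
    """Convenience accessor for packaged reference values.

    * ``fixture("uir")`` -> :class:`UIRParameters`
    * ``fixture("biorelevant_solubility", "FaSSGF blank")`` -> 56.3 (ug/mL)
    * ``fixture("br_solubility", "BR buffer pH 1.92")`` -> 70.8
    * ``fixture("weibull_params", "IBU-Lys")`` -> WeibullParams(B=2.087, ...)
    * ``fixture("observed_pk", "IBU")`` -> dict of observed PK values
    """
    if name == "uir":
        return REFERENCE_UIR
    df = load_table(name)
    if key is None:
        return df
    if name in ("br_solubility", "biorelevant_solubility"):
        row = df[df["medium"] == key]
        if row.empty:
            raise KeyError(f"medium {key!r} not found in {name}")
        return float(row["solubility_ug_ml"].iloc[0])
    if name == "weibull_params":
        row = df[df["formulation"] == key]
        if row.empty:
            raise KeyError(f"formulation {key!r} not found in {name}")
        return WeibullParams(B=float(row["B"].iloc[0]), MDT=float(row["MDT_min"].iloc[0]))
    if name == "observed_pk":
        row = df[df["formulation"] == key]
        if row.empty:
            raise KeyError(f"formulation {key!r} not found in {name}")
        return row.iloc[0].to_dict()
    raise KeyError(name)


def solubility_records(table: str = "biorelevant_solubility") -> list[SolubilityRecord]:
    df = load_table(table)
    return [
        SolubilityRecord(
            medium_name=str(r["medium"]),
            pH=float(r["pH"]),
            solubility=float(r["solubility_ug_ml"]),
            sd=float(r["sd_ug_ml"]),
            n_replicates=int(r["n"]),
        )
        for _, r in df.iterrows()
    ]


def solubility_map(config: GISConfig | None = None) -> dict[float, float]:
    """pH -> equilibrium solubility (mg/L) for the blank biorelevant media
    used in the simulator (blank FaSSGF at gastric pH, blank FaSSIF at
    intestinal pH)."""
    cfg = config or GISConfig()
    return {
        cfg.gastric_pH: fixture("biorelevant_solubility", "FaSSGF blank"),
        cfg.intestinal_pH: fixture("biorelevant_solubility", "FaSSIF blank"),
    }


def all_weibull_params() -> dict[str, WeibullParams]:
    df = load_table("weibull_params")
    return {
        str(r["formulation"]): WeibullParams(B=float(r["B"]), MDT=float(r["MDT_min"]))
        for _, r in df.iterrows()
    }


@dataclass
class SyntheticStudySpec:
    """Ground truth and sampling design for a synthetic study."""

    truth_weibull: Mapping[str, WeibullParams]
    truth_uir: UIRParameters
    truth_levy: LevyModel
    noise_cv: float = 0.05
    dose: float = 400.0  # mg (2 x 200 mg units)
    plasma_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 721.0, 15.0)
    )
    gis_config: GISConfig = field(default_factory=GISConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        self.plasma_grid = np.asarray(self.plasma_grid, dtype=float)


def default_study_spec(seed: int = 0, noise_cv: float = 0.05) -> SyntheticStudySpec:
    """Study conditions mirroring the published analysis: the packaged
    Weibull parameters and UIR as truth, 400 mg dose, 15-min plasma grid
    to 720 min.  The Levy scaling (slope 1.1, intercept 5 min) is a chosen
    truth -- the published study plots but does not print its regression."""
    return SyntheticStudySpec(
        truth_weibull=all_weibull_params(),
        truth_uir=REFERENCE_UIR,
        truth_levy=LevyModel(slope=1.1, intercept=5.0),
        noise_cv=noise_cv,
        seed=seed,
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def make_gis_profiles(
    spec: SyntheticStudySpec,
    scenarios: Mapping[str, FormulationScenario] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, GISResult]:
    """Simulate the GIS scenarios and apply measurement noise.

    Noise multiplies the dissolved amounts (and therefore concentrations);
    solid amounts are adjusted to preserve mass only when that keeps them
    non-negative.  With ``out_dir`` set, one tidy CSV per scenario is
    written (deterministic for a fixed seed).
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    rng = np.random.default_rng(spec.seed)
    sim = GISSimulator(spec.gis_config)
    smap = solubility_map(spec.gis_config)
    results: dict[str, GISResult] = {}
    for name in sorted(scenarios):
        res = sim.simulate(scenarios[name], smap)
        noisy = res.dissolved * _lognormal_noise(rng, spec.noise_cv, res.dissolved.shape)
        results[name] = GISResult(
            time=res.time,
            volume=res.volume,
            dissolved=noisy,
            solid=res.solid,
            dose=res.dose,
            config=res.config,
            scenario=res.scenario,
        )
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            results[name].write_csv(out / f"gis_{name}.csv")
    return results


def true_absorption(
    spec: SyntheticStudySpec, formulation: str, t_grid: np.ndarray | None = None
) -> AbsorptionProfile:
    """Noise-free Fa implied by the truth Weibull + Levy for a formulation."""
    t = np.asarray(t_grid, dtype=float) if t_grid is not None else spec.plasma_grid
    wb = spec.truth_weibull[formulation]
    t_vitro = np.maximum(spec.truth_levy.vitro_time(t), 0.0)
    fa = np.clip(weibull_cdf(wb, t_vitro) / 100.0, 0.0, 1.0)
    return AbsorptionProfile(time_points=t, fraction_absorbed=np.maximum.accumulate(fa))


def make_plasma_profiles(
    spec: SyntheticStudySpec, out_dir: str | Path | None = None
) -> dict[str, dict]:
    """Generate noisy plasma curves for every formulation in the truth set.

    Returns per formulation a dict with the noisy ``plasma``, the
    noise-free ``clean`` profile and the ``truth`` absorption profile, so
    recovery studies can score themselves.
    """
    rng = np.random.default_rng(spec.seed)
    out: dict[str, dict] = {}
    for name in sorted(spec.truth_weibull):
        fa = true_absorption(spec, name)
        clean = convolve(spec.truth_uir, fa, spec.dose, label=name)
        noise = _lognormal_noise(rng, spec.noise_cv, clean.concentrations.shape)
        noisy = PlasmaProfile(
            time_points=clean.time_points.copy(),
            concentrations=clean.concentrations * noise,
            dose=spec.dose,
            label=name,
        )
        out[name] = {"plasma": noisy, "clean": clean, "truth": fa}
        if out_dir is not None:
            p = Path(out_dir)
            p.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                {
                    "time_min": noisy.time_points,
                    "conc_ug_ml": noisy.concentrations,
                }
            ).to_csv(p / f"plasma_{name}.csv", index=False, float_format="%.10g")
    return out
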
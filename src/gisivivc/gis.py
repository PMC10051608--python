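"""In silico twin of the three-compartment Gastrointestinal Simulator (GIS).

The physical apparatus is three stirred vessels -- stomach, duodenum,
jejunum -- connected by peristaltic pumps.  The stomach starts with 300 mL
(50 mL pH 1.6 gastric fluid + 250 mL water), the duodenum with 50 mL of
pH 6.5 fluid, the jejunum empty.  Secretion pumps feed 1 mL/min of fresh
medium into the stomach and duodenum; transfer pumps move 5.5 mL/min
stomach -> duodenum and 6.5 mL/min duodenum -> jejunum.  The run lasts
45 min with 5-min sampling.  The jejunum is a terminal collection vessel.

The governing mass-balance model (per compartment, drug mass in mg,
concentrations in mg/L):

* dissolution      z * X * (S_eff - C), clipped at C = S_eff
* precipitation    k_prec * max(0, C - S_eq) * V, first order in the excess
* liquid transfer  carries dissolved drug at the vessel concentration
* solid transfer   same fractional rate as the liquid (suspension pumping)

Supersaturation of salt / pre-dissolved formulations is represented by an
effective (kinetic) solubility ``max_supersaturation_ratio * S_eq`` seen by
the undissolved salt, while any precipitate is ordinary free acid that only
redissolves up to S_eq.  pH is fixed per compartment (buffered media), so
S_eq is a per-compartment constant looked up from a pH -> solubility map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "COMPARTMENTS",
    "GISConfig",
    "FormulationScenario",
    "VolumeTrajectories",
    "GISResult",
    "GISSimulator",
    "volume_trajectories",
    "simulate",
    "cumulative_dissolved",
    "default_scenarios",
]

COMPARTMENTS = ("stomach", "duodenum", "jejunum")

_EPS_ML = 1e-9  # guard for the initially empty jejunum


@dataclass(frozen=True)
class GISConfig:
    """Apparatus settings (volumes in mL, flows in mL/min, times in min)."""

    initial_gastric_volume: float = 300.0
    initial_duodenal_volume: float = 50.0
    initial_jejunal_volume: float = 0.0
    gastric_secretion_rate: float = 1.0
    duodenal_secretion_rate: float = 1.0
    gastric_to_duodenal_flow: float = 5.5
    duodenal_to_jejunal_flow: float = 6.5
    duration: float = 45.0
    sampling_interval: float = 5.0
    gastric_pH: float = 1.6
    intestinal_pH: float = 6.5

    def __post_init__(self) -> None:
        for name in (
            "initial_gastric_volume",
            "initial_duodenal_volume",
            "initial_jejunal_volume",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gastric_to_duodenal_flow", "duodenal_to_jejunal_flow"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.duration <= 0 or self.sampling_interval <= 0:
            raise ValueError("duration and sampling_interval must be > 0")
        # volumes must stay non-negative over the whole run (linear in t,
        # so only the net rates and endpoints need checking)
        traj = volume_trajectories(self, _validate=False)
        for name, rate, v0 in (
            ("gastric", traj.gastric_rate, self.initial_gastric_volume),
            ("duodenal", traj.duodenal_rate, self.initial_duodenal_volume),
            ("jejunal", traj.jejunal_rate, self.initial_jejunal_volume),
        ):
            if rate < 0 and v0 + rate * self.duration < 0:
                t_dep = v0 / (-rate)
                raise ValueError(
                    f"{name} compartment is depleted at t = {t_dep:.2f} min, "
                    f"before the configured duration of {self.duration} min"
                )

    @property
    def sampling_grid(self) -> np.ndarray:
        n = int(round(self.duration / self.sampling_interval))
        return np.linspace(0.0, n * self.sampling_interval, n + 1)


@dataclass(frozen=True)
class VolumeTrajectories:
    """Closed-form (linear-in-time) compartment volumes, mL."""

    gastric_v0: float
    duodenal_v0: float
    jejunal_v0: float
    gastric_rate: float
    duodenal_rate: float
    jejunal_rate: float

    def gastric(self, t):
        return self.gastric_v0 + self.gastric_rate * np.asarray(t, dtype=float)

    def duodenal(self, t):
        return self.duodenal_v0 + self.duodenal_rate * np.asarray(t, dtype=float)

    def jejunal(self, t):
        return self.jejunal_v0 + self.jejunal_rate * np.asarray(t, dtype=float)

    def __call__(self, t) -> np.ndarray:
        """Stacked volumes, shape (3,) + shape of t."""
        return np.stack([self.gastric(t), self.duodenal(t), self.jejunal(t)])


def volume_trajectories(config: GISConfig, _validate: bool = True) -> VolumeTrajectories:
    """Analytic volume trajectories implied by constant pump rates.

    V_s(t) = V_s0 + (secretion_s - Q_sd) t
    V_d(t) = V_d0 + (Q_sd + secretion_d - Q_dj) t
    V_j(t) = V_j0 + Q_dj t
    """
    return VolumeTrajectories(
        gastric_v0=config.initial_gastric_volume,
        duodenal_v0=config.initial_duodenal_volume,
        jejunal_v0=config.initial_jejunal_volume,
        gastric_rate=config.gastric_secretion_rate - config.gastric_to_duodenal_flow,
        duodenal_rate=(
            config.gastric_to_duodenal_flow
            + config.duodenal_secretion_rate
            - config.duodenal_to_jejunal_flow
        ),
        jejunal_rate=config.duodenal_to_jejunal_flow,
    )


@dataclass(frozen=True)
class FormulationScenario:
    """Formulation behaviour inside the simulator.

    dose is mg of drug (acid equivalent) per dosage unit; ``form`` selects
    how the drug enters the stomach:

    * ``free_acid``     solid that dissolves up to S_eq only
    * ``salt``          solid with kinetic solubility ratio * S_eq
    * ``pre_dissolved`` enters in solution, capped at ratio * S_eq
      (the excess precipitates instantly to free-acid solid)

    z is the dissolution rate coefficient, 1/(min * mg/L); lag_time delays
    the release (soft-gelatin shell disintegration ~ 5 min).
    """

    dose: float
    form: str = "free_acid"
    dissolution_rate_coefficient_z: float = 2.0e-4
    lag_time: float = 0.0
    max_supersaturation_ratio: float = 1.0
    precipitation_rate_constant: float = 0.0
    n_units: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        if self.form not in ("free_acid", "salt", "pre_dissolved"):
            raise ValueError(f"unknown formulation form {self.form!r}")
        if self.dissolution_rate_coefficient_z < 0:
            raise ValueError("z must be >= 0")
        if self.max_supersaturation_ratio < 1.0:
            raise ValueError("max_supersaturation_ratio must be >= 1")
        if self.precipitation_rate_constant < 0:
            raise ValueError("precipitation_rate_constant must be >= 0")
        if self.lag_time < 0:
            raise ValueError("lag_time must be >= 0")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")

    @property
    def total_dose(self) -> float:
        return self.dose * self.n_units


def default_scenarios(dose: float = 200.0, n_units: int = 1) -> dict[str, FormulationScenario]:
    """Scenario presets for the four studied immediate-release products.

    z and k_prec are calibration constants of this simulator (the hardware
    study does not define a rate law); the supersaturation ratios and the
    soft-gel lag mirror the observed gastric behaviour: no supersaturation
    for the conventional tablet, ~2.5x / ~2.3x for the sodium and lysine
    salts, ~1.8x with a ~5 min delay for the pre-dissolved capsule.
    """
    return {
        "IBU": FormulationScenario(
            dose=dose, n_units=n_units, form="free_acid",
            dissolution_rate_coefficient_z=2.0e-4,
            precipitation_rate_constant=0.0, label="IBU",
        ),
        "IBU-Na": FormulationScenario(
            dose=dose, n_units=n_units, form="salt",
            dissolution_rate_coefficient_z=6.0e-3,
            max_supersaturation_ratio=2.5,
            precipitation_rate_constant=0.4, label="IBU-Na",
        ),
        "IBU-Lys": FormulationScenario(
            dose=dose, n_units=n_units, form="salt",
            dissolution_rate_coefficient_z=6.0e-3,
            max_supersaturation_ratio=2.3,
            precipitation_rate_constant=0.4, label="IBU-Lys",
        ),
        "IBU-lq": FormulationScenario(
            dose=dose, n_units=n_units, form="pre_dissolved",
            dissolution_rate_coefficient_z=6.0e-3,
            max_supersaturation_ratio=1.8, lag_time=5.0,
            precipitation_rate_constant=0.4, label="IBU-lq",
        ),
    }


@dataclass
class GISResult:
    """Per-compartment state sampled on a time grid.

    Arrays are shaped (3, n_times) with compartment order
    (stomach, duodenum, jejunum).
    """

    time: np.ndarray  # min, (n,)
    volume: np.ndarray  # mL
    dissolved: np.ndarray  # mg
    solid: np.ndarray  # mg
    dose: float  # total mg administered
    config: GISConfig | None = None
    scenario: FormulationScenario | None = None

    @property
    def concentration(self) -> np.ndarray:
        """mg/L; zero where the compartment volume is zero."""
        v_l = self.volume / 1000.0
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(v_l > 0, self.dissolved / np.maximum(v_l, 1e-12), 0.0)
        return c

    @property
    def percent_dissolved_of_dose(self) -> np.ndarray:
        if self.dose == 0:
            return np.zeros_like(self.dissolved)
        return 100.0 * self.dissolved / self.dose

    @property
    def total_drug(self) -> np.ndarray:
        """Dissolved + solid summed over compartments, mg, per sample."""
        return self.dissolved.sum(axis=0) + self.solid.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV layout: time_min,compartment,volume_ml,dissolved_mg,..."""
        rows = []
        conc = self.concentration
        pct = self.percent_dissolved_of_dose
        for i, comp in enumerate(COMPARTMENTS):
            for k, t in enumerate(self.time):
                rows.append(
                    {
                        "time_min": t,
                        "compartment": comp,
                        "volume_ml": self.volume[i, k],
                        "dissolved_mg": self.dissolved[i, k],
                        "solid_mg": self.solid[i, k],
                        "conc_mg_l": conc[i, k],
                        "pct_dissolved": pct[i, k],
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


class GISSimulator:
    """Mass-balance ODE model of the GIS run for one formulation scenario.

    State vector (mg): dissolved, free-acid solid and salt solid in each of
    the three compartments (9 entries).  Volumes follow the analytic
    trajectories; the drug ODE is integrated with a stiff-capable adaptive
    solver (LSODA, rtol = atol = 1e-10) and reported on the sampling grid.
    """

    def __init__(
        self,
        config: GISConfig | None = None,
        rtol: float = 1e-10,
        atol: float = 1e-10,
    ):
        self.config = config or GISConfig()
        self.rtol = rtol
        self.atol = atol

    # state layout
    _M = (0, 3, 6)  # dissolved
    _XA = (1, 4, 7)  # free-acid solid (incl. precipitate)
    _XS = (2, 5, 8)  # undissolved salt

    def _rhs_factory(
        self, scenario: FormulationScenario, s_gastric: float, s_intestinal: float
    ) -> Callable:
        cfg = self.config
        traj = volume_trajectories(cfg)
        z = scenario.dissolution_rate_coefficient_z
        ratio = scenario.max_supersaturation_ratio
        kp = scenario.precipitation_rate_constant
        q_sd = cfg.gastric_to_duodenal_flow  # mL/min
        q_dj = cfg.duodenal_to_jejunal_flow

        def rhs(t, y):
            y = np.maximum(y, 0.0)
            vs_ml = traj.gastric(t)
            vd_ml = traj.duodenal(t)
            vj_ml = max(traj.jejunal(t), _EPS_ML)
            vs, vd, vj = vs_ml / 1000.0, vd_ml / 1000.0, vj_ml / 1000.0
            cs, cd, cj = y[0] / vs, y[3] / vd, y[6] / vj
            fs = q_sd / vs_ml  # fractional transfer rates, 1/min
            fd = q_dj / vd_ml

            dy = np.empty(9)
            # stomach
            dis_a = z * y[1] * max(s_gastric - cs, 0.0)
            dis_s = z * y[2] * max(ratio * s_gastric - cs, 0.0)
            prc = kp * max(cs - s_gastric, 0.0) * vs
            out_liq = cs * q_sd / 1000.0  # mg/min
            dy[0] = dis_a + dis_s - prc - out_liq
            dy[1] = -dis_a + prc - y[1] * fs
            dy[2] = -dis_s - y[2] * fs
            # duodenum
            dis_a_d = z * y[4] * max(s_intestinal - cd, 0.0)
            dis_s_d = z * y[5] * max(ratio * s_intestinal - cd, 0.0)
            prc_d = kp * max(cd - s_intestinal, 0.0) * vd
            out_liq_d = cd * q_dj / 1000.0
            dy[3] = out_liq + dis_a_d + dis_s_d - prc_d - out_liq_d
            dy[4] = y[1] * fs - dis_a_d + prc_d - y[4] * fd
            dy[5] = y[2] * fs - dis_s_d - y[5] * fd
            # jejunum (terminal: no outflow)
            dis_a_j = z * y[7] * max(s_intestinal - cj, 0.0)
            dis_s_j = z * y[8] * max(ratio * s_intestinal - cj, 0.0)
            prc_j = kp * max(cj - s_intestinal, 0.0) * vj
            dy[6] = out_liq_d + dis_a_j + dis_s_j - prc_j
            dy[7] = y[4] * fd - dis_a_j + prc_j
            dy[8] = y[5] * fd - dis_s_j
            return dy

        return rhs

    def _initial_state(
        self, scenario: FormulationScenario, s_gastric: float, t_release: float
    ) -> np.ndarray:
        y0 = np.zeros(9)
        dose = scenario.total_dose
        if scenario.form == "free_acid":
            y0[1] = dose
        elif scenario.form == "salt":
            y0[2] = dose
        else:  # pre_dissolved: capped at the kinetic solubility, the
            # excess nucleates immediately as free-acid solid
            traj = volume_trajectories(self.config)
            v_l = traj.gastric(t_release) / 1000.0
            cap = scenario.max_supersaturation_ratio * s_gastric * v_l
            y0[0] = min(dose, cap)
            y0[1] = dose - y0[0]
        return y0

    def simulate(
        self,
        scenario: FormulationScenario,
        solubility: Mapping[float, float],
        t_eval: Sequence[float] | None = None,
    ) -> GISResult:
        """Run the scenario and return the sampled state.

        ``solubility`` maps pH -> equilibrium solubility in mg/L and must
        cover the gastric and intestinal pH of the config.
        """
        cfg = self.config
        try:
            s_gastric = float(solubility[cfg.gastric_pH])
            s_intestinal = float(solubility[cfg.intestinal_pH])
        except KeyError as exc:
            raise KeyError(
                f"solubility map lacks an entry for pH {exc.args[0]}; "
                f"needs pH {cfg.gastric_pH} and {cfg.intestinal_pH}"
            ) from exc

        grid = np.asarray(t_eval, dtype=float) if t_eval is not None else cfg.sampling_grid
        traj = volume_trajectories(cfg)
        volume = traj(grid)

        dissolved = np.zeros((3, grid.size))
        solid = np.zeros((3, grid.size))
        dose = scenario.total_dose

        t0 = min(scenario.lag_time, cfg.duration)
        if dose > 0 and t0 < cfg.duration:
            y0 = self._initial_state(scenario, s_gastric, t0)
            rhs = self._rhs_factory(scenario, s_gastric, s_intestinal)
            after = grid >= t0 - 1e-12
            t_pts = grid[after]
            # make sure the span starts exactly at t0
            span = (t0, cfg.duration)
            sol = solve_ivp(
                rhs,
                span,
                y0,
                method="LSODA",
                t_eval=np.clip(t_pts, t0, cfg.duration),
                rtol=self.rtol,
                atol=self.atol,
                max_step=1.0,
            )
            if not sol.success:
                raise RuntimeError(
                    f"GIS integration failed: {sol.message}; state at failure "
                    f"t={sol.t[-1] if sol.t.size else t0}: "
                    f"{sol.y[:, -1] if sol.y.size else y0}"
                )
            y = np.maximum(sol.y, 0.0)
            dissolved[:, after] = y[list(self._M), :]
            solid[:, after] = y[list(self._XA), :] + y[list(self._XS), :]
            # before release: all drug is undissolved inside the dosage form
            solid[0, ~after] = dose
        elif dose > 0:
            solid[0, :] = dose

        return GISResult(
            time=grid,
            volume=volume,
            dissolved=dissolved,
            solid=solid,
            dose=dose,
            config=cfg,
            scenario=scenario,
        )


def simulate(
    config: GISConfig,
    scenario: FormulationScenario,
    solubility: Mapping[float, float],
    t_eval: Sequence[float] | None = None,
) -> GISResult:
    """Functional wrapper over :class:`GISSimulator`."""
    return GISSimulator(config).simulate(scenario, solubility, t_eval=t_eval)


def cumulative_dissolved(result: GISResult, compartments: Iterable[str] = ("duodenum", "jejunum")):
    """Cumulative dissolved drug in a set of compartments as a profile.

    The jejunum is a terminal collection vessel, so summing the currently
    dissolved amounts automatically includes everything transferred onward
    from the duodenum.  Returns a :class:`~gisivivc.metrics.DissolutionProfile`
    in % of dose (mg amounts are in ``profile.amounts_mg``).
    """
    from .metrics import DissolutionProfile  # local import avoids a cycle

    comps = list(compartments)
    if not comps:
        raise ValueError("compartments must be non-empty")
    idx = []
    for c in comps:
        if c not in COMPARTMENTS:
            raise KeyError(f"unknown compartment {c!r}; valid: {COMPARTMENTS}")
        idx.append(COMPARTMENTS.index(c))
    amounts = result.dissolved[idx, :].sum(axis=0)
    pct = np.zeros_like(amounts) if result.dose == 0 else 100.0 * amounts / result.dose
    label = "+".join(comps)
    if result.scenario is not None and result.scenario.label:
        label = f"{result.scenario.label} ({label})"
    prof = DissolutionProfile(time_points=result.time.copy(), values=pct, label=label)
    prof.amounts_mg = amounts
    return prof
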
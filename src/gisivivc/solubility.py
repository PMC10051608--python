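"""pH-dependent equilibrium solubility of a monoprotic weak acid.

A poorly soluble acidic drug (ibuprofen is the worked case throughout this
package) follows the Henderson-Hasselbalch relationship

    S(pH) = S0 * (1 + 10**(pH - pKa))

over the pH range where the free acid controls the solid phase.  At high pH
the measured solubility levels off onto a salt plateau which the equation
does not describe; plateau records are excluded from fitting by default.

The module houses record containers, log-molar conversion, forward
evaluation, a scikit-learn style estimator for the (S0, pKa) fit, and
fold-change queries between named media.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from scipy.optimize import least_squares

__all__ = [
    "IBUPROFEN_MOLAR_MASS",
    "LITERATURE_LOG_S0_25C",
    "SolubilityRecord",
    "AcidSolubilityModel",
    "HendersonHasselbalchEstimator",
    "log_molar_solubility",
    "hh_solubility",
    "fit_hh",
    "fold_change",
    "read_solubility_csv",
    "write_solubility_csv",
]

#: Molar mass of ibuprofen (C13H18O2), g/mol.  Needed to convert mass
#: concentrations to molarity; shipped as a constant because the fixture
#: tables are reported in ug/mL.
IBUPROFEN_MOLAR_MASS = 206.28

#: Literature intrinsic solubility of ibuprofen, log10 mol/L, measured at
#: 25 C.  The packaged measurements were made at 37 C, where the observed
#: pH 1.92 value corresponds to logS = -3.46; the two are carried side by
#: side and no temperature correction is attempted.
LITERATURE_LOG_S0_25C = -3.62


@dataclass(frozen=True)
class SolubilityRecord:
    """One medium's equilibrium solubility measurement."""

    medium_name: str
    pH: float
    solubility: float  # ug/mL
    sd: float = 0.0  # ug/mL
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not self.solubility > 0:
            raise ValueError(f"solubility must be > 0, got {self.solubility}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH must lie in [0, 14], got {self.pH}")


@dataclass(frozen=True)
class AcidSolubilityModel:
    """Henderson-Hasselbalch description of a monoprotic weak acid.

    Attributes
    ----------
    intrinsic_solubility_s0 : float
        Solubility of the unionized acid, ug/mL.
    pka : float
        Acid dissociation constant (negative log).
    molar_mass : float
        g/mol, used for molar conversions only.
    rss : float
        Residual sum of squares of the log10-solubility fit that produced
        the model (0.0 for hand-constructed models).
    """

    intrinsic_solubility_s0: float
    pka: float
    molar_mass: float = IBUPROFEN_MOLAR_MASS
    rss: float = 0.0

    def __post_init__(self) -> None:
        if not self.intrinsic_solubility_s0 > 0:
            raise ValueError("intrinsic solubility S0 must be > 0")
        if not 0.0 < self.pka < 14.0:
            raise ValueError(f"pKa must lie in (0, 14), got {self.pka}")
        if not self.molar_mass > 0:
            raise ValueError("molar mass must be > 0")

    def solubility(self, pH) -> np.ndarray | float:
        return hh_solubility(self, pH)


def log_molar_solubility(solubility: float, molar_mass: float) -> float:
    """log10 molar solubility (mol/L) from a mass concentration in ug/mL.

    ug/mL is numerically mg/L, so the molarity is ``solubility * 1e-3 / M``
    with M in g/mol.
    """
    solubility = np.asarray(solubility, dtype=float)
    if np.any(solubility <= 0) or molar_mass <= 0:
        raise ValueError("solubility and molar mass must both be positive")
    out = np.log10(solubility * 1e-3 / molar_mass)
    return float(out) if out.ndim == 0 else out


def hh_solubility(model: AcidSolubilityModel, pH) -> np.ndarray | float:
    """Total solubility S0*(1 + 10**(pH - pKa)) in ug/mL.

    Strictly increasing in pH; tends to S0 in the fully unionized limit.
    """
    pH = np.asarray(pH, dtype=float)
    out = model.intrinsic_solubility_s0 * (1.0 + 10.0 ** (pH - model.pka))
    return float(out) if out.ndim == 0 else out


class HendersonHasselbalchEstimator(BaseEstimator, RegressorMixin):
    """Least-squares fit of the Henderson-Hasselbalch solubility curve.

    The fit is performed on log10 solubility (the data span several orders
    of magnitude, so a linear-scale fit would be dominated by the most
    soluble point):

        log10 S(pH) = log10 S0 + log10(1 + 10**(pH - pKa))

    Parameters
    ----------
    s0_init, pka_init : float, optional
        Starting values; data-driven defaults are used when omitted.

    Attributes
    ----------
    intrinsic_solubility_ : float
        Fitted S0 in the units of the training solubilities.
    pka_ : float
        Fitted pKa.
    rss_ : float
        Residual sum of squares in log10 space.
    """

    def __init__(self, s0_init: float | None = None, pka_init: float | None = None):
        self.s0_init = s0_init
        self.pka_init = pka_init

    def fit(self, X, y):
        pH = np.asarray(X, dtype=float).reshape(-1)
        S = np.asarray(y, dtype=float).reshape(-1)
        if pH.shape != S.shape:
            raise ValueError("pH and solubility arrays must have equal length")
        if pH.size < 2:
            raise ValueError(
                "need at least 2 records to fit the Henderson-Hasselbalch model"
            )
        if np.any(S <= 0):
            raise ValueError("solubilities must be positive")
        if np.ptp(pH) < 1.0:
            warnings.warn(
                "pH values span less than one unit; the (S0, pKa) fit is "
                "poorly conditioned",
                UserWarning,
            )

        logS = np.log10(S)
        log_s0_0 = np.log10(self.s0_init) if self.s0_init else float(logS.min())
        pka_0 = self.pka_init if self.pka_init else float(np.median(pH))

        def resid(theta):
            log_s0, pka = theta
            return log_s0 + np.log10(1.0 + 10.0 ** (pH - pka)) - logS

        sol = least_squares(
            resid,
            x0=[log_s0_0, pka_0],
            bounds=([-12.0, 0.0], [12.0, 14.0]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        self.intrinsic_solubility_ = float(10.0 ** sol.x[0])
        self.pka_ = float(sol.x[1])
        self.rss_ = float(2.0 * sol.cost)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        pH = np.asarray(X, dtype=float).reshape(-1)
        return self.intrinsic_solubility_ * (1.0 + 10.0 ** (pH - self.pka_))

    def to_model(self, molar_mass: float = IBUPROFEN_MOLAR_MASS) -> AcidSolubilityModel:
        return AcidSolubilityModel(
            intrinsic_solubility_s0=self.intrinsic_solubility_,
            pka=self.pka_,
            molar_mass=molar_mass,
            rss=self.rss_,
        )


def fit_hh(
    records: Sequence[SolubilityRecord],
    exclude_above_ph: float | None = 7.5,
    molar_mass: float = IBUPROFEN_MOLAR_MASS,
) -> AcidSolubilityModel:
    """Fit (S0, pKa) to solubility records.

    Records above ``exclude_above_ph`` are dropped before fitting: at high
    pH the solid phase is the salt and the measured solubility sits on a
    plateau the Henderson-Hasselbalch branch cannot describe.  Pass
    ``exclude_above_ph=None`` to keep everything.
    """
    recs = list(records)
    if exclude_above_ph is not None:
        recs = [r for r in recs if r.pH <= exclude_above_ph]
    if len(recs) < 2:
        raise ValueError(
            f"need at least 2 usable records, have {len(recs)} after plateau exclusion"
        )
    est = HendersonHasselbalchEstimator().fit(
        [r.pH for r in recs], [r.solubility for r in recs]
    )
    return est.to_model(molar_mass=molar_mass)


def fold_change(
    records: Iterable[SolubilityRecord], medium_a: str, medium_b: str
) -> float:
    """Solubility ratio medium_b / medium_a by medium name."""
    by_name = {r.medium_name: r for r in records}
    try:
        a = by_name[medium_a]
        b = by_name[medium_b]
    except KeyError as exc:
        known = ", ".join(sorted(by_name))
        raise KeyError(f"unknown medium {exc.args[0]!r}; known media: {known}") from exc
    return b.solubility / a.solubility


# ---------------------------------------------------------------------------
# CSV interface: header `medium,pH,solubility_ug_ml,sd_ug_ml,n`

_CSV_COLUMNS = ["medium", "pH", "solubility_ug_ml", "sd_ug_ml", "n"]


def read_solubility_csv(path: str | Path) -> list[SolubilityRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"solubility CSV {path} is missing columns {missing}")
    return [
        SolubilityRecord(
            medium_name=str(row["medium"]),
            pH=float(row["pH"]),
            solubility=float(row["solubility_ug_ml"]),
            sd=float(row["sd_ug_ml"]),
            n_replicates=int(row["n"]),
        )
        for _, row in df.iterrows()
    ]


def write_solubility_csv(records: Iterable[SolubilityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "medium": r.medium_name,
                "pH": r.pH,
                "solubility_ug_ml": r.solubility,
                "sd_ug_ml": r.sd,
                "n": r.n_replicates,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)
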
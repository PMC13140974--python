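"""Oxygen-dependent apparent Michaelis-Menten kinetics.

An amine oxidase consumes two substrates: the amine (S, e.g. THIQ) and
dissolved molecular oxygen.  Rates measured over an amine dilution series
at a fixed dissolved-oxygen level follow single-substrate Michaelis-Menten
form with *apparent* constants that depend on [O2].  Two limiting
two-substrate schemes are provided:

ping-pong (substituted enzyme),
    v = Vmax [S][O] / (KM_S [O] + KM_O [S] + [S][O])
    => Vmax_app = Vmax [O]/(KM_O+[O]),  KM_app = KM_S [O]/(KM_O+[O]).
    The apparent efficiency Vmax_app/KM_app = Vmax/KM_S is an [O2]
    invariant — the classic diagnostic for the mechanism.

independent sites (rapid-equilibrium, non-interacting),
    v = Vmax [S]/(KM_S+[S]) x [O]/(KM_O+[O])
    => Vmax_app as above but KM_app = KM_S, so the apparent efficiency
    rises with [O2].

The module also covers the periphery of a coupled peroxidase assay:
Beer-Lambert conversion of absorbance slopes to rates, the exclusion of
amine concentrations that inhibit the reporter enzyme, Henry's-law
conversion of oxygen saturation or partial pressure to mM, and a seeded
synthetic assay generator for round-trip testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import ConfigError, DataError, NumericalError

MECHANISMS = ("ping_pong", "independent_sites")

#: Molar absorptivity of the quinoneimine dye produced by the coupled
#: peroxidase assay (L mol^-1 cm^-1 at 510 nm).
DEFAULT_EPSILON = 29_400.0
#: Amine concentrations above this inhibit the reporter peroxidase and are
#: excluded from fits (mM).
DEFAULT_EXCLUSION_MM = 16.0
#: Henry's-law constant of O2 in water (mol m^-3 Pa^-1).
DEFAULT_HENRY = 1.2e-5
ATM_PA = 101_325.0


def dilution_series(start_mM: float = 128.0, n: int = 10,
                    factor: float = 2.0) -> np.ndarray:
    """Serial dilution, e.g. 128, 64, 32, ... mM."""
    return start_mM / factor ** np.arange(n)


@dataclass
class AssayConfig:
    epsilon_L_per_mol_cm: float = DEFAULT_EPSILON
    wavelength_nm: float = 510.0
    pathlength_cm: float | None = None
    enzyme_conc_mg_per_mL: float = 0.1
    substrate_series_mM: np.ndarray = field(
        default_factory=lambda: dilution_series())

    def __post_init__(self) -> None:
        self.substrate_series_mM = np.asarray(self.substrate_series_mM,
                                              dtype=float)
        if self.epsilon_L_per_mol_cm <= 0:
            raise ConfigError("epsilon must be positive")
        if self.pathlength_cm is not None and self.pathlength_cm <= 0:
            raise ConfigError("pathlength must be positive")
        if len(self.substrate_series_mM) > 1 and \
                not np.all(np.diff(self.substrate_series_mM) < 0):
            raise ConfigError("substrate series must be strictly decreasing")


@dataclass(frozen=True)
class KineticParams:
    Vmax: float
    KM_S_mM: float
    KM_O_mM: float
    mechanism: str = "ping_pong"

    def __post_init__(self) -> None:
        if min(self.Vmax, self.KM_S_mM, self.KM_O_mM) <= 0:
            raise ConfigError("kinetic constants must be positive")
        if self.mechanism not in MECHANISMS:
            raise ConfigError(
                f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")

    def rate(self, S_mM, O2_mM) -> np.ndarray:
        """Two-substrate rate law at given amine and oxygen concentrations."""
        S = np.asarray(S_mM, dtype=float)
        O = float(O2_mM)
        if self.mechanism == "ping_pong":
            return self.Vmax * S * O / (self.KM_S_mM * O + self.KM_O_mM * S
                                        + S * O)
        return (self.Vmax * S / (self.KM_S_mM + S)) * (O / (self.KM_O_mM + O))


@dataclass(frozen=True)
class ApparentParams:
    O2_mM: float
    Vmax_app: float
    KM_app_mM: float

    @property
    def efficiency_app(self) -> float:
        return self.Vmax_app / self.KM_app_mM


@dataclass
class OxygenState:
    henry_const_mol_per_m3_Pa: float = DEFAULT_HENRY
    partial_pressure_Pa: float | None = None
    saturation_percent: float | None = None

    def __post_init__(self) -> None:
        if self.henry_const_mol_per_m3_Pa <= 0:
            raise ConfigError("Henry constant must be positive")
        for v in (self.partial_pressure_Pa, self.saturation_percent):
            if v is not None and v < 0:
                raise ConfigError("oxygen inputs must be non-negative")


def absorbance_to_rate(slope_A_per_min: float, cfg: AssayConfig) -> float:
    """Beer-Lambert conversion of an absorbance slope to mM/min.

    rate [M/min] = slope / (epsilon * pathlength); x1000 for mM/min.
    The pathlength must be configured explicitly — in a plate reader it
    depends on the well volume.
    """
    if cfg.pathlength_cm is None:
        raise ConfigError(
            "pathlength_cm is required to convert absorbance slopes "
            "(plate-reader pathlength depends on well volume)")
    return slope_A_per_min / (cfg.epsilon_L_per_mol_cm * cfg.pathlength_cm) * 1e3


@dataclass
class MichaelisMentenFit:
    Vmax: float
    KM_mM: float
    se_Vmax: float
    se_KM: float
    r_squared: float
    n_used: int
    n_excluded: int
    excluded_S_mM: list[float] = field(default_factory=list)


def fit_michaelis_menten(points, exclusion_threshold_mM: float | None =
                         DEFAULT_EXCLUSION_MM) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of v = Vmax S / (KM + S).

    ``points`` is an iterable of (S_mM, rate) pairs.  Concentrations
    strictly above the exclusion threshold are dropped before fitting
    (reporter-enzyme inhibition); pass ``None`` to keep everything.
    Initial values: Vmax = max rate, KM = S at the rate closest to
    half-maximal.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DataError("points must be (S_mM, rate) pairs")
    S, v = pts[:, 0], pts[:, 1]
    if exclusion_threshold_mM is not None:
        keep = S <= exclusion_threshold_mM
    else:
        keep = np.ones(len(S), dtype=bool)
    excluded = sorted(S[~keep].tolist(), reverse=True)
    S, v = S[keep], v[keep]
    if len(S) < 3:
        raise DataError(
            f"need at least 3 usable points after exclusion, have {len(S)}")

    vmax0 = float(v.max())
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-9)

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    try:
        popt, pcov = curve_fit(mm, S, v, p0=[vmax0, km0], maxfev=10_000)
    except RuntimeError as exc:
        raise NumericalError(
            f"Michaelis-Menten fit did not converge (n={len(S)}, "
            f"p0=({vmax0:.3g}, {km0:.3g})): {exc}") from exc
    resid = v - mm(S, *popt)
    ss_res = float(resid @ resid)
    ss_tot = float(((v - v.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se = np.sqrt(np.diag(pcov))
    return MichaelisMentenFit(
        Vmax=float(popt[0]), KM_mM=float(popt[1]),
        se_Vmax=float(se[0]), se_KM=float(se[1]),
        r_squared=r2, n_used=len(S), n_excluded=len(excluded),
        excluded_S_mM=excluded)


def apparent_constants(p: KineticParams, O2_mM: float) -> ApparentParams:
    """Project two-substrate constants to fixed-[O2] apparent constants."""
    if O2_mM <= 0:
        raise ConfigError("O2 concentration must be positive")
    sat = O2_mM / (p.KM_O_mM + O2_mM)
    if p.mechanism == "ping_pong":
        return ApparentParams(O2_mM, p.Vmax * sat, p.KM_S_mM * sat)
    return ApparentParams(O2_mM, p.Vmax * sat, p.KM_S_mM)


def oxygen_concentration(state: OxygenState) -> float:
    """Dissolved O2 in mM from partial pressure or % saturation.

    c = kH * pO2; mol m^-3 is numerically mM.  Saturation is anchored to
    pure O2 at 1 atm = 100%.
    """
    has_p = state.partial_pressure_Pa is not None
    has_s = state.saturation_percent is not None
    if has_p == has_s:
        raise ConfigError(
            "set exactly one of partial_pressure_Pa or saturation_percent")
    if has_p:
        return state.henry_const_mol_per_m3_Pa * state.partial_pressure_Pa
    return (state.saturation_percent / 100.0) \
        * state.henry_const_mol_per_m3_Pa * ATM_PA


def simulate_assay(p: KineticParams, O2_levels_mM, cfg: AssayConfig,
                   noise_sigma: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic rate tables over the dilution series at each O2 level.

    Gaussian noise of absolute standard deviation ``noise_sigma`` (rate
    units) is added; the generator is seeded and deterministic.  Returns a
    tidy frame with columns ``O2_mM``, ``S_mM``, ``rate``.
    """
    levels = np.asarray(O2_levels_mM, dtype=float)
    if np.any(levels <= 0):
        raise ConfigError("O2 levels must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for O in levels:
        v = p.rate(cfg.substrate_series_mM, O)
        if noise_sigma > 0:
            v = v + rng.normal(0.0, noise_sigma, size=v.shape)
        rows.append(pd.DataFrame({
            "O2_mM": O, "S_mM": cfg.substrate_series_mM, "rate": v}))
    return pd.concat(rows, ignore_index=True)


def kcat_from_vmax(Vmax_mM_per_min: float, enzyme_mg_per_mL: float,
                   molar_mass_g_per_mol: float) -> float:
    """Turnover number (min^-1) from Vmax and the enzyme molar concentration.

    kcat = Vmax / [E]; [E] in mM is (mg/mL) / (g/mol) * 1000.  Requires an
    explicit molar mass — without it results stay in Vmax units.
    """
    if enzyme_mg_per_mL <= 0 or molar_mass_g_per_mol <= 0:
        raise ConfigError("enzyme concentration and molar mass must be positive")
    enzyme_mM = enzyme_mg_per_mL / molar_mass_g_per_mol * 1e3
    return Vmax_mM_per_min / enzyme_mM


def fit_assay_table(table: pd.DataFrame,
                    exclusion_threshold_mM: float | None = DEFAULT_EXCLUSION_MM
                    ) -> pd.DataFrame:
    """Per-O2-level Michaelis-Menten fits of a tidy rate table."""
    out = []
    for O, grp in table.groupby("O2_mM", sort=True):
        fit = fit_michaelis_menten(
            grp[["S_mM", "rate"]].to_numpy(), exclusion_threshold_mM)
        out.append({
            "O2_mM": float(O), "Vmax_app": fit.Vmax, "KM_app_mM": fit.KM_mM,
            "efficiency_app": fit.Vmax / fit.KM_mM,
            "se_Vmax": fit.se_Vmax, "se_KM": fit.se_KM,
            "r_squared": fit.r_squared,
            "n_used": fit.n_used, "n_excluded": fit.n_excluded,
        })
    return pd.DataFrame(out)
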
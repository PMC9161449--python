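"""One-site ITC binding analysis: Wiseman isotherm fit and ΔG/ΔH/−TΔS dissection.

The heat content of the calorimeter cell after the i-th injection, for a
single class of independent sites, is the closed-form (Wiseman) expression

    Q_i = n·Mt_i·V0·ΔH · Θ_i,
    Θ_i = ½ [ 1 + Xt/(n·Mt) + Kd/(n·Mt)
              − sqrt( (1 + Xt/(n·Mt) + Kd/(n·Mt))² − 4·Xt/(n·Mt) ) ]

with Mt_i and Xt_i the cell macromolecule and ligand concentrations after i
injections, corrected for the volume displaced from the fixed-volume cell:

    Mt_i = M0 · (1 − d_i/2V0) / (1 + d_i/2V0)
    Xt_i = X0 · (d_i/V0) / (1 + d_i/2V0)         (d_i = cumulative volume)

The measured per-injection heat applies the standard displaced-volume
correction ΔQ_i = Q_i − Q_{i−1} + (dV_i/V0)·(Q_i + Q_{i−1})/2 and is
normalized per mole of injectant (kcal/mol). A constant dilution offset is
co-fitted. Thermodynamic dissection uses ΔG = RT·ln(Kd [M]) and
−TΔS = ΔG − ΔH.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .constants import R_KCAL, T_STANDARD_K

__all__ = [
    "TitrationSeries",
    "OneSiteFit",
    "ThermoProfile",
    "wiseman_heats",
    "fit_one_site",
    "thermo_dissection",
    "fold_affinity_change",
]


@dataclass
class TitrationSeries:
    """Integrated per-injection heats plus the injection schedule.

    Heats are normalized per mole of injectant (kcal/mol of injectant).
    """

    injection_volumes_uL: np.ndarray
    heats: np.ndarray  # kcal per mol of injectant
    cell_volume_uL: float = 200.0
    cell_conc_uM: float = 70.0
    syringe_conc_uM: float = 800.0
    temperature_K: float = T_STANDARD_K

    def __post_init__(self):
        self.injection_volumes_uL = np.asarray(self.injection_volumes_uL, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        if self.injection_volumes_uL.size != self.heats.size:
            raise ValueError("injection schedule and heats differ in length")
        if self.injection_volumes_uL.size < 10:
            raise ValueError("need ≥ 10 injections for a one-site fit")
        if min(self.cell_volume_uL, self.cell_conc_uM, self.syringe_conc_uM) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if not np.all(np.isfinite(self.heats)):
            raise ValueError("non-finite heats")

    @property
    def molar_ratio(self) -> np.ndarray:
        """Xt/Mt after each injection (titration progress axis)."""
        d = np.cumsum(self.injection_volumes_uL)
        v0 = self.cell_volume_uL
        mt = self.cell_conc_uM * (1 - d / (2 * v0)) / (1 + d / (2 * v0))
        xt = self.syringe_conc_uM * (d / v0) / (1 + d / (2 * v0))
        return xt / mt


@dataclass
class OneSiteFit:
    Kd_uM: float
    Kd_se: float
    dH_kcal: float
    dH_se: float
    n: float
    n_se: float
    dilution_offset: float  # kcal/mol of injectant
    converged: bool
    measurable: bool = True
    residual_sd: float = np.nan
    note: str = ""


@dataclass(frozen=True)
class ThermoProfile:
    """Gibbs-energy dissection of binding at a stated temperature."""

    dG: float  # kcal/mol
    dH: float  # kcal/mol
    minusTdS: float  # kcal/mol
    temperature_K: float
    driving_force: str  # enthalpy-driven | entropy-driven | mixed


def wiseman_heats(
    n: float,
    Kd_uM: float,
    dH_kcal: float,
    injection_volumes_uL,
    cell_volume_uL: float,
    cell_conc_uM: float,
    syringe_conc_uM: float,
    offset: float = 0.0,
) -> np.ndarray:
    """Model per-injection heats (kcal per mol of injectant)."""
    dv = np.asarray(injection_volumes_uL, dtype=float)
    d = np.cumsum(dv)
    v0 = cell_volume_uL
    mt = cell_conc_uM * (1 - d / (2 * v0)) / (1 + d / (2 * v0))  # μM
    xt = syringe_conc_uM * (d / v0) / (1 + d / (2 * v0))  # μM

    nmt = n * mt
    b = 1.0 + xt / nmt + Kd_uM / nmt
    theta = 0.5 * (b - np.sqrt(np.maximum(b * b - 4.0 * xt / nmt, 0.0)))
    # cumulative heat content, kcal (concentrations μM → mol/L ×1e-6; volume μL → L ×1e-6)
    q = n * mt * 1e-6 * v0 * 1e-6 * dH_kcal * theta
    q_prev = np.concatenate(([0.0], q[:-1]))
    dq = q - q_prev + (dv / v0) * (q + q_prev) / 2.0
    mol_injected = syringe_conc_uM * 1e-6 * dv * 1e-6
    return dq / mol_injected + offset


def fit_one_site(
    series: TitrationSeries,
    noise_sd: float | None = None,
    fix_n: float | None = None,
) -> OneSiteFit:
    """Nonlinear least-squares fit of the one-site Wiseman model.

    Fits (n, Kd, ΔH, dilution offset) with multi-start over Kd decades.
    Declares "no measurable binding" when the heat trace is flat or the
    fitted |ΔH| is indistinguishable from zero (< 3× its standard error).

    ``fix_n`` pins the stoichiometry instead of fitting it — the standard
    constraint for low-c titrations (c = n·[cell]/Kd ≲ 1), where n and ΔH
    are otherwise strongly anti-correlated and only their product is well
    determined.
    """
    heats = series.heats
    span = float(np.max(heats) - np.min(heats))
    scale = float(np.max(np.abs(heats))) if heats.size else 0.0
    if span == 0.0 or scale == 0.0 or (noise_sd is not None and span < 3 * noise_sd):
        return OneSiteFit(
            Kd_uM=np.nan, Kd_se=np.nan, dH_kcal=0.0, dH_se=np.nan,
            n=np.nan, n_se=np.nan, dilution_offset=float(np.mean(heats)) if heats.size else 0.0,
            converged=False, measurable=False,
            note="no measurable binding: heat signal indistinguishable from baseline",
        )

    def model_free(_x, n, log_kd, dh, offset):
        return wiseman_heats(
            n, 10.0 ** log_kd, dh,
            series.injection_volumes_uL, series.cell_volume_uL,
            series.cell_conc_uM, series.syringe_conc_uM, offset,
        )

    def model_fixed(_x, log_kd, dh, offset):
        return model_free(_x, fix_n, log_kd, dh, offset)

    x = np.arange(heats.size)
    offset0 = float(np.mean(heats[-3:]))
    dh0 = float(heats[0] - offset0)
    n_free = fix_n is None
    model = model_free if n_free else model_fixed
    best = None
    for kd0 in (0.1, 1.0, 10.0, 100.0, 1000.0):
        p0 = [np.log10(kd0), dh0 if dh0 != 0 else -1.0, offset0]
        lo, hi = [-3.0, -1e3, -1e3], [6.0, 1e3, 1e3]
        if n_free:
            p0, lo, hi = [1.0] + p0, [1e-3] + lo, [20.0] + hi
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    model, x, heats, p0=p0, bounds=(lo, hi), maxfev=40000,
                )
        except RuntimeError:
            continue
        resid = heats - model(x, *popt)
        sse = float(np.sum(resid**2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise RuntimeError(
            "one-site fit did not converge from any start; "
            f"heat span {span:.3g} kcal/mol over {heats.size} injections"
        )

    sse, popt, pcov = best
    perr = np.sqrt(np.diag(pcov))
    if n_free:
        n, log_kd, dh, offset = popt
        n_se, kd_perr, dh_se = float(perr[0]), perr[1], float(perr[2])
    else:
        log_kd, dh, offset = popt
        n, n_se = float(fix_n), 0.0
        kd_perr, dh_se = perr[0], float(perr[1])
    kd = 10.0 ** log_kd
    kd_se = kd * np.log(10.0) * kd_perr  # delta method on log10(Kd)
    dof = max(heats.size - len(popt), 1)
    residual_sd = float(np.sqrt(sse / dof))
    measurable = not (np.isfinite(dh_se) and abs(dh) < 3.0 * dh_se)
    return OneSiteFit(
        Kd_uM=float(kd), Kd_se=float(kd_se),
        dH_kcal=float(dh), dH_se=dh_se,
        n=float(n), n_se=n_se,
        dilution_offset=float(offset),
        converged=True, measurable=measurable,
        residual_sd=residual_sd,
        note="" if measurable else "no measurable binding: |ΔH| < 3×SE",
    )


def thermo_dissection(
    Kd_uM: float, dH_kcal: float, temperature_K: float = T_STANDARD_K
) -> ThermoProfile:
    """ΔG = RT·ln(Kd in molar); −TΔS = ΔG − ΔH; classify the driving force.

    Entropy-driven: the favorable term is dominated by −TΔS (< 0);
    enthalpy-driven: dominated by ΔH (< 0); otherwise mixed.
    """
    if Kd_uM <= 0:
        raise ValueError("Kd must be positive")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    dg = R_KCAL * temperature_K * np.log(Kd_uM * 1e-6)
    minus_tds = dg - dH_kcal
    if abs(minus_tds) > abs(dH_kcal) and minus_tds < 0:
        force = "entropy-driven"
    elif abs(dH_kcal) > abs(minus_tds) and dH_kcal < 0:
        force = "enthalpy-driven"
    else:
        force = "mixed"
    return ThermoProfile(
        dG=float(dg), dH=float(dH_kcal), minusTdS=float(minus_tds),
        temperature_K=float(temperature_K), driving_force=force,
    )


def fold_affinity_change(Kd_a_uM: float, Kd_b_uM: float) -> float:
    """Affinity fold change Kd_a/Kd_b (a 40-fold tighter b gives ≈40)."""
    if Kd_a_uM <= 0 or Kd_b_uM <= 0:
        raise ValueError("dissociation constants must be positive")
    return Kd_a_uM / Kd_b_uM
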
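"""Seeded synthetic datasets for every stage of the pipeline.

Each generator emulates one instrument-data class with known ground-truth
parameters, so that every downstream fit can be validated by parameter
recovery: Michaelis–Menten velocity curves read out through a linear GDP
standard curve with a no-acceptor hydrolysis background, one-site Wiseman
ITC isotherms, mono-exponential STD build-ups, r⁻⁶-scaled NOE initial slopes
with saturation beyond a linear window, and glycopeptide precursor feature
lists with ppm-scale mass error and log-normal intensity scatter.

Noise is multiplicative Gaussian (parameterized by a coefficient of
variation) for kinetics/STD/NOE intensities — matching the roughly
proportional scatter of optical and NMR integrals and keeping values
positive at low CV — and additive Gaussian in heat units for ITC.
Every dataset ships with a ``GroundTruth`` record; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import itc as itc_mod
from . import std as std_mod
from .constants import PROTON_MASS
from .glycoms import BuildingBlockSet, composition_mass, parse_composition
from .kinetics import CalibrationCurve, KineticsDataset, michaelis_menten
from .noesy import NOEBuildUp
from .std import BuildUpSeries

__all__ = [
    "ScenarioConfig",
    "GroundTruth",
    "KineticsSim",
    "TitrationSim",
    "GlycoFeatureSim",
    "gen_kinetics_dataset",
    "gen_itc_titration",
    "gen_std_buildup",
    "gen_noe_buildup",
    "gen_glycopeptide_features",
    "DEFAULT_SAT_TIMES_S",
    "DEFAULT_MIXING_TIMES_MS",
    "DEFAULT_ACCEPTOR_CONCS_UM",
]

#: Saturation times (s) of the STD build-up experiment.
DEFAULT_SAT_TIMES_S = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0)

#: NOESY mixing times (ms).
DEFAULT_MIXING_TIMES_MS = (100, 150, 200, 250, 300, 400, 600, 800, 1000, 1500)

#: Acceptor concentration series spanning 5 μM – 1 mM.
DEFAULT_ACCEPTOR_CONCS_UM = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """Reproducibility knobs shared by all generators."""

    seed: int = 0
    noise_cv: float = 0.03
    replicate_count: int = 2
    output_dir: Path | None = None

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be ≥ 0")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be ≥ 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """True parameters behind a generated dataset, plus any warnings."""

    generator: str
    params: dict
    warnings: list[str] = field(default_factory=list)


@dataclass
class KineticsSim:
    dataset: KineticsDataset
    standard_curve: pd.DataFrame  # gdp_pmol, luminescence
    calibration: CalibrationCurve  # the true curve used to encode signals
    truth: GroundTruth


@dataclass
class TitrationSim:
    series: itc_mod.TitrationSeries
    truth: GroundTruth


@dataclass
class GlycoFeatureSim:
    features: pd.DataFrame
    peptides_by_site: dict[str, tuple[str, float]]
    truth: GroundTruth


def _mult_noise(rng: np.random.Generator, values: np.ndarray, cv: float) -> np.ndarray:
    if cv == 0:
        return values.copy()
    return values * (1.0 + cv * rng.standard_normal(values.shape))


def gen_kinetics_dataset(
    Km: float,
    Vmax: float,
    acceptor_concs=DEFAULT_ACCEPTOR_CONCS_UM,
    hydrolysis_rate: float = 5.0,
    config: ScenarioConfig = ScenarioConfig(),
    substrate_id: str = "substrate",
    cal_slope: float = 2.0,
    cal_intercept: float = 50.0,
    enzyme_conc_nM: float = 100.0,
    enzyme_molar_mass: float = 58000.0,
    incubation_time_min: float = 30.0,
    reaction_volume_uL: float = 10.0,
    linear_in_S: bool = False,
) -> KineticsSim:
    """Luminescence kinetics dataset on a hyperbola plus hydrolysis background.

    Velocities v(S) = Vmax·S/(Km+S) + hydrolysis_rate (all in
    nmol·min⁻¹·mg⁻¹) are encoded into luminescence through a linear GDP
    standard curve; no-acceptor blank rows carry the hydrolysis rate alone.
    ``linear_in_S=True`` instead produces v ∝ S (a non-saturable substrate).
    """
    acceptor_concs = np.asarray(acceptor_concs, dtype=float)
    if acceptor_concs.size == 0 or np.any(acceptor_concs <= 0):
        raise ValueError("acceptor concentrations must be non-empty and positive")
    if Km <= 0 or Vmax < 0:
        raise ValueError("Km must be positive and Vmax non-negative")
    rng = config.rng()

    if linear_in_S:
        v_true = Vmax * acceptor_concs / Km  # the Km→∞ limiting line
    else:
        v_true = michaelis_menten(acceptor_concs, Vmax, Km)
    v_true = v_true + hydrolysis_rate

    nrep = config.replicate_count
    s_all = np.repeat(acceptor_concs, nrep)
    rep_all = np.tile(np.arange(1, nrep + 1), acceptor_concs.size)
    v_noisy = _mult_noise(rng, np.repeat(v_true, nrep), config.noise_cv)
    blank_v = _mult_noise(
        rng, np.full(nrep, hydrolysis_rate, dtype=float), config.noise_cv
    )

    # velocities → pmol GDP per reaction → luminescence
    enzyme_mg = enzyme_conc_nM * 1e-9 * reaction_volume_uL * 1e-6 * enzyme_molar_mass * 1e3
    to_pmol = incubation_time_min * enzyme_mg * 1e3  # nmol → pmol
    cal = CalibrationCurve(slope=cal_slope, intercept=cal_intercept, r_squared=1.0)
    lum = cal_slope * (v_noisy * to_pmol) + cal_intercept
    blank_lum = cal_slope * (blank_v * to_pmol) + cal_intercept

    dataset = KineticsDataset(
        substrate_id=substrate_id, acceptor_conc_uM=s_all, replicate=rep_all,
        luminescence=lum, blank_luminescence=blank_lum,
        enzyme_conc_nM=enzyme_conc_nM, enzyme_molar_mass=enzyme_molar_mass,
        incubation_time_min=incubation_time_min,
        reaction_volume_uL=reaction_volume_uL,
    )

    gdp_pmol = np.linspace(0.0, 1.2 * float(np.max(v_noisy)) * to_pmol, 8)
    sc_lum = cal_slope * gdp_pmol + cal_intercept
    if config.noise_cv > 0:
        sc_lum = sc_lum * (1.0 + config.noise_cv * rng.standard_normal(sc_lum.shape))
    standard_curve = pd.DataFrame({"gdp_pmol": gdp_pmol, "luminescence": sc_lum})

    truth = GroundTruth(
        generator="kinetics",
        params={
            "Km": Km, "Vmax": Vmax, "hydrolysis_rate": hydrolysis_rate,
            "linear_in_S": linear_in_S, "cal_slope": cal_slope,
            "cal_intercept": cal_intercept, "enzyme_molar_mass": enzyme_molar_mass,
            "kcat": Vmax * enzyme_molar_mass * 1e-6,
            "seed": config.seed, "noise_cv": config.noise_cv,
        },
    )
    return KineticsSim(dataset=dataset, standard_curve=standard_curve,
                       calibration=cal, truth=truth)


def gen_itc_titration(
    Kd: float,
    dH: float,
    n: float = 1.0,
    cell_conc: float = 70.0,
    syringe_conc: float = 800.0,
    injections=None,
    cell_volume_uL: float = 200.0,
    dilution_offset: float = 0.0,
    config: ScenarioConfig = ScenarioConfig(),
) -> TitrationSim:
    """One-site Wiseman titration with additive Gaussian heat noise.

    The noise standard deviation is ``noise_cv × max|model heat|`` (additive
    in kcal/mol-of-injectant units). A c-value n·[cell]/Kd outside the
    fittable range [0.01, 10⁴] is recorded as a warning in the ground truth.
    """
    if min(Kd, cell_conc, syringe_conc, cell_volume_uL) <= 0 or n <= 0:
        raise ValueError("Kd, n, concentrations and volumes must be positive")
    if injections is None:
        injections = np.full(19, 2.0)
    injections = np.asarray(injections, dtype=float)
    if injections.size < 10:
        raise ValueError("need ≥ 10 injections")
    rng = config.rng()

    heats = itc_mod.wiseman_heats(
        n, Kd, dH, injections, cell_volume_uL, cell_conc, syringe_conc,
        offset=dilution_offset,
    )
    noise_sd = config.noise_cv * float(np.max(np.abs(heats))) if config.noise_cv else 0.0
    if noise_sd > 0:
        heats = heats + noise_sd * rng.standard_normal(heats.shape)

    warns = []
    c_value = n * cell_conc / Kd
    if not 0.01 <= c_value <= 1e4:
        warns.append(f"c-value {c_value:.3g} outside the fittable range [0.01, 1e4]")

    series = itc_mod.TitrationSeries(
        injection_volumes_uL=injections, heats=heats,
        cell_volume_uL=cell_volume_uL, cell_conc_uM=cell_conc,
        syringe_conc_uM=syringe_conc,
    )
    truth = GroundTruth(
        generator="itc",
        params={
            "Kd": Kd, "dH": dH, "n": n, "dilution_offset": dilution_offset,
            "c_value": c_value, "noise_sd": noise_sd, "seed": config.seed,
        },
        warnings=warns,
    )
    return TitrationSim(series=series, truth=truth)


def gen_std_buildup(
    protons: list[str],
    STDmax: list[float],
    ksat: list[float],
    sat_times=DEFAULT_SAT_TIMES_S,
    condition: str = "apo",
    config: ScenarioConfig = ScenarioConfig(),
) -> tuple[list[BuildUpSeries], GroundTruth]:
    """Mono-exponential STD build-up curves, one per proton."""
    sat_times = np.asarray(sat_times, dtype=float)
    if sat_times.size < 4 or np.any(sat_times <= 0):
        raise ValueError("need ≥ 4 positive saturation times")
    if not len(protons) == len(STDmax) == len(ksat):
        raise ValueError("protons, STDmax and ksat must align")
    rng = config.rng()
    series = []
    for pid, amax, k in zip(protons, STDmax, ksat):
        amp = std_mod.std_buildup(sat_times, amax, k)
        amp = np.clip(_mult_noise(rng, amp, config.noise_cv), 0.0, None)
        series.append(
            BuildUpSeries(proton_id=pid, condition=condition,
                          sat_times_s=sat_times.copy(), std_amplitude=amp)
        )
    truth = GroundTruth(
        generator="std",
        params={
            "protons": list(protons), "STDmax": list(map(float, STDmax)),
            "ksat": list(map(float, ksat)),
            "buildup_rate": [float(a * k) for a, k in zip(STDmax, ksat)],
            "condition": condition, "seed": config.seed, "noise_cv": config.noise_cv,
        },
    )
    return series, truth


def noe_curve(
    tau_ms: np.ndarray, slope: float, linear_window_ms: float, tau_damp_ms: float
) -> np.ndarray:
    """Build-up curve: exactly linear to ``linear_window_ms``, then saturating.

    C1-continuous: I(τ) = s·τ for τ ≤ L, and
    I(τ) = s·L + s·τd·(1 − exp(−(τ−L)/τd)) beyond. The initial slope is s.
    """
    tau = np.asarray(tau_ms, dtype=float)
    lin = slope * tau
    sat = slope * linear_window_ms + slope * tau_damp_ms * (
        1.0 - np.exp(-(tau - linear_window_ms) / tau_damp_ms)
    )
    return np.where(tau <= linear_window_ms, lin, sat)


def gen_noe_buildup(
    pairs: list[str],
    distances: list[float],
    ref_pair: str,
    ref_distance: float,
    mixing_times=DEFAULT_MIXING_TIMES_MS,
    ref_slope: float = 1.0,
    linear_window_ms: float = 300.0,
    tau_damp_ms: float = 50.0,
    config: ScenarioConfig = ScenarioConfig(),
) -> tuple[list[NOEBuildUp], GroundTruth]:
    """NOE build-ups with initial slopes ∝ r⁻⁶ and saturation past a window.

    ``ref_pair`` (at ``ref_distance``) gets slope ``ref_slope``; every other
    pair's slope is scaled by (r_ref/r)⁶.
    """
    if ref_pair not in pairs:
        raise ValueError("ref_pair must be among pairs")
    if any(d <= 0 for d in distances) or ref_distance <= 0:
        raise ValueError("distances must be positive")
    mixing_times = np.asarray(mixing_times, dtype=float)
    rng = config.rng()
    out = []
    slopes = {}
    for pid, r in zip(pairs, distances):
        s = ref_slope * (ref_distance / r) ** 6
        slopes[pid] = s
        integ = noe_curve(mixing_times, s, linear_window_ms, tau_damp_ms)
        integ = _mult_noise(rng, integ, config.noise_cv)
        out.append(NOEBuildUp(pair_id=pid, mixing_times_ms=mixing_times.copy(),
                              integrals=integ))
    truth = GroundTruth(
        generator="noesy",
        params={
            "pairs": list(pairs), "distances": list(map(float, distances)),
            "ref_pair": ref_pair, "ref_distance": float(ref_distance),
            "slopes": slopes, "linear_window_ms": linear_window_ms,
            "tau_damp_ms": tau_damp_ms, "seed": config.seed,
            "noise_cv": config.noise_cv,
        },
    )
    return out, truth


def gen_glycopeptide_features(
    site_profiles: dict[str, dict[str, float]],
    peptide_masses: dict[str, float],
    ppm_error_sd: float = 0.0,
    charge_states=(2, 3),
    base_intensity: float = 1e8,
    intensity_sigma: float = 0.0,
    blocks: BuildingBlockSet | None = None,
    config: ScenarioConfig = ScenarioConfig(),
) -> GlycoFeatureSim:
    """Precursor feature table built from known per-site glycoform fractions.

    ``site_profiles`` maps glycosite → {composition string: fraction}
    (fractions must sum to 1); ``peptide_masses`` maps glycosite → backbone
    peptide monoisotopic mass (Da). Each glycoform appears at every charge
    state with its intensity split across charges; intensities get optional
    log-normal scatter (``intensity_sigma`` in log units) and m/z values a
    Gaussian error of ``ppm_error_sd`` ppm.
    """
    blocks = blocks or BuildingBlockSet()
    rng = config.rng()
    charge_states = tuple(int(z) for z in charge_states)
    # deterministic split of a glycoform's intensity across its charge states
    charge_weights = np.array([0.7, 0.3][: len(charge_states)], dtype=float)
    if charge_weights.size < len(charge_states):
        charge_weights = np.ones(len(charge_states))
    charge_weights = charge_weights / charge_weights.sum()

    rows = []
    peptides_by_site = {}
    truth_fracs = {}
    fid = 0
    for site, profile in site_profiles.items():
        total = sum(profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions at site {site!r} sum to {total}, not 1")
        pep_mass = float(peptide_masses[site])
        peptides_by_site[site] = (f"pep_{site}", pep_mass)
        truth_fracs[site] = dict(profile)
        for comp_text, frac in profile.items():
            counts = parse_composition(comp_text, blocks)  # rejects unknown blocks
            theo = pep_mass + composition_mass(counts, blocks)
            scale = 1.0
            if intensity_sigma > 0:
                scale = float(np.exp(intensity_sigma * rng.standard_normal()))
            for z, w in zip(charge_states, charge_weights):
                mz = (theo + z * PROTON_MASS) / z
                if ppm_error_sd > 0:
                    mz = mz * (1.0 + ppm_error_sd * 1e-6 * rng.standard_normal())
                fid += 1
                rows.append(
                    {
                        "feature_id": f"F{fid:04d}",
                        "mz": mz,
                        "charge": z,
                        "rt_min": round(20.0 + 0.01 * fid, 3),
                        "intensity": base_intensity * frac * scale * w,
                        "sample_id": "synthetic",
                        "glycosite": site,
                    }
                )
    features = pd.DataFrame(rows)
    truth = GroundTruth(
        generator="glycoms",
        params={
            "site_profiles": truth_fracs,
            "peptide_masses": dict(peptide_masses),
            "ppm_error_sd": ppm_error_sd,
            "charge_states": list(charge_states),
            "seed": config.seed,
        },
    )
    return GlycoFeatureSim(features=features, peptides_by_site=peptides_by_site,
                           truth=truth)
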
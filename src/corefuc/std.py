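"""STD-NMR build-up analysis and ligand binding-epitope mapping.

Each ligand proton's saturation-transfer-difference amplitude grows with
saturation time as the mono-exponential

    STD(t) = STDmax · (1 − exp(−ksat·t))

and the epitope map is built from the build-up *rates* STDmax·ksat — the
initial slopes — rather than single-time STD values, which removes the bias
from unequal proton T1 relaxation. Rates are normalized so that the largest
equals 100%; protons closer to the protein surface show larger values.
Overlapping resonances (e.g. two GlcNAc rings whose signals coincide) are
combined into one pseudo-proton before fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "BuildUpSeries",
    "BuildUpFit",
    "EpitopeMap",
    "std_buildup",
    "fit_buildup",
    "merge_overlapping",
    "build_epitope_map",
    "compare_conditions",
]


def std_buildup(t, std_max, ksat):
    """Mono-exponential STD build-up curve."""
    t = np.asarray(t, dtype=float)
    return std_max * (1.0 - np.exp(-ksat * t))


@dataclass
class BuildUpSeries:
    """STD amplitude versus saturation time for one proton (or merged group)."""

    proton_id: str
    condition: str  # "apo" or "plus_GDP"
    sat_times_s: np.ndarray
    std_amplitude: np.ndarray
    merged_group: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.sat_times_s = np.asarray(self.sat_times_s, dtype=float)
        self.std_amplitude = np.asarray(self.std_amplitude, dtype=float)
        if np.any(np.diff(self.sat_times_s) <= 0):
            raise ValueError("saturation times must be strictly increasing")
        if np.any(self.std_amplitude < 0):
            raise ValueError("STD amplitudes must be non-negative")
        if self.sat_times_s.size != self.std_amplitude.size:
            raise ValueError("time and amplitude lengths differ")


@dataclass
class BuildUpFit:
    proton_id: str
    condition: str
    std_max: float
    std_max_se: float
    ksat: float  # s⁻¹
    ksat_se: float
    buildup_rate: float  # STDmax·ksat, s⁻¹ (initial slope)
    null: bool = False  # no build-up observed
    residual_sd: float = np.nan


@dataclass
class EpitopeMap:
    """Normalized build-up rates per proton for one condition (max = 100%)."""

    condition: str
    rates: pd.DataFrame  # index proton_id; columns std_max, ksat, buildup_rate, normalized_pct
    reference_proton: str

    def normalized(self) -> "EpitopeMap":
        """Re-normalize (idempotent: the map is already scaled to max 100)."""
        df = self.rates.copy()
        df["normalized_pct"] = 100.0 * df["buildup_rate"] / df["buildup_rate"].max()
        return EpitopeMap(self.condition, df, df["buildup_rate"].idxmax())


def fit_buildup(series: BuildUpSeries) -> BuildUpFit:
    """Least-squares fit of STDmax·(1 − e^(−ksat·t)) to one build-up series.

    A series with no overall growth (flat or decreasing amplitudes) is
    flagged null rather than fitted.
    """
    t, a = series.sat_times_s, series.std_amplitude
    if t.size < 4:
        raise ValueError("need ≥ 4 saturation times")
    if np.max(a) <= 0 or a[-1] < a[0]:
        return BuildUpFit(
            proton_id=series.proton_id, condition=series.condition,
            std_max=0.0, std_max_se=np.nan, ksat=0.0, ksat_se=np.nan,
            buildup_rate=0.0, null=True,
        )

    a_max = float(np.max(a))
    half_idx = np.argmax(a >= a_max / 2.0)
    ksat0 = 1.0 / t[half_idx] if t[half_idx] > 0 else 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                std_buildup, t, a, p0=[a_max, ksat0],
                bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000,
            )
    except RuntimeError as exc:
        raise RuntimeError(
            f"build-up fit for {series.proton_id} did not converge: {exc}"
        ) from exc
    std_max, ksat = popt
    perr = np.sqrt(np.diag(pcov))
    resid = a - std_buildup(t, *popt)
    return BuildUpFit(
        proton_id=series.proton_id, condition=series.condition,
        std_max=float(std_max), std_max_se=float(perr[0]),
        ksat=float(ksat), ksat_se=float(perr[1]),
        buildup_rate=float(std_max * ksat),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
    )


def merge_overlapping(
    series_list: list[BuildUpSeries], group: list[str], mode: str = "sum"
) -> BuildUpSeries:
    """Combine overlapping protons into one pseudo-proton series.

    ``mode='sum'`` adds amplitudes pointwise (the convention for overlapped
    STD integrals); ``mode='mean'`` averages them. All members must share
    the condition and the saturation-time grid.
    """
    members = [s for s in series_list if s.proton_id in group]
    if len(members) != len(group):
        missing = set(group) - {s.proton_id for s in members}
        raise ValueError(f"group members not found: {sorted(missing)}")
    ref = members[0]
    for s in members[1:]:
        if s.condition != ref.condition:
            raise ValueError("cannot merge series from different conditions")
        if not np.array_equal(s.sat_times_s, ref.sat_times_s):
            raise ValueError("cannot merge series on mismatched time grids")
    stacked = np.vstack([s.std_amplitude for s in members])
    combined = stacked.sum(axis=0) if mode == "sum" else stacked.mean(axis=0)
    if mode not in ("sum", "mean"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    return BuildUpSeries(
        proton_id="+".join(group), condition=ref.condition,
        sat_times_s=ref.sat_times_s.copy(), std_amplitude=combined,
        merged_group=list(group),
    )


def build_epitope_map(fits: list[BuildUpFit], condition: str) -> EpitopeMap:
    """Normalize build-up rates to the strongest proton (assigned 100%)."""
    live = [f for f in fits if f.condition == condition and not f.null]
    if not live:
        raise ValueError(f"no non-null build-up fits for condition {condition!r}")
    df = pd.DataFrame(
        {
            "std_max": [f.std_max for f in live],
            "ksat": [f.ksat for f in live],
            "buildup_rate": [f.buildup_rate for f in live],
        },
        index=pd.Index([f.proton_id for f in live], name="proton_id"),
    )
    df["normalized_pct"] = 100.0 * df["buildup_rate"] / df["buildup_rate"].max()
    return EpitopeMap(condition=condition, rates=df,
                      reference_proton=str(df["buildup_rate"].idxmax()))


def compare_conditions(map_apo: EpitopeMap, map_gdp: EpitopeMap) -> dict:
    """Per-proton change in STD build-up between apo and +GDP conditions.

    Returns a table of raw-rate ratios/differences and normalized-percentage
    deltas over the shared protons, the protons present in only one map, and
    an ``all_increase`` flag set when every shared proton's raw rate rises.
    """
    shared = map_apo.rates.index.intersection(map_gdp.rates.index)
    if shared.empty:
        raise ValueError("the two epitope maps share no protons")
    apo = map_apo.rates.loc[shared]
    gdp = map_gdp.rates.loc[shared]
    table = pd.DataFrame(
        {
            "rate_apo": apo["buildup_rate"],
            "rate_gdp": gdp["buildup_rate"],
            "rate_ratio": gdp["buildup_rate"] / apo["buildup_rate"],
            "rate_delta": gdp["buildup_rate"] - apo["buildup_rate"],
            "normalized_delta_pct": gdp["normalized_pct"] - apo["normalized_pct"],
        }
    )
    excluded = sorted(
        set(map_apo.rates.index).symmetric_difference(map_gdp.rates.index)
    )
    return {
        "table": table,
        "excluded_protons": excluded,
        "all_increase": bool((table["rate_delta"] > 0).all()),
    }
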
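"""NOESY initial-slope extraction and ISPA inter-proton distances.

In the initial-rate regime the NOESY cross-peak integral of a proton pair
grows linearly with mixing time, with slope proportional to the
cross-relaxation rate σ ∝ r⁻⁶. Under the isolated spin pair approximation
(ISPA) an unknown distance follows from a reference pair of known distance:

    r = r_ref · (σ_ref / σ)^(1/6)

The "linear initial part" of each build-up curve is chosen automatically as
the largest prefix of mixing times whose ordinary-least-squares line has
R² ≥ 0.99 (at least 3 points); beyond that window spin diffusion and
relaxation bend the curve. The chitobiose glycosidic ψ conformation is
called by comparing measured distances with user-supplied expected values
for the syn and anti rotamers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NOEBuildUp",
    "SlopeEstimate",
    "DistanceEstimate",
    "ConformerCall",
    "initial_slope",
    "ispa_distance",
    "distances_from_buildups",
    "call_conformer",
]


@dataclass
class NOEBuildUp:
    """Cross-peak integral versus mixing time for one proton pair."""

    pair_id: str
    mixing_times_ms: np.ndarray
    integrals: np.ndarray

    def __post_init__(self):
        self.mixing_times_ms = np.asarray(self.mixing_times_ms, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if self.mixing_times_ms.size < 4:
            raise ValueError("need ≥ 4 mixing times")
        if np.any(np.diff(self.mixing_times_ms) <= 0):
            raise ValueError("mixing times must be strictly increasing")
        if self.mixing_times_ms.size != self.integrals.size:
            raise ValueError("mixing times and integrals differ in length")


@dataclass
class SlopeEstimate:
    pair_id: str
    slope: float  # integral units per ms
    slope_se: float
    window_ms: tuple[float, float]
    n_points: int
    r_squared: float
    flagged: bool = False  # negative or zero slope
    note: str = ""


@dataclass(frozen=True)
class DistanceEstimate:
    pair_id: str
    slope: float
    reference_pair: str
    reference_distance_A: float
    distance_A: float
    linear_window_ms: tuple[float, float]


@dataclass(frozen=True)
class ConformerCall:
    linkage: str
    call: str  # syn | anti | ambiguous
    evidence: tuple  # (pair_id, distance, expected_syn, expected_anti, vote)


def initial_slope(
    buildup: NOEBuildUp,
    window_ms: tuple[float, float] | None = None,
    r2_threshold: float = 0.99,
) -> SlopeEstimate:
    """OLS slope of the linear initial part of a NOE build-up curve.

    With ``window_ms=None`` the window is chosen automatically as the largest
    prefix of points whose linear fit has R² ≥ ``r2_threshold`` (minimum 3
    points). An explicit window restricts the fit to mixing times inside it.
    """
    t, y = buildup.mixing_times_ms, buildup.integrals

    if np.allclose(y, 0.0):
        return SlopeEstimate(
            pair_id=buildup.pair_id, slope=0.0, slope_se=0.0,
            window_ms=(float(t[0]), float(t[-1])), n_points=t.size,
            r_squared=0.0, flagged=True, note="all-zero integrals",
        )

    if window_ms is not None:
        mask = (t >= window_ms[0]) & (t <= window_ms[1])
        if mask.sum() < 3:
            raise ValueError("fewer than 3 points inside the requested window")
        idx = np.flatnonzero(mask)
    else:
        best = None
        for k in range(3, t.size + 1):
            res = stats.linregress(t[:k], y[:k])
            r2 = res.rvalue**2
            if r2 >= r2_threshold:
                best = np.arange(k)
        if best is None:
            best = np.arange(3)  # shortest admissible window, reported as-is
        idx = best

    res = stats.linregress(t[idx], y[idx])
    flagged = res.slope <= 0
    return SlopeEstimate(
        pair_id=buildup.pair_id, slope=float(res.slope),
        slope_se=float(res.stderr), window_ms=(float(t[idx[0]]), float(t[idx[-1]])),
        n_points=int(idx.size), r_squared=float(res.rvalue**2),
        flagged=flagged, note="non-positive slope" if flagged else "",
    )


def ispa_distance(slope: float, ref_slope: float, ref_distance_A: float) -> float:
    """r = r_ref · (σ_ref/σ)^(1/6) — strictly decreasing in the pair's slope."""
    if slope <= 0 or ref_slope <= 0:
        raise ValueError("ISPA requires strictly positive slopes")
    if ref_distance_A <= 0:
        raise ValueError("reference distance must be positive")
    return float(ref_distance_A * (ref_slope / slope) ** (1.0 / 6.0))


def distances_from_buildups(
    buildups: list[NOEBuildUp],
    ref_pair: str,
    ref_distance_A: float,
    window_ms: tuple[float, float] | None = None,
    r2_threshold: float = 0.99,
) -> list[DistanceEstimate]:
    """Slopes for every pair, then ISPA distances referenced to ``ref_pair``."""
    slopes = {
        b.pair_id: initial_slope(b, window_ms=window_ms, r2_threshold=r2_threshold)
        for b in buildups
    }
    if ref_pair not in slopes:
        raise ValueError(f"reference pair {ref_pair!r} not among build-ups")
    ref = slopes[ref_pair]
    out = []
    for pid, est in slopes.items():
        if pid == ref_pair or est.flagged:
            continue
        out.append(
            DistanceEstimate(
                pair_id=pid, slope=est.slope, reference_pair=ref_pair,
                reference_distance_A=ref_distance_A,
                distance_A=ispa_distance(est.slope, ref.slope, ref_distance_A),
                linear_window_ms=est.window_ms,
            )
        )
    return out


def call_conformer(
    distances: list[DistanceEstimate],
    reference_geometry: dict[str, tuple[float, float]],
    linkage: str = "GlcNAc-b1,4-GlcNAc",
    tolerance_A: float = 0.5,
) -> ConformerCall:
    """Vote syn/anti per pair by nearest expected distance; unanimity decides.

    ``reference_geometry`` maps pair_id → (expected_syn_Å, expected_anti_Å).
    A pair farther than ``tolerance_A`` from both expectations, or a split
    vote, yields an ambiguous call.
    """
    usable = [d for d in distances if d.pair_id in reference_geometry]
    if not usable:
        raise ValueError("no distance has reference geometry expectations")
    votes, evidence = [], []
    for d in usable:
        exp_syn, exp_anti = reference_geometry[d.pair_id]
        dev_syn, dev_anti = abs(d.distance_A - exp_syn), abs(d.distance_A - exp_anti)
        if min(dev_syn, dev_anti) > tolerance_A:
            vote = "ambiguous"
        else:
            vote = "syn" if dev_syn <= dev_anti else "anti"
        votes.append(vote)
        evidence.append((d.pair_id, d.distance_A, exp_syn, exp_anti, vote))
    call = votes[0] if len(set(votes)) == 1 and votes[0] != "ambiguous" else "ambiguous"
    return ConformerCall(linkage=linkage, call=call, evidence=tuple(evidence))
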
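"""Site-specific glycopeptide composition assignment and fucosylation reports.

Precursor features (m/z, charge, intensity) are mapped to glycopeptide
compositions by bounded combinatorial decomposition of the neutral mass over
monosaccharide building blocks (Hex, HexNAc, dHex, NeuAc, phosphate) on top
of candidate peptide backbones, within a ppm mass tolerance. Glycosite
peptides are identified from the gain in deamidated (+0.98402 Da) peptide
yield after PNGase F treatment. Per-site reports quantify glycoform fractions
over the top-N most intense assigned features; the core-fucosylated fraction
is the intensity share of compositions containing ≥ 1 dHex (fucose).

Compositions, not structures: isobaric structural isomers cannot be told
apart at the precursor level, so structure labels are annotation only.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as pyt_mass

from .constants import (
    BLOCK_MASSES,
    BLOCK_ORDER,
    DEAMIDATION_SHIFT,
    DEFAULT_BLOCK_BOUNDS,
    PROTON_MASS,
    WATER_MASS,
)

__all__ = [
    "BuildingBlockSet",
    "PrecursorFeature",
    "GlycopeptideAssignment",
    "GlycositeReport",
    "neutral_mass",
    "peptide_mass",
    "composition_mass",
    "parse_composition",
    "composition_label",
    "decompose_mass",
    "assign_features",
    "detect_glycosite_peptides",
    "site_report",
]

_COMP_TOKEN = re.compile(r"(HexNAc|Hex|dHex|NeuAc|Phospho|GlcNAc|Fuc|Man)(\d*)")


@dataclass(frozen=True)
class BuildingBlockSet:
    """Monosaccharide building blocks with residue masses and count bounds."""

    masses: dict[str, float] = field(default_factory=lambda: dict(BLOCK_MASSES))
    bounds: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BLOCK_BOUNDS))

    def __post_init__(self):
        for name, m in self.masses.items():
            if m <= 0:
                raise ValueError(f"block {name!r} has non-positive mass")
        for name, b in self.bounds.items():
            if name not in self.masses:
                raise ValueError(f"bound given for unknown block {name!r}")
            if b < 0:
                raise ValueError(f"block {name!r} has negative bound")

    @property
    def order(self) -> tuple[str, ...]:
        known = [b for b in BLOCK_ORDER if b in self.masses]
        extra = sorted(set(self.masses) - set(known))
        return tuple(known + extra)


@dataclass(frozen=True)
class PrecursorFeature:
    feature_id: str
    mz: float
    charge: int
    retention_time_min: float
    intensity: float
    sample_id: str = ""
    glycosite: str = ""

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("charge must be ≥ 1")


@dataclass(frozen=True)
class GlycopeptideAssignment:
    feature_id: str
    glycosite: str
    peptide_id: str
    peptide_mass: float
    composition: tuple[tuple[str, int], ...]  # canonical block order, zero counts kept
    theoretical_mass: float
    observed_mass: float
    ppm_error: float
    intensity: float

    @property
    def composition_dict(self) -> dict[str, int]:
        return dict(self.composition)

    @property
    def fucosylated(self) -> bool:
        return self.composition_dict.get("dHex", 0) >= 1


@dataclass
class GlycositeReport:
    site_id: str
    top_assignments: list[GlycopeptideAssignment]
    glycoform_fractions: pd.DataFrame  # index glycoform label; columns intensity, fraction, fucosylated
    fucosylated_fraction: float
    top_n: int


def neutral_mass(mz: float, charge: int) -> float:
    """Neutral monoisotopic mass from an [M+zH]^z+ species: m/z·z − z·m(H+)."""
    if charge < 1:
        raise ValueError("charge must be ≥ 1")
    return mz * charge - charge * PROTON_MASS


def peptide_mass(sequence: str) -> float:
    """Monoisotopic peptide mass: sum of residue masses + water."""
    total = WATER_MASS
    for aa in sequence:
        try:
            total += pyt_mass.std_aa_mass[aa]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue {aa!r}") from None
    return total


def parse_composition(text: str, blocks: BuildingBlockSet | None = None) -> dict[str, int]:
    """Parse 'Hex5HexNAc2dHex1' (aliases: Man→Hex, Fuc→dHex) into counts."""
    blocks = blocks or BuildingBlockSet()
    alias = {"Man": "Hex", "Fuc": "dHex", "GlcNAc": "HexNAc"}
    counts: dict[str, int] = {}
    pos = 0
    for m in _COMP_TOKEN.finditer(text.replace("-", "")):
        if m.start() != pos:
            raise ValueError(
                f"cannot parse composition {text!r}: unknown building block or malformed counts"
            )
        name = alias.get(m.group(1), m.group(1))
        if name not in blocks.masses:
            raise ValueError(f"unknown building block {m.group(1)!r} in {text!r}")
        counts[name] = counts.get(name, 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(text.replace("-", "")) or not counts:
        raise ValueError(
                f"cannot parse composition {text!r}: unknown building block or malformed counts"
            )
    return counts


def composition_mass(counts: dict[str, int], blocks: BuildingBlockSet | None = None) -> float:
    blocks = blocks or BuildingBlockSet()
    total = 0.0
    for name, k in counts.items():
        if name not in blocks.masses:
            raise ValueError(f"unknown building block {name!r}")
        total += k * blocks.masses[name]
    return total


def composition_label(counts: dict[str, int]) -> str:
    """Human-readable glycoform label, e.g. {Hex:5, HexNAc:2, dHex:1} → 'Man5-GlcNAc2-Fuc'."""
    trivial = {"Hex": "Man", "HexNAc": "GlcNAc", "dHex": "Fuc",
               "NeuAc": "NeuAc", "Phospho": "P"}
    parts = []
    for name in BLOCK_ORDER:
        k = counts.get(name, 0)
        if k == 0:
            continue
        parts.append(trivial[name] + (str(k) if k > 1 else ""))
    return "-".join(parts) if parts else "unglycosylated"


def _canonical(counts: dict[str, int], order: tuple[str, ...]) -> tuple[tuple[str, int], ...]:
    return tuple((name, counts.get(name, 0)) for name in order)


def decompose_mass(
    observed_mass: float,
    peptide_candidates: list[tuple[str, float]],
    blocks: BuildingBlockSet | None = None,
    tolerance_ppm: float = 5.0,
    max_nodes: int = 1_000_000,
) -> list[dict]:
    """All building-block compositions matching an observed neutral mass.

    For every candidate peptide (id, mass), enumerates compositions with
    |10⁶·(observed − theoretical)/theoretical| ≤ ``tolerance_ppm`` by
    depth-first search over block counts with branch-and-bound pruning on
    the remaining mass. Results are ranked by |ppm error|, ties broken by
    the lexicographic composition vector — fully deterministic.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    blocks = blocks or BuildingBlockSet()
    order = blocks.order
    masses = [blocks.masses[b] for b in order]
    bounds = [blocks.bounds.get(b, 0) for b in order]
    # max additional mass attainable from blocks i..end
    suffix_max = [0.0] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * bounds[i]

    tol = tolerance_ppm * 1e-6
    # theoretical mass must lie in [observed/(1+tol), observed/(1−tol)]
    lo = observed_mass / (1.0 + tol)
    hi = observed_mass / (1.0 - tol)

    results: list[dict] = []
    nodes = 0

    for pep_id, pep_mass in peptide_candidates:
        counts = [0] * len(order)

        def dfs(i: int, partial: float):
            nonlocal nodes
            nodes += 1
            if nodes > max_nodes:
                raise RuntimeError(
                    "composition enumeration exceeded node budget; tighten block bounds"
                )
            if partial > hi:
                return
            if i == len(order):
                if lo <= partial <= hi:
                    theo = partial
                    ppm = 1e6 * (observed_mass - theo) / theo
                    results.append(
                        {
                            "peptide_id": pep_id,
                            "peptide_mass": pep_mass,
                            "composition": _canonical(
                                dict(zip(order, counts)), order
                            ),
                            "theoretical_mass": theo,
                            "ppm_error": ppm,
                        }
                    )
                return
            if partial + suffix_max[i] < lo:
                return  # even maxed-out remaining blocks cannot reach the window
            for k in range(bounds[i] + 1):
                counts[i] = k
                dfs(i + 1, partial + k * masses[i])
            counts[i] = 0

        dfs(0, pep_mass)

    results.sort(key=lambda r: (abs(r["ppm_error"]), tuple(k for _, k in r["composition"])))
    return results


def assign_features(
    features: list[PrecursorFeature] | pd.DataFrame,
    peptides_by_site: dict[str, tuple[str, float]],
    blocks: BuildingBlockSet | None = None,
    tolerance_ppm: float = 5.0,
) -> list[GlycopeptideAssignment]:
    """Assign each feature the best in-tolerance composition for its glycosite.

    ``peptides_by_site`` maps glycosite → (peptide_id, peptide monoisotopic
    mass). Features whose site has no candidate peptide, or with no
    in-tolerance composition, are skipped.
    """
    if isinstance(features, pd.DataFrame):
        features = [
            PrecursorFeature(
                feature_id=str(r.feature_id), mz=float(r.mz), charge=int(r.charge),
                retention_time_min=float(getattr(r, "rt_min", 0.0)),
                intensity=float(r.intensity),
                sample_id=str(getattr(r, "sample_id", "")),
                glycosite=str(r.glycosite),
            )
            for r in features.itertuples(index=False)
        ]
    blocks = blocks or BuildingBlockSet()
    out = []
    for feat in features:
        if feat.glycosite not in peptides_by_site:
            continue
        pep_id, pep_mass = peptides_by_site[feat.glycosite]
        obs = neutral_mass(feat.mz, feat.charge)
        cands = decompose_mass(obs, [(pep_id, pep_mass)], blocks, tolerance_ppm)
        if not cands:
            continue
        best = cands[0]
        out.append(
            GlycopeptideAssignment(
                feature_id=feat.feature_id, glycosite=feat.glycosite,
                peptide_id=pep_id, peptide_mass=pep_mass,
                composition=best["composition"],
                theoretical_mass=best["theoretical_mass"],
                observed_mass=obs, ppm_error=best["ppm_error"],
                intensity=feat.intensity,
            )
        )
    return out


def detect_glycosite_peptides(
    before: pd.DataFrame,
    after_pngasef: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag peptides whose deamidated yield rises after PNGase F treatment.

    Both tables need columns ``peptide_id``, ``is_deamidated`` (bool) and
    ``intensity``. PNGase F converts the glycosylated Asn to Asp
    (+0.98402 Da), so a glycosite peptide's deamidated form gains intensity
    after treatment. Peptides lacking a deamidated row in either table are
    skipped with a warning.
    """
    def deam_yield(df: pd.DataFrame) -> pd.Series:
        d = df[df["is_deamidated"]].groupby("peptide_id")["intensity"].sum()
        return d

    y_before, y_after = deam_yield(before), deam_yield(after_pngasef)
    all_ids = sorted(set(before["peptide_id"]) | set(after_pngasef["peptide_id"]))
    rows, skipped = [], []
    for pid in all_ids:
        if pid not in y_before.index or pid not in y_after.index:
            skipped.append(pid)
            continue
        b, a = float(y_before[pid]), float(y_after[pid])
        ratio = np.inf if b == 0 and a > 0 else (a / b if b > 0 else 1.0)
        rows.append(
            {
                "peptide_id": pid,
                "deamidated_before": b,
                "deamidated_after": a,
                "fold_increase": ratio,
                "is_glycosite": bool(ratio > fold_threshold),
            }
        )
    if skipped:
        warnings.warn(
            f"skipped peptides lacking deamidated rows: {skipped}", stacklevel=2
        )
    return pd.DataFrame(rows)


def site_report(
    assignments: list[GlycopeptideAssignment], site_id: str, top_n: int = 5
) -> GlycositeReport:
    """Glycoform fractions at one site over the top-N most intense assignments.

    Features are ranked by intensity; the top-N define the denominator
    ("total"). Intensities of features sharing a composition are summed into
    one glycoform row. The fucosylated fraction is the share of glycoforms
    carrying ≥ 1 dHex.
    """
    site = [a for a in assignments if a.glycosite == site_id]
    if not site:
        raise ValueError(f"no assignments for glycosite {site_id!r}")
    top = sorted(site, key=lambda a: -a.intensity)[:top_n]
    total = sum(a.intensity for a in top)
    rows: dict[str, dict] = {}
    for a in top:
        label = composition_label(a.composition_dict)
        row = rows.setdefault(
            label, {"intensity": 0.0, "fucosylated": a.fucosylated}
        )
        row["intensity"] += a.intensity
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "glycoform"
    df["fraction"] = df["intensity"] / total
    df = df.sort_values("fraction", ascending=False)
    fuc = float(df.loc[df["fucosylated"], "fraction"].sum())
    return GlycositeReport(
        site_id=site_id, top_assignments=top, glycoform_fractions=df,
        fucosylated_fraction=fuc, top_n=top_n,
    )
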
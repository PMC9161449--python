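"""Plain-text dataset I/O: TSV tables plus JSON ground-truth/metadata sidecars.

Column conventions
------------------
kinetics      substrate_id, acceptor_conc_uM, replicate, luminescence, is_blank
standard      gdp_pmol, luminescence
itc           injection_index, injection_volume_uL, heat_kcal_per_mol
              (+ JSON sidecar: cell_volume_uL, cell_conc_uM, syringe_conc_uM,
               temperature_K)
std           proton_id, condition, sat_time_s, std_amplitude
noesy         pair_id, mixing_time_ms, integral
features      feature_id, mz, charge, rt_min, intensity, sample_id, glycosite
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .itc import TitrationSeries
from .kinetics import KineticsDataset
from .noesy import NOEBuildUp
from .std import BuildUpSeries
from .synthetic import GroundTruth

__all__ = [
    "write_ground_truth",
    "read_ground_truth",
    "kinetics_to_tsv",
    "kinetics_from_tsv",
    "itc_to_tsv",
    "itc_from_tsv",
    "std_to_tsv",
    "std_from_tsv",
    "noesy_to_tsv",
    "noesy_from_tsv",
]

_FLOAT_FMT = "%.10g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = dataclasses.asdict(truth)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(**payload)


def kinetics_to_tsv(dataset: KineticsDataset, path: str | Path) -> None:
    sig = pd.DataFrame(
        {
            "substrate_id": dataset.substrate_id,
            "acceptor_conc_uM": dataset.acceptor_conc_uM,
            "replicate": dataset.replicate,
            "luminescence": dataset.luminescence,
            "is_blank": 0,
        }
    )
    blank = pd.DataFrame(
        {
            "substrate_id": dataset.substrate_id,
            "acceptor_conc_uM": 0.0,
            "replicate": np.arange(1, dataset.blank_luminescence.size + 1),
            "luminescence": dataset.blank_luminescence,
            "is_blank": 1,
        }
    )
    _write_tsv(pd.concat([sig, blank], ignore_index=True), Path(path))


def kinetics_from_tsv(path: str | Path, **metadata) -> KineticsDataset:
    """Load a kinetics TSV; assay metadata (enzyme conc etc.) via keywords."""
    df = pd.read_csv(path, sep="\t")
    sig = df[df["is_blank"] == 0]
    blank = df[df["is_blank"] == 1]
    return KineticsDataset(
        substrate_id=str(sig["substrate_id"].iloc[0]),
        acceptor_conc_uM=sig["acceptor_conc_uM"].to_numpy(float),
        replicate=sig["replicate"].to_numpy(),
        luminescence=sig["luminescence"].to_numpy(float),
        blank_luminescence=blank["luminescence"].to_numpy(float),
        **metadata,
    )


def itc_to_tsv(series: TitrationSeries, path: str | Path) -> None:
    p = Path(path)
    _write_tsv(
        pd.DataFrame(
            {
                "injection_index": np.arange(1, series.heats.size + 1),
                "injection_volume_uL": series.injection_volumes_uL,
                "heat_kcal_per_mol": series.heats,
            }
        ),
        p,
    )
    meta = {
        "cell_volume_uL": series.cell_volume_uL,
        "cell_conc_uM": series.cell_conc_uM,
        "syringe_conc_uM": series.syringe_conc_uM,
        "temperature_K": series.temperature_K,
    }
    p.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def itc_from_tsv(path: str | Path) -> TitrationSeries:
    p = Path(path)
    df = pd.read_csv(p, sep="\t")
    meta = json.loads(p.with_suffix(".meta.json").read_text())
    return TitrationSeries(
        injection_volumes_uL=df["injection_volume_uL"].to_numpy(float),
        heats=df["heat_kcal_per_mol"].to_numpy(float),
        **meta,
    )


def std_to_tsv(series_list: list[BuildUpSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "proton_id": s.proton_id,
                "condition": s.condition,
                "sat_time_s": s.sat_times_s,
                "std_amplitude": s.std_amplitude,
            }
        )
        for s in series_list
    ]
    _write_tsv(pd.concat(frames, ignore_index=True), Path(path))


def std_from_tsv(path: str | Path) -> list[BuildUpSeries]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (pid, cond), grp in df.groupby(["proton_id", "condition"], sort=False):
        out.append(
            BuildUpSeries(
                proton_id=str(pid), condition=str(cond),
                sat_times_s=grp["sat_time_s"].to_numpy(float),
                std_amplitude=grp["std_amplitude"].to_numpy(float),
            )
        )
    return out


def noesy_to_tsv(buildups: list[NOEBuildUp], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "pair_id": b.pair_id,
                "mixing_time_ms": b.mixing_times_ms,
                "integral": b.integrals,
            }
        )
        for b in buildups
    ]
    _write_tsv(pd.concat(frames, ignore_index=True), Path(path))


def noesy_from_tsv(path: str | Path) -> list[NOEBuildUp]:
    df = pd.read_csv(path, sep="\t")
    return [
        NOEBuildUp(
            pair_id=str(pid),
            mixing_times_ms=grp["mixing_time_ms"].to_numpy(float),
            integrals=grp["integral"].to_numpy(float),
        )
        for pid, grp in df.groupby("pair_id", sort=False)
    ]
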
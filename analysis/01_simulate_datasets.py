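#!/usr/bin/env python
"""Generate one synthetic dataset per input class, with ground-truth sidecars.

Writes TSV datasets under results/datasets/ that the later drivers consume:
luminescence kinetics for three saturable substrates plus one non-saturable,
five one-site ITC titrations, ±GDP STD build-ups, NOESY build-ups, and a
three-site glycopeptide feature table.
"""

import argparse
from pathlib import Path

import numpy as np

from corefuc import io as cio
from corefuc import synthetic as syn
from corefuc.glycoms import peptide_mass

KINETIC_TRUTH = {
    "GDP-Fuc": (14.56, 244.3),
    "G0": (113.1, 282.1),
    "G0-peptide": (133.1, 224.7),
}
ITC_TRUTH = {
    "GDP": (6.1, -5.02, 0.60),
    "G0_plus_GDP": (8.0, -2.42, 1.2),
    "G0_no_GDP": (318.0, 8.35, 1.6),
    "G0-peptide": (10.0, -3.2, 0.84),
    "M3N2-peptide": (406.0, 7.7, 1.6),
}
SITE_PROFILES = {
    "N51": {"Hex5HexNAc2dHex1": 0.48, "Hex5HexNAc2": 0.52},
    "N65": {"Hex5HexNAc2dHex1": 0.90, "Hex5HexNAc2": 0.10},
    "N110": {"Hex5HexNAc2dHex1": 0.67, "Hex5HexNAc2": 0.33},
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/datasets"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    for i, (name, (km, vmax)) in enumerate(KINETIC_TRUTH.items()):
        cfg = syn.ScenarioConfig(seed=args.seed + i, noise_cv=0.03)
        sim = syn.gen_kinetics_dataset(Km=km, Vmax=vmax, substrate_id=name, config=cfg)
        slug = name.lower().replace("-", "_")
        cio.kinetics_to_tsv(sim.dataset, out / f"kinetics_{slug}.tsv")
        sim.standard_curve.to_csv(out / f"standard_curve_{slug}.tsv", sep="\t", index=False)
        cio.write_ground_truth(sim.truth, out / f"kinetics_{slug}.truth.json")
    # a substrate the enzyme never saturates on (velocity linear in S)
    sim = syn.gen_kinetics_dataset(
        Km=1e6, Vmax=2e5, substrate_id="M5N2-Asn", linear_in_S=True,
        config=syn.ScenarioConfig(seed=args.seed + 9, noise_cv=0.03),
    )
    cio.kinetics_to_tsv(sim.dataset, out / "kinetics_m5n2_asn.tsv")
    sim.standard_curve.to_csv(out / "standard_curve_m5n2_asn.tsv", sep="\t", index=False)
    cio.write_ground_truth(sim.truth, out / "kinetics_m5n2_asn.truth.json")

    for i, (name, (kd, dh, n)) in enumerate(ITC_TRUTH.items()):
        weak = n * 70.0 / kd < 1.0
        sim = syn.gen_itc_titration(
            Kd=kd, dH=dh, n=n,
            syringe_conc=1000.0 if weak else 800.0,
            injections=np.full(30, 2.5) if weak else None,
            config=syn.ScenarioConfig(seed=args.seed + 20 + i, noise_cv=0.02),
        )
        slug = name.lower().replace("-", "_")
        cio.itc_to_tsv(sim.series, out / f"itc_{slug}.tsv")
        cio.write_ground_truth(sim.truth, out / f"itc_{slug}.truth.json")

    protons = ["GlcNAc-A H1", "GlcNAc-A H4", "GlcNAc-B H1", "Man-C H1", "Asn4 Ha"]
    stdmax, ksat = [0.12, 0.10, 0.08, 0.05, 0.02], [0.9, 0.9, 0.85, 0.8, 0.7]
    all_series = []
    for cond, factor, off in (("apo", 1.0, 40), ("plus_GDP", 1.5, 41)):
        series, truth = syn.gen_std_buildup(
            protons, [a * factor for a in stdmax], ksat, condition=cond,
            config=syn.ScenarioConfig(seed=args.seed + off, noise_cv=0.03),
        )
        all_series += series
        cio.write_ground_truth(truth, out / f"std_{cond}.truth.json")
    cio.std_to_tsv(all_series, out / "std_buildups.tsv")

    buildups, truth = syn.gen_noe_buildup(
        ["H1B-H5B", "H1B-H4A", "H1B-H5A"], [2.58, 2.60, 3.70], "H1B-H5B", 2.58,
        config=syn.ScenarioConfig(seed=args.seed + 50, noise_cv=0.02),
    )
    cio.noesy_to_tsv(buildups, out / "noesy_buildups.tsv")
    cio.write_ground_truth(truth, out / "noesy.truth.json")

    pep = peptide_mass("KVANKT")
    sim = syn.gen_glycopeptide_features(
        SITE_PROFILES, {s: pep for s in SITE_PROFILES}, ppm_error_sd=1.0,
        config=syn.ScenarioConfig(seed=args.seed + 60, noise_cv=0.0),
    )
    sim.features.to_csv(out / "glyco_features.tsv", sep="\t", index=False)
    cio.write_ground_truth(sim.truth, out / "glyco_features.truth.json")

    print(f"wrote synthetic datasets for all five input classes to {out}")


if __name__ == "__main__":
    main()
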
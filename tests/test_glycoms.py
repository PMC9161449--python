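"""Mass arithmetic, bounded composition decomposition, glycosite reports."""

import itertools

import numpy as np
import pandas as pd
import pytest

from corefuc import glycoms as g
from corefuc import synthetic as syn
from corefuc.constants import BLOCK_MASSES, PROTON_MASS, WATER_MASS


class TestMassArithmetic:
    def test_neutral_mass_singly_charged(self):
        assert g.neutral_mass(101.0072765, 1) == pytest.approx(100.0, abs=1e-9)

    def test_charge_states_agree_on_neutral_mass(self):
        m = 1957.87255
        mz2 = (m + 2 * PROTON_MASS) / 2
        mz3 = (m + 3 * PROTON_MASS) / 3
        assert g.neutral_mass(mz2, 2) == pytest.approx(g.neutral_mass(mz3, 3), abs=1e-6)

    def test_kvankt_peptide_mass(self):
        assert g.peptide_mass("KVANKT") == pytest.approx(659.39661, abs=5e-5)

    def test_empty_sequence_is_water(self):
        assert g.peptide_mass("") == pytest.approx(WATER_MASS)

    def test_mass_additivity(self):
        assert g.peptide_mass("KVA") + g.peptide_mass("NKT") - WATER_MASS == pytest.approx(
            g.peptide_mass("KVANKT")
        )

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            g.peptide_mass("KVXNKT")

    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Hex5HexNAc2dHex1", {"Hex": 5, "HexNAc": 2, "dHex": 1}),
            ("Hex3HexNAc4", {"Hex": 3, "HexNAc": 4}),
            ("Man5-GlcNAc2-Fuc", {"Hex": 5, "HexNAc": 2, "dHex": 1}),
            ("NeuAc2Hex5HexNAc4", {"NeuAc": 2, "Hex": 5, "HexNAc": 4}),
        ],
    )
    def test_composition_parsing(self, text, expected):
        assert g.parse_composition(text) == expected

    def test_unknown_block_rejected(self):
        with pytest.raises(ValueError, match="unknown building block"):
            g.parse_composition("Xyl2Hex1")

    def test_labels_render_trivial_names(self):
        assert g.composition_label({"Hex": 5, "HexNAc": 2, "dHex": 1}) == "Man5-GlcNAc2-Fuc"
        assert g.composition_label({"Hex": 3, "HexNAc": 4}) == "Man3-GlcNAc4"


class TestDecomposeMass:
    PEP = ("KVANKT", 659.39662463525)

    def test_g0_composition_unique_at_5ppm(self):
        obs = self.PEP[1] + 3 * BLOCK_MASSES["Hex"] + 4 * BLOCK_MASSES["HexNAc"]
        cands = g.decompose_mass(obs, [self.PEP])
        assert len(cands) == 1
        assert dict(cands[0]["composition"]) == {
            "Hex": 3, "HexNAc": 4, "dHex": 0, "NeuAc": 0, "Phospho": 0,
        }
        assert cands[0]["ppm_error"] == pytest.approx(0.0, abs=1e-9)

    def test_bare_peptide_mass_gives_empty_composition(self):
        cands = g.decompose_mass(self.PEP[1], [self.PEP])
        assert len(cands) == 1
        assert all(k == 0 for _, k in cands[0]["composition"])

    def test_matches_cartesian_product_oracle(self):
        """Sound and complete against full enumeration over the bounds."""
        bounds = {"Hex": 9, "HexNAc": 6, "dHex": 2, "NeuAc": 4, "Phospho": 2}
        blocks = g.BuildingBlockSet(bounds=bounds)
        order = blocks.order
        rng = np.random.default_rng(11)
        pep = self.PEP
        tol = 5.0

        def oracle(obs):
            found = set()
            for counts in itertools.product(*(range(bounds[b] + 1) for b in order)):
                theo = pep[1] + sum(k * BLOCK_MASSES[b] for b, k in zip(order, counts))
                if abs(1e6 * (obs - theo) / theo) <= tol:
                    found.add(counts)
            return found

        for _ in range(100):
            # half the masses sit exactly on a random composition (± jitter),
            # half are arbitrary — exercising hits, near-misses and misses
            if rng.random() < 0.5:
                counts = [rng.integers(0, bounds[b] + 1) for b in order]
                obs = pep[1] + sum(k * BLOCK_MASSES[b] for b, k in zip(order, counts))
                obs *= 1 + rng.normal(0.0, 3e-6)
            else:
                obs = rng.uniform(600.0, 3500.0)
            got = {
                tuple(k for _, k in c["composition"])
                for c in g.decompose_mass(obs, [pep], blocks, tolerance_ppm=tol)
            }
            assert got == oracle(obs)

    def test_every_candidate_within_tolerance(self):
        obs = 2000.0
        for c in g.decompose_mass(obs, [self.PEP], tolerance_ppm=50.0):
            assert abs(c["ppm_error"]) <= 50.0

    def test_deterministic_ordering_by_ppm_then_lexicographic(self):
        obs = self.PEP[1] + 5 * BLOCK_MASSES["Hex"] + 2 * BLOCK_MASSES["HexNAc"]
        cands = g.decompose_mass(obs, [self.PEP], tolerance_ppm=500.0)
        keys = [(abs(c["ppm_error"]), tuple(k for _, k in c["composition"])) for c in cands]
        assert keys == sorted(keys)

    def test_node_budget_enforced(self):
        blocks = g.BuildingBlockSet(bounds={b: 40 for b in BLOCK_MASSES})
        with pytest.raises(RuntimeError, match="node budget"):
            g.decompose_mass(5000.0, [self.PEP], blocks, tolerance_ppm=5.0, max_nodes=100)

    def test_empty_candidate_list_gives_empty_result(self):
        assert g.decompose_mass(2000.0, []) == []


class TestGlycositeDetection:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["peptide_id", "is_deamidated", "intensity"])

    def test_fold_increase_above_threshold_flagged(self):
        before = self._table([("p1", True, 1.0), ("p1", False, 99.0)])
        after = self._table([("p1", True, 10.0), ("p1", False, 90.0)])
        out = g.detect_glycosite_peptides(before, after, fold_threshold=2.0)
        assert bool(out.set_index("peptide_id").loc["p1", "is_glycosite"])

    def test_equal_yields_not_flagged(self):
        t = self._table([("p1", True, 5.0), ("p1", False, 95.0)])
        out = g.detect_glycosite_peptides(t, t.copy())
        assert not bool(out.set_index("peptide_id").loc["p1", "is_glycosite"])

    def test_exactly_the_true_glycosites_flagged(self):
        rows_before, rows_after = [], []
        glyco = {"g1", "g2", "g3"}
        for pid in ["g1", "g2", "g3", "n1", "n2"]:
            rows_before += [(pid, True, 1.0), (pid, False, 50.0)]
            gain = 20.0 if pid in glyco else 1.1
            rows_after += [(pid, True, gain), (pid, False, 50.0)]
        out = g.detect_glycosite_peptides(
            self._table(rows_before), self._table(rows_after), fold_threshold=2.0
        )
        flagged = set(out[out["is_glycosite"]]["peptide_id"])
        assert flagged == glyco

    def test_missing_deamidated_rows_skipped_with_warning(self):
        before = self._table([("p1", True, 1.0), ("p2", False, 5.0)])
        after = self._table([("p1", True, 9.0), ("p2", False, 5.0)])
        with pytest.warns(UserWarning, match="p2"):
            out = g.detect_glycosite_peptides(before, after)
        assert out["peptide_id"].tolist() == ["p1"]


class TestSiteReport:
    def test_nine_to_one_fucosylated_fractions(self, noiseless):
        sim = syn.gen_glycopeptide_features(
            {"N65": {"Hex5HexNAc2dHex1": 0.90, "Hex5HexNAc2": 0.10}},
            {"N65": 659.39661}, config=noiseless,
        )
        rep = g.site_report(g.assign_features(sim.features, sim.peptides_by_site), "N65")
        assert rep.fucosylated_fraction == pytest.approx(0.90)
        assert rep.glycoform_fractions.loc["Man5-GlcNAc2-Fuc", "fraction"] == pytest.approx(0.90)
        assert rep.glycoform_fractions.loc["Man5-GlcNAc2", "fraction"] == pytest.approx(0.10)

    def test_single_glycoform_fraction_one(self, noiseless):
        sim = syn.gen_glycopeptide_features(
            {"N1": {"Hex5HexNAc4dHex1": 1.0}}, {"N1": 659.39661}, config=noiseless,
        )
        rep = g.site_report(g.assign_features(sim.features, sim.peptides_by_site), "N1")
        assert rep.fucosylated_fraction == pytest.approx(1.0)

    def test_fractions_sum_to_one_over_random_sites(self):
        rng = np.random.default_rng(3)
        forms = ["Hex5HexNAc2", "Hex5HexNAc2dHex1", "Hex3HexNAc4", "Hex3HexNAc4dHex1"]
        for seed in range(20):
            w = rng.dirichlet(np.ones(len(forms)))
            profile = {f: float(x) for f, x in zip(forms, w / w.sum())}
            total = sum(profile.values())
            profile[forms[0]] += 1.0 - total  # exact unit sum
            sim = syn.gen_glycopeptide_features(
                {"S": profile}, {"S": 659.39661}, intensity_sigma=0.3,
                config=syn.ScenarioConfig(seed=seed, noise_cv=0.0),
            )
            rep = g.site_report(g.assign_features(sim.features, sim.peptides_by_site), "S",
                                top_n=8)
            assert rep.glycoform_fractions["fraction"].sum() == pytest.approx(1.0)

    def test_assignment_invariant_to_charge_state(self, noiseless):
        sim = syn.gen_glycopeptide_features(
            {"N65": {"Hex5HexNAc2dHex1": 1.0}}, {"N65": 659.39661},
            charge_states=(2, 3), config=noiseless,
        )
        assignments = g.assign_features(sim.features, sim.peptides_by_site)
        comps = {a.composition for a in assignments}
        assert len(assignments) == 2 and len(comps) == 1

    def test_no_assignments_rejected(self):
        with pytest.raises(ValueError, match="no assignments"):
            g.site_report([], "N65")
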
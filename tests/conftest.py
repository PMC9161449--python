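import pytest

from corefuc.synthetic import ScenarioConfig


@pytest.fixture
def noiseless():
    return ScenarioConfig(seed=1, noise_cv=0.0)


#: Published one-site thermodynamic profiles (Kd μM, ΔG, ΔH, −TΔS kcal/mol, n)
#: for the GDP / G0 / G0-peptide / M3N2-peptide titrations at 25 °C.
THERMO_ROWS = [
    ("GDP", 6.1, -7.09, -5.02, -2.07, 0.60),
    ("G0 (excess GDP)", 8.0, -6.89, -2.42, -4.47, 1.2),
    ("G0 (without GDP)", 318.0, -4.75, 8.35, -13.1, 1.6),
    ("G0-peptide (excess GDP)", 10.0, -6.82, -3.2, -3.62, 0.84),
    ("M3N2-peptide (excess GDP)", 406.0, -4.6, 7.7, -12.3, 1.6),
]

#: Published kinetic parameters (Km μM, Vmax nmol·min⁻¹·mg⁻¹, kcat min⁻¹,
#: kcat/Km min⁻¹·μM⁻¹) for the saturable substrates.
KINETIC_ROWS = [
    ("GDP-Fuc", 14.56, 244.3, 14.17, 0.97),
    ("G0", 113.1, 282.1, 15.62, 0.14),
    ("G0-peptide", 133.1, 224.7, 13.03, 0.1),
]
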
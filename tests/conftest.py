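import numpy as np
import pytest

from xlms.chem import CrosslinkerSpec, Peptide, synthetic_crosslinker


@pytest.fixture(scope="session")
def xl() -> CrosslinkerSpec:
    return synthetic_crosslinker()


@pytest.fixture(scope="session")
def toy_xl() -> CrosslinkerSpec:
    """Round-number crosslinker for arithmetic checks: spacer 100 = 40 + 60."""
    return CrosslinkerSpec(
        name="toy",
        spacer_mass_light=100.0,
        short_arm_mass=40.0,
        long_arm_mass=60.0,
        deadend_masses={"hydrolyzed": 118.0105646863},
    )


def peptide_with_mass(target_mass: float, sequence: str = "AKA", **kwargs) -> Peptide:
    """A peptide whose monoisotopic mass is forced to ``target_mass`` via a mod."""
    from xlms.chem import peptide_monoisotopic_mass

    base = peptide_monoisotopic_mass(sequence)
    return Peptide(sequence=sequence, mods=((1, target_mass - base),), **kwargs)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
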
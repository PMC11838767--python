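import numpy as np
import pytest

from plaquetime import isotope_model as im


@pytest.fixture(scope="session")
def abeta_species():
    return im.PeptideSpecies(im.ABETA42_SEQUENCE)


@pytest.fixture(scope="session")
def abeta_composition(abeta_species):
    return im.composition_from_sequence(abeta_species)


@pytest.fixture(scope="session")
def isotope_table():
    return im.IsotopeTable.natural()


@pytest.fixture(scope="session")
def abeta_natural(abeta_composition, isotope_table):
    return im.natural_distribution(abeta_composition, isotope_table)


@pytest.fixture(scope="session")
def abeta_labeled_15(abeta_composition, isotope_table):
    """Labeled envelope at the generator's default enrichment."""
    return im.labeled_distribution(abeta_composition, isotope_table, rho=0.15)


@pytest.fixture(scope="session")
def abeta_labeled_98(abeta_composition, isotope_table):
    return im.labeled_distribution(abeta_composition, isotope_table, rho=0.98)


@pytest.fixture(scope="session")
def linear_grid():
    return np.arange(4455.0, 4590.0, 0.2)


@pytest.fixture(scope="session")
def reflector_grid():
    return np.arange(4455.0, 4590.0, 0.02)


def mixture(f, rho, nat, lab):
    return im.mixture_envelope(im.LabelingModel(f, rho), nat, lab)
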
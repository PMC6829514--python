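import numpy as np
import pytest

from peptikit import (CatalogueEntry, PeptideCatalogue, ProteinRecord,
                      default_registry)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def pepsin(registry):
    return registry["pepsin_ph_gt2"]


@pytest.fixture(scope="session")
def trypsin(registry):
    return registry["trypsin"]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture()
def tiny_catalogue():
    """The three-entry fixture used throughout: AE/GP are DPP-IV
    inhibitors, the reversed dipeptide EA inhibits ACE."""
    return PeptideCatalogue([
        CatalogueEntry("AE", "DPP-IV inhibitor", "T1"),
        CatalogueEntry("EA", "ACE inhibitor", "T2"),
        CatalogueEntry("GP", "DPP-IV inhibitor", "T3"),
    ])


@pytest.fixture()
def protein():
    return ProteinRecord("P1", "test protein", "AFAVALAEA")


def random_protein(rng, length, identifier="R1") -> ProteinRecord:
    alphabet = sorted("ACDEFGHIKLMNPQRSTVWY")
    return ProteinRecord(
        identifier, "", "".join(rng.choice(alphabet, size=length)))
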
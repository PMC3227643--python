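import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from methyloflux import build_core_model, enumerate_efms, make_icl_variant
from methyloflux.mfa13c import AtomTransitionModel
from methyloflux.synthetic import (reference_constraints,
                                   reference_flux_distribution)


@pytest.fixture(scope="session")
def core():
    return build_core_model()


@pytest.fixture(scope="session")
def icl(core):
    return make_icl_variant(core)


@pytest.fixture(scope="session")
def biomass_efms(core):
    """Biomass-targeted elementary modes of the core model (shared:
    enumeration is the expensive step)."""
    return enumerate_efms(core, target_drain="biomass")


@pytest.fixture(scope="session")
def atoms():
    return AtomTransitionModel()


@pytest.fixture(scope="session")
def reference(atoms):
    return reference_flux_distribution(atoms)


@pytest.fixture(scope="session")
def ref_constraints(atoms):
    return reference_constraints(atoms)
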
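import pytest

from cadtrace.simulate import (
    default_blueprint,
    generate_protein,
    preserved_positions,
)


@pytest.fixture(scope="session")
def type_iii():
    """A full-size type III cadherin mimic with its planted truth."""
    record, truth = generate_protein(default_blueprint("III", seed=101),
                                     record_id="pt1_like")
    return record, truth


@pytest.fixture(scope="session")
def type_iii_preserved(type_iii):
    _, truth = type_iii
    return preserved_positions(truth)


@pytest.fixture(scope="session")
def type_iva():
    record, truth = generate_protein(default_blueprint("IVa", seed=202),
                                     record_id="de_cad_like")
    return record, truth
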
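import numpy as np
import pytest

from btbpk import datasets
from btbpk.cns import CNSModelSpec
from btbpk.plasma import DoseEvent


@pytest.fixture(scope="session")
def rat():
    return datasets.load_physiology("rat")


@pytest.fixture(scope="session")
def human():
    return datasets.load_physiology("human")


@pytest.fixture(scope="session")
def drugs():
    return {name: datasets.load_drug(name) for name in datasets.drug_names()}


@pytest.fixture(scope="session")
def tmz_spec(rat):
    return CNSModelSpec(
        drug=datasets.load_drug("temozolomide"),
        physiology=rat,
        plasma=datasets.load_plasma_model("temozolomide"),
    )


@pytest.fixture(scope="session")
def mtx_spec(rat):
    return CNSModelSpec(
        drug=datasets.load_drug("methotrexate"),
        physiology=rat,
        plasma=datasets.load_plasma_model("methotrexate_sham"),
        kpuu_ecf_target=0.114,
    )


@pytest.fixture()
def bolus():
    return [DoseEvent("iv_bolus", amount=10000.0, start=0.0)]


@pytest.fixture()
def times():
    return np.linspace(5.0, 360.0, 36)
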
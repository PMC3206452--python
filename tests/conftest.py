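import logging

import pytest

from cclog.convert import load_ch4_document, load_gaussian_pack, load_gaussian_rules
from cclog.dictionary import load_compchem_dictionary

logging.getLogger("cclog").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def compchem_dict():
    return load_compchem_dictionary()


@pytest.fixture(scope="session")
def gaussian_pack():
    return load_gaussian_pack()


@pytest.fixture(scope="session")
def gaussian_rules():
    return load_gaussian_rules()


@pytest.fixture()
def ch4_doc():
    # function-scoped: several tests mutate the tree
    return load_ch4_document()


@pytest.fixture(scope="session")
def eigen_template(gaussian_pack):
    return next(t for t in gaussian_pack if t.id == "l601.alphabetaeigen")


EIGEN_BLOCK = """\
Alpha occ. eigenvalues -- -10.17514 -0.68437 -0.38581 -0.38581 -0.38581
Alpha virt. eigenvalues -- 0.11292 0.17036 0.17036 0.17036 0.53917
Alpha virt. eigenvalues -- 0.53917 0.53917 0.88316 0.88316 0.88316
Alpha virt. eigenvalues -- 0.91927 1.09380 1.66027 1.66027 2.21731
Alpha virt. eigenvalues -- 2.21731 2.21731 4.16488
"""


@pytest.fixture(scope="session")
def eigen_block():
    return EIGEN_BLOCK
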
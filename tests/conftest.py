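import numpy as np
import pytest

from pose_triage import synthetic_data as synth
from pose_triage.structure_io import Atom


def make_atom(
    name,
    element,
    xyz,
    resname="LIG",
    resnum=401,
    chain="A",
    hetero=True,
):
    return Atom(
        name=name,
        element=element,
        coords=np.asarray(xyz, dtype=float),
        residue_name=resname,
        residue_number=resnum,
        chain_id=chain,
        is_hetero=hetero,
    )


@pytest.fixture(scope="session")
def site_and_criteria():
    return synth.make_active_site(seed=11)


@pytest.fixture(scope="session")
def oxamate_complex():
    return synth.make_reference_complex("oxamate", seed=11)


@pytest.fixture(scope="session")
def inhibitor_88n_complex():
    return synth.make_reference_complex("88N", seed=11)
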
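import numpy as np
import pandas as pd
import pytest

from mangrove_allometry.allometry import ModelForm, ModelFormName
from mangrove_allometry.published_models import builtin_registry


@pytest.fixture(scope="session")
def registry():
    return builtin_registry()


@pytest.fixture
def power_form():
    return ModelForm(ModelFormName.POWER, ("x",))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_tree(tree_id="t1", height_cm=100.0, diameter_cm=2.0, r1=30.0, r2=20.0,
              disk_dry_mass_g=70.0, disk_volume_cm3=100.0):
    from mangrove_allometry.mensuration import TreeRecord, diameter_convention

    return TreeRecord(
        tree_id=tree_id,
        height_cm=height_cm,
        diameter_cm=diameter_cm,
        diameter_kind=diameter_convention(height_cm),
        crown_r1_cm=r1,
        crown_r2_cm=r2,
        disk_dry_mass_g=disk_dry_mass_g,
        disk_volume_cm3=disk_volume_cm3,
    )


@pytest.fixture
def tree_factory():
    return make_tree
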
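import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fibryze.io import Atom, Structure  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def model():
    from fibryze.specificity import load_specificity

    return load_specificity()


def random_structure(seed: int, n_models: int = 2, n_res: int = 5) -> Structure:
    """Small random multi-model structure for round-trip tests."""
    rng = np.random.default_rng(seed)
    res_names = ["GLY", "ALA", "CYS", "SER", "HIS"]
    atoms = []
    serial = 1
    for m in range(1, n_models + 1):
        for r in range(1, n_res + 1):
            for name, elem in (("N", "N"), ("CA", "C"), ("C", "C")):
                atoms.append(
                    Atom(
                        serial=serial, name=name,
                        res_name=res_names[(r - 1) % len(res_names)],
                        chain_id="A", res_seq=r,
                        coords=np.round(rng.normal(scale=20, size=3), 3),
                        element=elem, model=m,
                    )
                )
                serial += 1
    return Structure(id=f"random{seed}", atoms=atoms)
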
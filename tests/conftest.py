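import numpy as np
import pandas as pd
import pytest

from qttnet.simulate import SimulationDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """16-animal, 3-tissue cohort with planted NEFA signal and modules."""
    design = SimulationDesign(n_probesets=400, n_tissues=3, n_traits=6,
                              qtt_traits=("NEFA",), n_true_qtt=40)
    return simulate_cohort(design, seed=11) + (design,)


@pytest.fixture(scope="session")
def null_cohort():
    """Pure-null cohort: no planted QTT, no modules."""
    design = SimulationDesign(n_probesets=1000, n_tissues=1, n_traits=4,
                              qtt_traits=(), n_true_qtt=0,
                              n_modules=0, module_sizes=())
    return simulate_cohort(design, seed=7) + (design,)


@pytest.fixture()
def toy_pheno():
    rng = np.random.default_rng(0)
    n = 16
    breeds = ["B1"] * 4 + ["B2"] * 4 + ["B3"] * 4 + ["B4"] * 4
    sexes = (["M", "M", "F", "F"] * 3) + ["M", "M", "M", "F"]
    pheno = pd.DataFrame({
        "sex": sexes, "breed": breeds,
        "traitA": rng.normal(size=n), "traitB": rng.normal(size=n),
    }, index=pd.Index([f"S{i:02d}" for i in range(n)], name="sample"))
    return pheno
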
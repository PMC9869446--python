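import pandas as pd
import pytest

from hiveforage import ColonyParams, LearningCurveParams
from hiveforage.synth import GeneratorSpec, generate_interactions


@pytest.fixture(scope="session")
def lc_default() -> LearningCurveParams:
    return LearningCurveParams()


@pytest.fixture(scope="session")
def cp_default() -> ColonyParams:
    return ColonyParams()


@pytest.fixture(scope="session")
def toy_interactions() -> pd.DataFrame:
    """Hand-built visitation table with known composition.

    Species Apis_a (eusocial): 4 visits, 3 bilateral, corollas 4/6/2/8 mm.
    Species Andrena_b (solitary): 2 visits, 1 bilateral, corollas 3/5 mm.
    Species Halictus_c (solitary): 4 visits, 0 bilateral, corollas 1/2/3/2 mm.
    """
    rows = []
    for sym, cor in zip("bbbr", (4.0, 6.0, 8.0, 2.0)):
        rows.append(("Apis_a", "Apis", "eusocial", 6.0, sym, cor))
    for sym, cor in zip("br", (5.0, 3.0)):
        rows.append(("Andrena_b", "Andrena", "solitary", 4.0, sym, cor))
    for sym, cor in zip("rrrr", (1.0, 2.0, 3.0, 2.0)):
        rows.append(("Halictus_c", "Halictus", "solitary", 2.0, sym, cor))
    df = pd.DataFrame(
        rows,
        columns=["bee_species", "bee_genus", "sociality", "proboscis_mm",
                 "symmetry", "corolla_mm"],
    )
    df["symmetry"] = df["symmetry"].map({"b": "bilateral", "r": "radial"})
    df["plant_species"] = "Plant_x"
    df["round"] = 1
    df["plot"] = 1
    return df


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-margin synthetic dataset with its generator truth record."""
    table, truth, tree = generate_interactions(GeneratorSpec(seed=20230313))
    return table, truth, tree
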
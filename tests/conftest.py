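import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from pollidiv.simulate import SimConfig, generate_survey


@pytest.fixture(scope="session")
def small_config():
    """Compact study design for fast unit tests (~350 sites)."""
    return SimConfig(n_studies=8, blocks_per_study=(2, 3),
                     sites_per_block=(12, 18), seed=101)


@pytest.fixture(scope="session")
def small_survey(small_config):
    table, truth = generate_survey(small_config)
    return table, truth


@pytest.fixture(scope="session")
def toy_taxonomy():
    """Hand-built 12-genus taxonomy covering every extrapolation case.

    Apidae: 3 subfamilies (one with tribes) -> family-level candidate.
    Syrphidae: genera sit directly under the family.
    Macroscelididae-like Soricidae: one genus only.
    """
    rows = [
        # genus, tribe, subfamily, family, order, class
        ("Apis",     "Apini",     "Apinae",     "Apidae",    "Hymenoptera", "Insecta"),
        ("Bombus",   "Bombini",   "Apinae",     "Apidae",    "Hymenoptera", "Insecta"),
        ("Euglossa", "Euglossini","Apinae",     "Apidae",    "Hymenoptera", "Insecta"),
        ("Xylocopa", None,        "Xylocopinae","Apidae",    "Hymenoptera", "Insecta"),
        ("Ceratina", None,        "Xylocopinae","Apidae",    "Hymenoptera", "Insecta"),
        ("Nomada",   None,        "Nomadinae",  "Apidae",    "Hymenoptera", "Insecta"),
        ("Eristalis", None,       None,         "Syrphidae", "Diptera",     "Insecta"),
        ("Syrphus",  None,        None,         "Syrphidae", "Diptera",     "Insecta"),
        ("Volucella", None,       None,         "Syrphidae", "Diptera",     "Insecta"),
        ("Elephantulus", None,    None,         "Soricidae", "Macroscelidea", "Mammalia"),
        ("Thomisus", None,        None,         "Thomisidae","Araneae",     "Arachnida"),
        ("Misumena", None,        None,         "Thomisidae","Araneae",     "Arachnida"),
    ]
    return pd.DataFrame(rows, columns=["genus", "tribe", "subfamily",
                                       "family", "order", "class"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
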
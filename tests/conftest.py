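import numpy as np
import pandas as pd
import pytest

from rhizogeo import LocusAlignment
from rhizogeo.genospecies_assign import validate_metadata
from rhizogeo.synthetic_study import StudyConfig, simulate_study


@pytest.fixture
def tiny_alignment():
    # columns: AAAA, AAAC, AACC patterns spread over 4 strains
    return LocusAlignment("tiny", {
        "s1": "AAA", "s2": "AAA", "s3": "AAC", "s4": "ACC"})


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_alignment(rng, n_rows=6, n_cols=20, alphabet="ACGT-N"):
    chars = np.array(list(alphabet))
    rows = {f"t{i}": "".join(rng.choice(chars, size=n_cols))
            for i in range(n_rows)}
    return LocusAlignment("rand", rows)


@pytest.fixture(scope="session")
def small_study():
    """12 local strains in 6 genospecies + 6 references; HGT on."""
    cfg = StudyConfig(n_genospecies=6, n_strains=12,
                      genospecies_weights=(1, 1, 1, 1, 1, 1),
                      locus_lengths=(400, 400, 400, 400),
                      sym_locus_length=400, ph_associated_clade=None,
                      sym_absent_clade=None, n_offpanel_references=0,
                      hgt_probability=0.3, seed=3)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Full-size emulation: ~95 strains, 8 genospecies, references."""
    return simulate_study(StudyConfig(seed=11))


@pytest.fixture
def reference_metadata():
    rows = [
        {"strain_id": "q1", "collection": "current", "latitude": 7.0,
         "longitude": 38.0, "elevation": 1500.0, "soil_pH": 5.5},
        {"strain_id": "q2", "collection": "previous", "latitude": 7.5,
         "longitude": 38.5, "elevation": 1700.0, "soil_pH": 7.0},
        {"strain_id": "REF_etli", "collection": "reference",
         "reference_species": "R. etli"},
        {"strain_id": "REF_phaseoli", "collection": "reference",
         "reference_species": "R. phaseoli"},
    ]
    return validate_metadata(pd.DataFrame(rows))
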
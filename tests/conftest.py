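import numpy as np
import pytest

from charon.findings import TRISTATE_FIELDS, parse_findings
from charon.knowledge import default_knowledge_base


@pytest.fixture(scope="session")
def tree():
    return default_knowledge_base()


GLOBAL_ATROPHY = {
    "mri_vermis_superior_atrophy": "present",
    "mri_vermis_inferior_atrophy": "present",
    "mri_hemispheric_atrophy": "present",
}

NO_SIGNAL_CHANGES = {
    "mri_dn_t2_hyperintensity": "absent",
    "mri_hcb_sign": "absent",
    "mri_mcp_wm_lesions": "absent",
    "mri_splenium_wm_lesions": "absent",
    "mri_lateral_pons_lesions": "absent",
}


def random_findings(rng: np.random.Generator):
    """A random partial findings record (deliberately messy)."""
    record = {
        name: rng.choice(["present", "absent", "unknown"], p=[0.3, 0.4, 0.3])
        for name in TRISTATE_FIELDS
    }
    if rng.random() < 0.7:
        record["onset_age_years"] = float(rng.uniform(0, 80))
    if rng.random() < 0.7:
        record["lab_afp_ug_per_L"] = float(rng.uniform(0, 100))
    record["lab_vitamin_e"] = rng.choice(["reduced", "normal", "unknown"])
    record["lab_coq10"] = rng.choice(["low", "normal", "unknown"])
    return parse_findings(record)
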
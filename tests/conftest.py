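import pytest

from drugcombo import DoseResponsePoint, DrugTruth, MedianEffectParams, fa_from_dose

# Three-drug single-agent median-effect doses used as fixture constants
# throughout (same unit); their sum is 19.95.
DM_TRIPLE = (6.54, 5.53, 7.88)
COMBO_DM = 3.72


@pytest.fixture
def dm_triple_params():
    return [MedianEffectParams(dm=dm, m=2.0, unit="ug/mL") for dm in DM_TRIPLE]


@pytest.fixture
def drug_truths():
    return (
        DrugTruth("A", DM_TRIPLE[0], 2.0),
        DrugTruth("B", DM_TRIPLE[1], 1.8),
        DrugTruth("C", DM_TRIPLE[2], 2.2),
    )


def model_points(dm, m, doses, unit="uM"):
    """Noiseless points lying exactly on the median-effect curve."""
    params = MedianEffectParams(dm=dm, m=m, unit=unit)
    return [DoseResponsePoint(dose=d, fa=fa_from_dose(params, d), unit=unit) for d in doses]
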
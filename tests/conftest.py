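import pytest

from lipoform.pipeline import fit_calibration
from lipoform.synthetic import paper_like_campaign


@pytest.fixture(scope="session")
def campaign():
    """One default two-device synthetic campaign shared by read-only tests."""
    return paper_like_campaign(seed=20)


@pytest.fixture(scope="session")
def calibrations(campaign):
    return (
        fit_calibration(campaign.calibrations["lipid"], "lipid"),
        fit_calibration(campaign.calibrations["calcein"], "calcein"),
    )
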
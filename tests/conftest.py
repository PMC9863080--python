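import warnings

import pytest

from bottlebioassay import CampaignDesign, MCMCConfig, TrueCurve

# arviz emits a refactor FutureWarning on import; irrelevant to the checks here
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture
def default_curve() -> TrueCurve:
    """The reference simulation curve: LC50 = e^0 = 1 µg/bottle, 3% background."""
    return TrueCurve(B=3.0, C=0.0, E=1.0, Z=0.03)


@pytest.fixture
def step2_design() -> CampaignDesign:
    """The standard main-phase design: 6 concentrations, 4x25 + 2x25 controls, 3 bioassays."""
    return CampaignDesign()


@pytest.fixture
def fast_mcmc() -> MCMCConfig:
    """Short schedule for unit tests where full-length chains are unnecessary."""
    return MCMCConfig(chains=4, iterations=1200, escalation_iterations=2400, seed=0)


CSV_HEADER = (
    "institution,country,species,strain,insecticide,endpoint_type,bioassay_id,"
    "replicate_id,concentration_ug_per_bottle,n_exposed,n_responded,n_chambered,"
    "recording_time_h"
)


def make_csv(tmp_path, rows, name="bioassays.csv"):
    path = tmp_path / name
    path.write_text(CSV_HEADER + "\n" + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def tiny_csv(tmp_path):
    """One control and two treated rows of a single mortality bioassay."""
    rows = [
        "labA,SIM,An. gambiae,Kisumu,clothianidin,mortality,a1,ctrl1,0,25,1,,24",
        "labA,SIM,An. gambiae,Kisumu,clothianidin,mortality,a1,rep1,1,25,12,,24",
        "labA,SIM,An. gambiae,Kisumu,clothianidin,mortality,a1,rep2,10,25,24,,24",
    ]
    return make_csv(tmp_path, rows)
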
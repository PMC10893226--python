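"""ioqsp: mechanistic immuno-oncology QSP virtual-trial simulator for
atezolizumab + carboplatin + nab-paclitaxel in NSCLC."""

from importlib import resources

from .model_core import (
    InhibitionSignals,
    IntegrationError,
    ModelParameters,
    PARAM_NAMES,
    STATE_NAMES,
    cancer_capacity,
    cancer_rhs,
    checkpoint_occupancy,
    full_rhs,
    gompertz_solution,
    inhibition_terms,
    tumour_diameter,
    tumour_volume_mm3,
)
from .pharmacokinetics import (
    DoseEvent,
    DrugComponent,
    PKParameters,
    Regimen,
    STANDARD_REGIMENS,
    atezolizumab_conc_central,
    atezolizumab_pk_rhs,
    build_schedule,
    carboplatin_exposure,
    chemo_backbone,
    nabp_pk_rhs,
    triple_regimen,
)
from .population import (
    ParameterDistribution,
    PopulationSpec,
    VirtualPatient,
    build_population,
    default_variable_parameters,
    lhs_sample,
    parameter_table,
    population_frame,
)
from .engine import (
    CohortResult,
    TumourTrajectory,
    burn_in,
    simulate_cohort,
    simulate_patient,
    trajectories_frame,
)
from .response import (
    EndpointSummary,
    ResponseRecord,
    classify_recist,
    compute_orr,
    median_dor,
    summarise_endpoints,
    waterfall,
)
from .sensitivity import PSAResult, prcc, run_psa
from .biomarkers import (
    BIOMARKER_NAMES,
    ROCResult,
    biomarker_report,
    biomarker_table,
    extract_biomarkers,
    rank_sum_test,
    roc_auc,
)
from .calibration import (
    CalibrationTarget,
    calibrate,
    impower131_targets,
    objective,
    simulate_endpoints,
)

__version__ = "0.1.0"


def shipped_spec() -> PopulationSpec:
    """The calibrated population specification shipped with the package."""
    ref = resources.files("ioqsp").joinpath("data/calibrated_population.yaml")
    with resources.as_file(ref) as path:
        return PopulationSpec.load(path)
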
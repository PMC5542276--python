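"""Phenotype-conditioned gene dependency networks and damped fixed-point
gene prioritization for prognostic signatures."""

from importlib import resources

import pandas as pd

from .discretize import (
    BinaryMatrix,
    BinaryPhenotype,
    discretize_expression,
    discretize_phenotype,
)
from .estimators import (
    CoxStabilitySelector,
    DependencyNetworkInference,
    DirGenerankPipeline,
    DirGenerankRanker,
)
from .information import (
    conditional_mutual_information,
    mutual_information,
    permutation_pvalue,
)
from .io import (
    ClinicalTable,
    ExpressionMatrix,
    PPIEdgeList,
    collapse_probes,
    read_clinical,
    read_expression,
    read_ppi,
)
from .network import (
    DegreeFit,
    DependencyEdge,
    DependencyNetwork,
    build_network,
    degree_powerlaw_fit,
    read_network,
)
from .ranking import (
    RankResult,
    Signature,
    dirgenerank,
    ks_rank_enrichment,
    select_signature,
    signature_size,
)
from .simulate import SimConfig, SimTruth, generate_cohort, generate_null_cohort
from .survival import (
    CoxResult,
    GeneStability,
    hazard_ratio,
    logrank_test,
    resample_stability,
    univariate_cox,
)
from .validation import (
    RiskScores,
    Stratification,
    hypergeometric_test,
    median_split,
    risk_score,
    stratify,
)

__version__ = "0.1.0"


def load_ovarian_signature() -> pd.DataFrame:
    """The published 40-gene ovarian-cancer prognostic signature.

    Columns: Entrez gene ID, averaged univariate Cox coefficient, and
    resample stability (out of 400 replicates).
    """
    ref = resources.files("dirgenerank").joinpath("data/ovarian_signature_40.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
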
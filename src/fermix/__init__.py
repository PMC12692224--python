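"""fermix: mixture-design modelling and flavor screening for mixed-strain fermentation.

Toolkit for optimizing co-culture inoculation ratios and profiling the
resulting flavor chemistry: simplex-lattice mixture designs, Scheffe
polynomial response models with ANOVA, genetic-algorithm maximization
over the strain-ratio simplex, fuzzy comprehensive sensory scoring, and
OAV/rOAV-based screening of volatile-compound tables.
"""

from importlib import resources as _resources

from .mixture_design import (
    Composition,
    MixtureDesign,
    ValidationError,
    augment_design,
    generate_simplex_lattice,
    validate_composition,
)
from .scheffe import (
    FitDiagnostics,
    ResponseTable,
    ScheffeModel,
    anova,
    build_model_matrix,
    fit_scheffe,
    model_from_json,
    model_to_json,
    predict,
)
from .ga import GAConfig, GAResult, ga_maximize, grid_maximize, project_to_simplex
from .fuzzy import (
    FuzzyResult,
    SensoryPanel,
    counts_to_rating_matrix,
    fuzzy_score,
    score_panel,
)
from .flavor import (
    VOCRecord,
    VOCTable,
    aggregate_by_category,
    compute_oav,
    compute_roav,
    kovats_ri,
    screen_key_compounds,
    voc_table_from_csv,
)
from .synthetic import (
    SyntheticSpec,
    gen_mixture_responses,
    gen_sensory_counts,
    gen_voc_table,
)

__version__ = "0.1.0"


def _data_path(name: str) -> str:
    return str(_resources.files("fermix.data") / name)


def load_tpc_model() -> ScheffeModel:
    """Published special-cubic model for total phenolic content (mg GAE/mL)."""
    return model_from_json(_data_path("tpc_model.json"))


def load_lactic_model() -> ScheffeModel:
    """Published special-cubic model for lactic acid concentration (g/L)."""
    return model_from_json(_data_path("lactic_model.json"))


def load_fwj_sl05_rating():
    """Published fuzzy rating matrix, weights and grade scores for FWJ-SL05.

    Returns (R, X, P): attribute-major rating matrix, attribute weights,
    grade scores.
    """
    import json
    from pathlib import Path

    payload = json.loads(
        Path(_data_path("fwj_sl05_rating.json")).read_text(encoding="utf-8")
    )
    return (
        payload["rating_matrix"],
        payload["weights"],
        payload["grade_scores"],
    )


def load_gcms_table() -> VOCTable:
    """Transcribed GC-MS volatile-compound table (five juice samples, mg/L)."""
    return voc_table_from_csv(_data_path("table2_gcms.csv"), mode="gcms")
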
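"""Structural-divergence scoring of mutant protein models.

Given wildtype and mutant 3D models of the same protein, this package
superimposes their alpha-carbon traces, condenses the per-residue deviations
over functionally relevant domains into one unitless score (higher = more
likely deleterious), classifies scores against control-derived thresholds,
validates them against measured residual enzyme activity, and trains
per-residue weights to sharpen the score/activity correlation.
"""

__version__ = "0.1.0"

from .correlate import (
    ActivityPoint,
    CorrelationResult,
    Trendline,
    exclude_outliers,
    fit_trendline,
    pearson,
    predict_activity,
    prediction_error,
    read_activity_table,
)
from .errors import ContractError, FormatError, ModictError
from .interpret import (
    CATEGORIES,
    ControlSet,
    ThresholdBracket,
    classify,
    compute_threshold,
    roc_sweep,
)
from .optimize import (
    IterationProfile,
    TrainingConfig,
    TrainingResult,
    compare_models,
    iterate_contributions,
    train_weights,
)
from .scoring import (
    DomainSet,
    ScoreBreakdown,
    background_sum,
    delta_sum,
    final_score,
    gamma_sum,
    isf_sum,
    kappa,
    pair_grid,
    raw_score,
)
from .structio import (
    CaTrace,
    RmsdProfile,
    SuperpositionResult,
    read_ca_trace,
    read_rmsd_file,
    read_score_file,
    superpose,
    write_pdb,
    write_rmsd_file,
)
from .synthetic import (
    PerturbationSpec,
    make_activity_panel,
    make_backbone,
    make_training_panel,
    perturb,
)

__all__ = [name for name in dir() if not name.startswith("_")]


def packaged_table(name: str):
    """Path to a packaged activity-table fixture ('pah_table1' or 'acadm_table2')."""
    from importlib.resources import files

    return files("modict.data").joinpath(f"{name}.tsv")
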
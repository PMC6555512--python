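"""mosppi: matrix-of-sequence protein descriptors and PPI prediction.

Sequence-only protein-protein interaction prediction built around the
matrix-of-sequence (MOS) descriptor: proteins are reduced to a 7-group
alphabet, summarized by an exact pair-count matrix over the whole
sequence order, and classified in pairs by a feed-forward network.
Conjoint-triad, auto-covariance and local-descriptor encoders are
included for comparison, along with dataset filtering, a synthetic
benchmark generator and a repeated hold-out evaluation harness.
"""

from .groups import (
    GroupAlphabet,
    InvalidResidueError,
    ValidationResult,
    build_group_alphabet,
    map_to_groups,
    groups_to_string,
    validate_protein,
)
from .mos import (
    MOSEncoder,
    MOS_DIM,
    SequenceMatrix,
    compute_vos,
    compute_mos_streaming,
    compute_mos_bruteforce,
    normalize_matrix,
    mos_features,
)
from .baseline_encoders import CTEncoder, ACEncoder, LDEncoder
from .dataset_io import (
    InteractionRecord,
    ExclusionReport,
    PairFeatureTable,
    read_fasta,
    read_pairs,
    filter_records,
    build_pair_table,
    split_train_holdout,
)
from .synthetic import SyntheticConfig, generate_proteome, generate_interactions
from .model_eval import (
    ModelConfig,
    BASELINE_ENCODER_PRESET,
    EvalMetrics,
    MLPPairClassifier,
    train_mlp,
    predict,
    evaluate,
    holdout_repeat,
    classic_classifier,
)

__version__ = "1.0.0"

ENCODERS = {
    "mos": MOSEncoder,
    "ct": CTEncoder,
    "ac": ACEncoder,
    "ld": LDEncoder,
}


def get_encoder(name: str):
    """Instantiate an encoder by case-insensitive name (mos | ct | ac | ld)."""
    key = name.lower()
    if key not in ENCODERS:
        raise ValueError(f"unknown encoder {name!r}; choose from {sorted(ENCODERS)}")
    return ENCODERS[key]()
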
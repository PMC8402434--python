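"""phenospec: hyperspectral leaf reflectance phenotyping of plant heat stress.

Class-structured leaf spectra (real cubes or synthetic stand-ins) are
reduced to per-leaf mean spectra, encoded with LDA-derived continuous
class codes (BPV) or equal-interval codes (SPRI), modelled with PLS1
discriminant analysis, compressed to fewer than 20 wavebands by a
VIP -> SPA ensemble, and projected back onto images pixel by pixel.
"""

__version__ = "0.1.0"

from .containers import HyperCube, LeafMask, SpectrumTable
from .encoding import (
    GroupEncoding,
    LDAModel,
    best_projection_values,
    encode_groups_bpv,
    encode_groups_spri,
    fit_lda,
)
from .envi import calibrate_reflectance, crop_bands, read_envi, write_envi
from .extraction import mean_spectra, segment_leaf, split_cal_val
from .imaging import PredictionMap, predict_map, render_map
from .pls import (
    AccuracyTable,
    PLSDAResults,
    PLSDiscriminant,
    PLSModel,
    accuracy_table,
    choose_n_lv,
    classify,
    fit_pls1,
    predict,
    vip,
)
from .pipeline import RunConfig, run_pipeline
from .selection import BandSelection, ensemble_select, spa_chain, spa_select, vip_filter
from .synthetic import (
    ClassArchetype,
    Ellipse,
    NoiseConfig,
    make_archetypes,
    simulate_cube,
    simulate_spectra,
)

__all__ = [
    "HyperCube", "LeafMask", "SpectrumTable",
    "GroupEncoding", "LDAModel", "fit_lda", "best_projection_values",
    "encode_groups_bpv", "encode_groups_spri",
    "read_envi", "write_envi", "calibrate_reflectance", "crop_bands",
    "segment_leaf", "mean_spectra", "split_cal_val",
    "PLSModel", "PLSDiscriminant", "PLSDAResults", "AccuracyTable",
    "fit_pls1", "choose_n_lv", "predict", "classify", "accuracy_table", "vip",
    "BandSelection", "vip_filter", "spa_chain", "spa_select", "ensemble_select",
    "PredictionMap", "predict_map", "render_map",
    "ClassArchetype", "NoiseConfig", "Ellipse",
    "make_archetypes", "simulate_spectra", "simulate_cube",
    "RunConfig", "run_pipeline",
]
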
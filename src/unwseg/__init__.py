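"""unwseg: nucleus segmentation with class-guided feature alignment.

A U-shaped encoder-decoder for stained pathology images that inserts two
plug-and-play alignment blocks at the bottleneck: Feature Center Alignment
(class-region instance normalization guided by labels in training and by a
pre-segmentation branch at inference) and Feature Distribution Alignment
(classifier-weight-guided grouped instance whitening).  Both strip
image-specific stain/contrast "style" from the features while preserving
class semantics, which is what lets a model trained on one staining
appearance generalise to another.
"""

from .primitives import (instance_normalize, channel_covariance,
                         batched_channel_covariance, iw_loss,
                         covariance_oracle, DEFAULT_BETA)
from .fca import (FCA, ClassAffine, class_region_normalize, highlight_class,
                  FeatureRefine, RegionMaskHead, make_region_mask,
                  region_normalize, fca_loss, DEFAULT_THRESHOLD)
from .fda import ChannelGrouping, rank_channels, build_groups, fda_loss
from .metrics import (ConfusionCounts, MetricsReport, confusion,
                      compute_metrics, aggregate, metrics_frame)
from .synthetic import (StyleDomain, GeneratorConfig, SegSample, STYLES,
                        generate_dataset, augment, AUGMENT_OPS,
                        make_feature_fixture, split_dataset, kfold_split,
                        gaussian_denoise)
from .unw import (ModelConfig, TrainConfig, UNW, build_unw, total_loss,
                  train, predict, evaluate, save_checkpoint, load_checkpoint)
from .experiments import (VARIANTS, variant_config, domain_shift_data,
                          run_variant, ablation)

__version__ = "0.1.0"
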
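import numpy as np
import pytest

from hyperbroad.pipeline import AutoencoderConfig, CvConfig, PipelineConfig
from hyperbroad.bls import BlsConfig
from hyperbroad.synthetic import SyntheticSpec, generate_subjects


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-scale dataset: 20 subjects, 16 ROIs in 4 modules."""
    return SyntheticSpec(
        n_per_class=10,
        n_rois=16,
        n_timepoints=60,
        n_modules=4,
        within_module_corr=0.6,
        between_module_corr_control=0.1,
        between_module_corr_case=0.5,
        noise_sd=0.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    subjects, labels = generate_subjects(small_spec)
    return subjects, np.asarray(labels)


@pytest.fixture()
def small_config() -> PipelineConfig:
    """Light pipeline configuration for fast CV tests."""
    return PipelineConfig(
        autoencoder=AutoencoderConfig(bottleneck=12, epochs=30),
        bls=BlsConfig(n_map_groups=4, nodes_per_group=20, enh_nodes_per_group=8),
        cv=CvConfig(n_folds=5, n_repeats=1, seed=7),
    )
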
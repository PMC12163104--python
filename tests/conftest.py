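import dataclasses

import numpy as np
import pytest

from hipshape import PipelineConfig, build_subject
from hipshape.pipeline import run_pipeline
from hipshape.synthetic import GeneratorConfig, HipParams, SubjectParams, generate_cohort


def make_subject(
    ce=30.0, ai=10.0, acav=20.0, aasa=50.0, pasa=90.0, noise_sd=0.0, seed=0, **kwargs
):
    """One symmetric surrogate subject with explicit hip angles."""
    hp = dict(ce=ce, ai=ai, acav=acav, aasa=aasa, pasa=pasa)
    return build_subject(
        SubjectParams(
            left=HipParams(**hp), right=HipParams(**hp), noise_sd=noise_sd, seed=seed, **kwargs
        )
    )


def small_cohort_config(n_subjects=10, n_female=6, seed=123, **overrides):
    return GeneratorConfig(
        n_subjects=n_subjects,
        n_female=n_female,
        seed=seed,
        **overrides,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """10-subject default-condition cohort for alignment/SSM tests."""
    return generate_cohort(small_cohort_config())


@pytest.fixture(scope="session")
def default_result():
    """The full default pipeline (75 subjects, master seed 0) with intermediates."""
    return run_pipeline(PipelineConfig(), return_intermediates=True)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def replace_gen(cfg: GeneratorConfig, **kw) -> GeneratorConfig:
    return dataclasses.replace(cfg, **kw)
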
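import numpy as np
import pytest

from wmhperf import pipeline, synthetic
from wmhperf.volumes import LabelVolume


@pytest.fixture(scope="session")
def small_cohort_spec():
    """A small but full-size-grid cohort shared across integration tests."""
    return synthetic.CohortSpec(
        n_subjects=3,
        n_longitudinal=2,
        voxel_noise_cv=0.05,
        lesion_count_dist={"kind": "poisson", "mean": 9.0, "min": 5},
        seed=20240917,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_spec):
    """Generated subjects (anatomy, lesions, painted sessions) keyed by index."""
    return {s: synthetic.generate_subject(small_cohort_spec, s) for s in range(small_cohort_spec.n_subjects)}


@pytest.fixture(scope="session")
def small_cohort_tables(small_cohort_spec):
    """ROI and lesion tables from running the pipeline over the small cohort."""
    return pipeline.cohort_tables(small_cohort_spec)


def masks_from_subject(data, session):
    """Raw-mask view of a generated subject, as the pipeline would load it."""
    anatomy = data["anatomy"]
    labels = (
        data["lesions"].baseline_labels if session == "baseline" else data["lesions"].followup_labels
    )
    return pipeline.SubjectMasks(
        ventricle=anatomy.as_volume("ventricle"),
        gm=anatomy.as_volume("gm"),
        wm=anatomy.as_volume("wm"),
        csf=anatomy.as_volume("csf"),
        brain=anatomy.as_volume("brain"),
        wmh=LabelVolume(labels > 0, anatomy.voxel_size_mm),
    )
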
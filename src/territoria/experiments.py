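"""Reference experiments on synthetic cohorts.

Self-contained, seeded recipes that exercise the whole pipeline on
generator-defined study conditions: end-to-end axial-orientation cohorts
(power and false-positive behaviour of the binomial test against the
random-positioning null) and the calibration of that test under the
uniform-angle null.  These back the package's reproducibility checks and
the worked examples.
"""

from __future__ import annotations

import numpy as np

from ._geometry import is_major_parallel
from .config import RunConfig
from .pipeline import measure_scene
from .stats import binomial_obs_vs_expected
from .synth import (
    CohortGroup,
    CohortSpec,
    NoiseSpec,
    PlacementSpec,
    concentration_for_major_fraction,
    sample_axial_angles,
    simulate_cohort_scenes,
)

# Study conditions for end-to-end axial cohorts: one mononucleated cell per
# frame, one territory per nucleus at ~5% of the nuclear area, clearly
# elongated nuclei so the major axis is well defined, confocal-like noise.
AXIAL_COHORT_FRAME = (128, 128)
AXIAL_SEMI_MAJOR_RANGE = (34.0, 40.0)
AXIAL_AXIS_RATIO_RANGE = (1.4, 1.6)


def _axial_cohort_spec(p_major_true: float, n_nuclei: int) -> CohortSpec:
    kappa = concentration_for_major_fraction(p_major_true)
    group = CohortGroup(
        name="cohort",
        n_scenes=n_nuclei,
        semi_major_px_range=AXIAL_SEMI_MAJOR_RANGE,
        axis_ratio_range=AXIAL_AXIS_RATIO_RANGE,
        placement=PlacementSpec(
            n_territories=1,
            angular_concentration=kappa,
            territory_area_fraction=0.05,
        ),
    )
    return CohortSpec(groups=[group], image_shape=AXIAL_COHORT_FRAME, noise=NoiseSpec())


def run_axial_cohort(
    p_major_true: float, n_nuclei: int, seed: int
) -> tuple[int, int]:
    """Full-pipeline axial measurement of one synthetic cohort.

    Renders ``n_nuclei`` single-nucleus scenes whose territories have true
    major-parallel probability ``p_major_true``, runs segmentation,
    assignment, morphometry and axial classification, and returns
    ``(k_major, n_measured)``.
    """
    config = RunConfig(input_dir=".", out_dir=".")
    k = n = 0
    for _, scene_id, scene in simulate_cohort_scenes(
        _axial_cohort_spec(p_major_true, n_nuclei), seed
    ):
        _, terr_df, _ = measure_scene("cohort", scene_id, scene.dapi, scene.paint, config)
        measured = terr_df[terr_df["axial_class"] != ""] if len(terr_df) else terr_df
        n += len(measured)
        if len(measured):
            k += int((measured["axial_class"] == "major_parallel").sum())
    return k, n


def axial_rejection_rate(
    p_major_true: float,
    n_cohorts: int,
    n_nuclei: int,
    seed: int,
    p0: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Fraction of end-to-end cohorts where the binomial test rejects p0."""
    seeds = np.random.SeedSequence(seed).generate_state(n_cohorts) % (2**31)
    rejections = 0
    for s in seeds:
        k, n = run_axial_cohort(p_major_true, n_nuclei, int(s))
        if n and binomial_obs_vs_expected(k, n, p0).p_value < alpha:
            rejections += 1
    return rejections / n_cohorts


def binomial_calibration_rate(
    n_cohorts: int = 1000,
    n_per_cohort: int = 100,
    seed: int = 0,
    p0: float = 0.5,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the binomial test under the uniform-angle null.

    Samples cohorts of axial angles straight from the generator's angular
    law at concentration 0 (uniform on [0, 180)), classifies them with the
    45/135-degree rule, and tests each cohort's major count against p0.
    The imaging layer is bypassed because, by symmetry, measurement noise
    cannot change the Bernoulli(1/2) class distribution under this null.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_cohorts):
        theta = sample_axial_angles(n_per_cohort, 0.0, rng)
        k = int(sum(is_major_parallel(t) for t in theta))
        if binomial_obs_vs_expected(k, n_per_cohort, p0).p_value <= alpha:
            rejections += 1
    return rejections / n_cohorts
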
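import numpy as np
import pytest

from caroseg import geometry as g
from caroseg import phantom as ph


@pytest.fixture(scope="session")
def cylinder_stack():
    """Coaxial circular cylinders R=4 mm, r=2 mm, length 10 mm."""
    contours = {}
    for z in np.arange(0.0, 10.0001, 2.0):
        contours[float(z)] = (
            g.circle_contour(4.0, z=z, boundary_kind="MAB"),
            g.circle_contour(2.0, z=z, boundary_kind="LIB"),
        )
    return g.ContourStack(contours=contours, bifurcation_z=10.0, isd=2.0)


@pytest.fixture(scope="session")
def rendered_case():
    """One rendered baseline phantom case (shared across tests)."""
    cohort = ph.sample_cohort(1, ph.CohortParams(render=True), seed=11)
    return cohort[0][0]


@pytest.fixture(scope="session")
def geometry_only_cases():
    """Three phantom cases without rendered volumes (fast)."""
    cohort = ph.sample_cohort(3, ph.CohortParams(render=False), seed=23)
    return [base for base, _ in cohort]
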
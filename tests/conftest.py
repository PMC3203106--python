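import numpy as np
import pytest

from mamrud import phantom, segmentation


@pytest.fixture(scope="session")
def default_stack():
    """A bud-stage phantom with the standard labelling fractions."""
    spec = phantom.PhantomSpec(rng_seed=7)
    sections, truth = phantom.generate_stack(spec)
    return spec, sections, truth


@pytest.fixture(scope="session")
def sphere_stack():
    """A 50 um digital sphere, fully covered by 21 five-um sections."""
    spec = phantom.PhantomSpec(semi_axes_um=(50.0, 50.0, 50.0), n_sections=21, rng_seed=3)
    sections, truth = phantom.generate_stack(spec)
    return spec, sections, truth


@pytest.fixture(scope="session")
def central_labeling(default_stack):
    """Full compartment labelling of the central section of the phantom."""
    spec, sections, truth = default_stack
    index = truth.central_index
    section = next(s for s in sections if s.index == index)
    annotations = phantom.annotations_from_truth(truth, index)
    labeling, overlay = segmentation.label_compartments(section.image, annotations, spec.pixel_size_um)
    return section, annotations, labeling, overlay


def section_by_index(sections, index):
    return next(s for s in sections if s.index == index)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.count_nonzero(a | b)
    return np.count_nonzero(a & b) / union if union else 1.0
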
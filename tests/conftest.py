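"""Shared fixtures: phantoms and their segmentations, computed once per session."""

from __future__ import annotations

import pytest
from hypothesis import settings

from lvtrab.phantom import PhantomSpec, generate_phantom, trabeculation_sweep
from lvtrab.segmentation import segment_slice

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SWEEP_FRACTIONS = (0.1, 0.2, 0.3, 0.4)


@pytest.fixture(scope="session")
def default_phantom():
    """Moderately trabeculated 9-slice study with RV, default acquisition."""
    return generate_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_segs(default_phantom):
    stack, _ = default_phantom
    return [segment_slice(s) for s in stack.slices]


@pytest.fixture(scope="session")
def clean_annulus():
    """Noise-free, strand-free, RV-free annulus with exactly known radii."""
    spec = PhantomSpec(
        n_trabeculae=0, rv_present=False, noise_sd=0.0, n_slices=1,
        cavity_radius=25.0, wall_thickness=8.0,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def sweep_data():
    return list(zip(SWEEP_FRACTIONS, trabeculation_sweep(PhantomSpec(), list(SWEEP_FRACTIONS))))


@pytest.fixture(scope="session")
def sweep_segs(sweep_data):
    """Full segmentations of every sweep stack (the expensive shared fixture)."""
    out = []
    for frac, (stack, truth) in sweep_data:
        out.append((frac, stack, truth, [segment_slice(s) for s in stack.slices]))
    return out


@pytest.fixture(scope="session")
def zero_phantom_segs():
    stack, truth = generate_phantom(PhantomSpec(n_trabeculae=0))
    return stack, truth, [segment_slice(s) for s in stack.slices]
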
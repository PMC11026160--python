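"""Shared fixtures: one default phantom generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from vesiquant import build_layers, layer_profile
from vesiquant.phantom import PhantomSpec, generate_bladder_phantom, phantom_masks


@pytest.fixture(scope="session")
def phantom_bundle():
    """Default-condition phantom (4:1 density ratio, λ = 95 µm), seed 1."""
    spec = PhantomSpec(seed=1)
    af, scattered, truth = generate_bladder_phantom(spec)
    return spec, af, scattered, truth


@pytest.fixture(scope="session")
def layer_bundle(phantom_bundle):
    """33 µm three-layer analysis of the session phantom."""
    spec, af, scattered, truth = phantom_bundle
    masks = phantom_masks(truth)
    layers = build_layers(masks["bc"], urothelium=masks["u1"], tumour=masks["t1"])
    profile = layer_profile(scattered, layers)
    return masks, layers, profile


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
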
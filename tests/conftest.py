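"""Shared fixtures: small seeded phantoms so no test touches real data."""

from __future__ import annotations

import numpy as np
import pytest

import fintrack as ft


@pytest.fixture(scope="session")
def small_spec() -> ft.PhantomSpec:
    """Reduced imaging geometry: 160×160 px, 12 frames, 3 z, 5 cells."""
    return ft.PhantomSpec(
        width=160, height=160,
        metadata=ft.ImagingMetadata(n_frames=12, n_z=3),
        wound=ft.WoundSpec(perimeter_um=120.0),
        cells=ft.CellSpec(n=5),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(lapses, truth) for the reduced phantom; generated once per session."""
    return ft.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_spec(small_spec) -> ft.PhantomSpec:
    """Same scene without noise: rendered values equal ground truth."""
    from dataclasses import replace
    return replace(small_spec, noise=ft.NoiseSpec(poisson_scale=0.0, read_sd=0.0))


@pytest.fixture(scope="session")
def clean_phantom(clean_spec):
    return ft.generate_phantom(clean_spec)


@pytest.fixture(scope="session")
def metadata() -> ft.ImagingMetadata:
    return ft.ImagingMetadata()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
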
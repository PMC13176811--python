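"""Shared fixtures: rasterized phantoms measured once per session."""

from __future__ import annotations

import numpy as np
import pytest

from aortamorph import synthetic
from aortamorph.pipeline import measure_mask


def tube_spec(
    name: str = "tube",
    length: float = 60.0,
    diameter: float = 30.0,
    ovality: float = 0.0,
    curved: bool = False,
) -> synthetic.AortaSpec:
    """Constant-profile tube: straight along z or a 60-degree planar arc."""
    if curved:
        cp = synthetic._arc_control_points(length)
    else:
        z = np.linspace(0.0, length, 9)
        cp = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
    return synthetic.AortaSpec(
        name=name,
        phase="systole",
        total_length=length,
        centerline_control_points=cp,
        diameter_knots=((0.0, diameter), (1.0, diameter)),
        ovality_knots=((0.0, ovality), (1.0, ovality)),
        phase_offset_knots=((0.0, 0.0), (1.0, 0.0)),
    )


@pytest.fixture(scope="session")
def cylinder_run():
    spec = tube_spec("cylinder", length=60.0, diameter=30.0)
    img, lms = synthetic.rasterize(spec, 0.5)
    return {"spec": spec, "img": img, "lms": lms}


@pytest.fixture(scope="session")
def dg_run():
    """Dilated systolic archetype through the full pipeline at 0.5 mm."""
    spec = synthetic.make_archetype("dilated", "systole")
    img, lms = synthetic.rasterize(spec, 0.5)
    cl, profiles, sweep = measure_mask(img, lms["stj"], lms["bt"], "systole",
                                       sweep_step_mm=1.0)
    return {"spec": spec, "img": img, "lms": lms, "cl": cl,
            "profiles": profiles, "sweep": sweep}


@pytest.fixture(scope="session")
def ndg_run():
    """Nondilated systolic archetype through the full pipeline at 0.5 mm."""
    spec = synthetic.make_archetype("nondilated", "systole")
    img, lms = synthetic.rasterize(spec, 0.5)
    cl, profiles, _ = measure_mask(img, lms["stj"], lms["bt"], "systole")
    return {"spec": spec, "img": img, "lms": lms, "cl": cl, "profiles": profiles}


@pytest.fixture(scope="session")
def default_cohort():
    return synthetic.sample_cohort(35, 100, seed=20240501)
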
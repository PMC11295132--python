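"""Shared fixtures: a small synthetic CV-ramp acquisition with planted
gangliosides, decoys and noise, plus the matching target list."""

from __future__ import annotations

import pytest

from gangliofaims.faims import build_schedule
from gangliofaims.masslist import GangliosideClass, MassListEntry
from gangliofaims.synthetic import PlantSpec, generate


@pytest.fixture(scope="session")
def ramp_schedule():
    return build_schedule(25, 77, 2, 6)


def make_demo_plants() -> list[PlantSpec]:
    """Ten genuine plants spanning charges 1-5 plus two decoys.

    Decoys carry MS1 signal but no mandatory diagnostic fragments in their
    MS/MS scans, so a correct pipeline must reject them.
    """
    return [
        PlantSpec("GM3", "34:1;O2", charges={1: 1.0}),
        PlantSpec("GM1", "36:1;O2", charges={1: 1.0}),
        PlantSpec("GD1", "36:1;O2", charges={2: 1.0}),
        PlantSpec("GD1", "38:1;O2", charges={2: 1.0}, molecular={"18:1;O2/20:0": 1.0}),
        PlantSpec("GD3", "36:1;O2", charges={2: 1.0}),
        PlantSpec("GT1", "38:1;O2", charges={3: 1.0}),
        PlantSpec("GT3", "36:1;O2", charges={3: 1.0}),
        PlantSpec("GQ1", "38:1;O2", charges={4: 1.0}),
        PlantSpec("GP1", "38:1;O2", charges={5: 1.0}),
        PlantSpec("GD1-Ac", "36:1;O2", charges={2: 1.0}),
        PlantSpec("GD2", "36:1;O2", charges={2: 1.0}, decoy=True),
        PlantSpec("GT2", "38:1;O2", charges={3: 1.0}, decoy=True),
    ]


@pytest.fixture(scope="session")
def demo_plants():
    return make_demo_plants()


@pytest.fixture(scope="session")
def demo_series(demo_plants, ramp_schedule):
    """Noise-on acquisition (plant intensity ~1e3 x noise floor), seed-fixed."""
    series, manifest = generate(
        demo_plants,
        ramp_schedule,
        noise_peaks=200,
        ms2_noise_peaks=50,
        noise_intensity_mean=1.0e3,
        seed=7,
    )
    return series, manifest


@pytest.fixture(scope="session")
def demo_masslist(demo_plants) -> list[MassListEntry]:
    """Targets: every planted (class, species, z) plus unplanted padding."""
    entries = [p.entry(z) for p in demo_plants for z in sorted(p.charges)]
    padding = [
        ("GM2", "35:2;O2", 1),
        ("GD3", "42:3;O3", 2),
        ("GQ1", "40:2;O2", 3),
        ("GT1", "33:0;O2", 2),
    ]
    for name, species, z in padding:
        entries.append(MassListEntry.build(GangliosideClass.from_name(name), species, z))
    return entries
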
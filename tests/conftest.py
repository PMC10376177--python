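"""Shared fixtures: synthetic stand-in proteins and ground-truthed LC-MS runs.

All LC-MS fixtures are generated programmatically with fixed seeds; the two
protein records are SYNTHETIC stand-ins with the length and adduct-site
geometry of a thermophilic (723 aa, M244/Y218/W90) and a mesophilic (750 aa,
M264/Y238/W90) fungal catalase-peroxidase, not the real sequences.
"""

import numpy as np
import pytest

from katglink.synthetic_data import (
    NoiseModel,
    PlantedSpecies,
    simulate_run,
    synthetic_katg_protein,
)


@pytest.fixture(scope="session")
def thermo_standin():
    return synthetic_katg_protein(
        "CthedisKatG-synthetic",
        length=723,
        sites={90: "W", 218: "Y", 244: "M"},
        seed=11,
        his_tag=True,
    )


@pytest.fixture(scope="session")
def meso_standin():
    return synthetic_katg_protein(
        "MagKatG1-synthetic",
        length=750,
        sites={90: "W", 238: "Y", 264: "M"},
        seed=13,
        his_tag=True,
    )


@pytest.fixture(scope="session")
def recovery_world():
    """One seeded 60-min run with 100 planted crosslink-sized species.

    Species masses 3-7 kDa, three charge states each, SNR >= 10 over an
    exponential noise floor; ground truth returned alongside.  Also provides
    100 decoy neutral masses at least 20 Da from every planted mass.
    """
    rng = np.random.default_rng(20230901)
    masses = np.sort(rng.uniform(3000.0, 7000.0, 100))
    centers = rng.uniform(5.0, 55.0, 100)
    species = [
        PlantedSpecies(
            mass=float(m),
            charges=(4, 5, 6),
            rt_center=float(c),
            rt_sigma=0.1,
            abundance=1e6,
            label=f"sp{i}",
        )
        for i, (m, c) in enumerate(zip(masses, centers))
    ]
    noise = NoiseModel(
        peaks_per_scan=50, mean_intensity=1e4, mz_jitter_ppm=2.0, seed=20230901
    )
    run, truth = simulate_run(species, scan_interval=0.05, run_length=60.0, noise=noise)

    decoys = []
    while len(decoys) < 100:
        m = float(rng.uniform(3000.0, 7000.0))
        if np.min(np.abs(masses - m)) >= 20.0:
            decoys.append(m)
    return run, species, truth, decoys
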
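"""Ground-truthed synthetic inputs for every pipeline stage.

Three generators emulate the three kinds of raw data the analysis consumes:

* centroided LC-MS runs with planted (crosslinked) peptide species — averagine
  isotope envelopes, several charge states, Gaussian elution profiles, and a
  configurable random-noise floor;
* linear absorbance kinetics traces with a known slope (spectrophotometric
  peroxidase/catalase assays);
* sigmoidal 350/330 nm fluorescence-ratio melting curves with a known
  midpoint (nanoDSF-style thermal unfolding).

Everything is driven by explicit integer seeds: identical seed and
parameters give byte-identical output.  A synthetic catalase-peroxidase-like
protein generator is included so that the full search can run end-to-end
without any external sequence database; its products are stand-ins, not the
real MagKatG1 / CthedisKatG chains.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .proteoforms import ISOTOPE_SPACING, PROTON, ProteinRecord, cleavage_sites
from .ms_signal import MSRun, Scan

__all__ = [
    "PlantedSpecies",
    "NoiseModel",
    "isotope_envelope",
    "simulate_run",
    "simulate_kinetics_trace",
    "simulate_melt_curve",
    "synthetic_katg_protein",
]

# averagine: average elemental composition per amino-acid residue,
# C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per 111.1254 Da
_AVERAGINE_MASS = 111.1254
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
# natural abundance of the dominant +1 heavy isotope per element
_HEAVY_P = {"C": 0.0107, "H": 0.000115, "N": 0.00364, "O": 0.00038, "S": 0.0076}


@dataclass(frozen=True)
class PlantedSpecies:
    """One species planted in a synthetic run, with full ground truth."""

    mass: float  # neutral monoisotopic, Da
    charges: tuple[int, ...]
    rt_center: float  # min
    rt_sigma: float  # min
    abundance: float  # apex intensity of the monoisotopic peak, per charge
    n_isotopes: int = 5
    label: str = ""

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.rt_sigma <= 0:
            raise ValueError("mass and rt_sigma must be positive")
        if any(z <= 0 for z in self.charges):
            raise ValueError("charges must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Random chemical-noise floor: uniform m/z positions, exponential heights."""

    baseline: float = 0.0
    peaks_per_scan: int = 0
    mean_intensity: float = 1.0
    mz_range: tuple[float, float] = (300.0, 2000.0)
    mz_jitter_ppm: float = 0.0  # applied to planted peaks
    seed: int = 0


def isotope_envelope(mass: float, n_peaks: int = 5) -> list[tuple[float, float]]:
    """Averagine-Poisson isotope envelope, normalised to max intensity 1.

    Returns (mass offset in Da, relative intensity) for the first ``n_peaks``
    isotopes.  The Poisson rate is the expected number of heavy-isotope
    substitutions for an averagine pseudo-peptide of this mass.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    n_units = mass / _AVERAGINE_MASS
    lam = sum(n_units * count * _HEAVY_P[el] for el, count in _AVERAGINE.items())
    weights = [math.exp(-lam) * lam**k / math.factorial(k) for k in range(n_peaks)]
    top = max(weights)
    return [(k * ISOTOPE_SPACING, w / top) for k, w in enumerate(weights)]


def simulate_run(
    species: list[PlantedSpecies],
    scan_interval: float = 0.01,
    run_length: float = 60.0,
    noise: NoiseModel = NoiseModel(),
) -> tuple[MSRun, pd.DataFrame]:
    """Build a centroided run from planted species plus a noise model.

    Scans lie on a regular RT grid.  Each species contributes, per charge,
    its isotope envelope at (M + k*1.00335 + z*proton)/z, scaled by a
    Gaussian elution profile centred on ``rt_center``.  The returned ground
    truth table records mass, charges, apex RT and observability per species.
    """
    if run_length <= 0:
        raise ValueError("run_length must be positive")
    rng = np.random.default_rng(noise.seed)
    rts = np.arange(scan_interval, run_length + 1e-9, scan_interval)
    truth_rows = []
    for sp in species:
        observable = 0.0 <= sp.rt_center <= run_length
        if not observable:
            warnings.warn(
                f"species {sp.label or sp.mass} elutes outside the run", stacklevel=2
            )
        truth_rows.append(
            {
                "label": sp.label or f"M{sp.mass:.3f}",
                "mass": sp.mass,
                "charges": ",".join(map(str, sp.charges)),
                "apex_rt": sp.rt_center,
                "abundance": sp.abundance,
                "observable": observable,
                "seed": noise.seed,
            }
        )
    envelopes = {sp: isotope_envelope(sp.mass, sp.n_isotopes) for sp in species}

    scans = []
    for rt in rts:
        mz_list: list[float] = []
        int_list: list[float] = []
        for sp in species:
            profile = math.exp(-0.5 * ((rt - sp.rt_center) / sp.rt_sigma) ** 2)
            if profile * sp.abundance < 1e-12:
                continue
            for z in sp.charges:
                for offset, rel in envelopes[sp]:
                    mz = (sp.mass + offset + z * PROTON) / z
                    if noise.mz_jitter_ppm > 0:
                        mz *= 1.0 + rng.normal(0.0, noise.mz_jitter_ppm * 1e-6)
                    mz_list.append(mz)
                    int_list.append(sp.abundance * rel * profile)
        if noise.peaks_per_scan > 0:
            lo, hi = noise.mz_range
            noise_mz = rng.uniform(lo, hi, noise.peaks_per_scan)
            noise_int = noise.baseline + rng.exponential(
                noise.mean_intensity, noise.peaks_per_scan
            )
            mz_list.extend(noise_mz.tolist())
            int_list.extend(noise_int.tolist())
        if not mz_list:
            mz_list, int_list = [], []
        scans.append(Scan(rt=float(rt), mz=np.array(mz_list), intensity=np.array(int_list)))
    run = MSRun(
        scans=scans,
        metadata={"generator": "katglink.synthetic_data", "seed": noise.seed},
    )
    return run, pd.DataFrame(truth_rows)


def simulate_kinetics_trace(
    slope: float,
    intercept: float = 0.0,
    duration: float = 1.0,
    interval: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Linear absorbance time course A(t) = intercept + slope*t + noise.

    ``slope`` is in absorbance units per minute, ``duration`` in minutes and
    ``interval`` in seconds (spectrophotometers sample every few seconds).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 1e-12, interval / 60.0)
    a = intercept + slope * t
    if noise_sd > 0:
        a = a + rng.normal(0.0, noise_sd, t.size)
    return pd.DataFrame({"time_min": t, "absorbance": a})


def simulate_melt_curve(
    tm: float,
    steepness: float = 2.0,
    lower: float = 0.80,
    upper: float = 0.95,
    t_min: float = 20.0,
    t_max: float = 95.0,
    t_step: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Logistic 350/330 fluorescence-ratio melting curve with midpoint ``tm``.

    ratio(T) = lower + (upper - lower) / (1 + exp((tm - T)/steepness)) + noise.
    The default 20-95 degC grid at 0.5 degC matches a 1 degC/min nanoDSF ramp
    sampled twice per degree.
    """
    t = np.arange(t_min, t_max + 1e-9, t_step)
    if not (t_min <= tm <= t_max):
        warnings.warn(f"Tm {tm} outside the temperature grid", stacklevel=2)
    elif tm < t_min + 3 * steepness or tm > t_max - 3 * steepness:
        warnings.warn(f"Tm {tm} near the grid edge; transition truncated", stacklevel=2)
    ratio = lower + (upper - lower) / (1.0 + np.exp((tm - t) / steepness))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ratio = ratio + rng.normal(0.0, noise_sd, t.size)
    return pd.DataFrame({"temperature_C": t, "ratio": ratio})


# amino-acid frequencies of an average globular protein (Swiss-Prot-like)
_AA_FREQ = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0674, "G": 0.0708, "H": 0.0227, "I": 0.0593,
    "L": 0.0965, "K": 0.0582, "M": 0.0241, "F": 0.0386, "P": 0.0472,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


def synthetic_katg_protein(
    protein_id: str,
    length: int,
    sites: dict[int, str],
    seed: int = 0,
    his_tag: bool = False,
) -> ProteinRecord:
    """SYNTHETIC stand-in for a catalase-peroxidase chain.

    Generates a random protein of the requested natural-chain ``length`` with
    the given residues pinned at the given 1-based positions (e.g.
    ``{90: "W", 218: "Y", 244: "M"}`` for the Met-Tyr-Trp adduct sites of a
    thermophilic KatG).  Positions adjacent to a pinned site are kept free of
    K/R/P so that each site sits strictly inside a tryptic peptide of
    reasonable size.  This is a stand-in with realistic composition, NOT the
    real MagKatG1 or CthedisKatG sequence.
    """
    for pos, letter in sites.items():
        if not 1 <= pos <= length:
            raise ValueError(f"site position {pos} outside [1, {length}]")
        if letter not in _AA_FREQ:
            raise ValueError(f"bad site residue {letter!r}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(_AA_FREQ))
    probs = np.array(list(_AA_FREQ.values()))
    probs = probs / probs.sum()
    seq = list(rng.choice(letters, size=length, p=probs))
    protected = set()
    for pos, letter in sites.items():
        seq[pos - 1] = letter
        protected.update({pos - 1, pos - 2, pos})
    # keep pinned sites strictly interior to their tryptic peptide
    for i in sorted(protected & set(range(length))):
        if i + 1 in sites:
            continue
        while seq[i] in "KRP":
            seq[i] = str(rng.choice(letters, p=probs))
    sequence = "".join(seq)
    # guarantee at least one cleavage site between consecutive pinned sites so
    # the adduct spans separate peptides, as in the real proteins
    positions = sorted(sites)
    for a, b in zip(positions, positions[1:]):
        segment = sequence[a:b - 1]
        if not cleavage_sites(segment + "A"):
            m = (a + b) // 2 - 1  # 0-based, strictly between the two sites
            chars = list(sequence)
            chars[m] = "K"
            if chars[m + 1] == "P":  # K-P is not cleaved
                chars[m + 1] = "A"
            sequence = "".join(chars)
    tag_span = None
    if his_tag:
        sequence = sequence + "HHHHHH"
        tag_span = (length + 1, length + 6)
    return ProteinRecord(
        id=protein_id,
        sequence=sequence,
        description=f"{protein_id} synthetic catalase-peroxidase stand-in",
        tag_span=tag_span,
    )
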
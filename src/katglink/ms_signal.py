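"""LC-MS run model, minimal I/O, XIC extraction, coelution and deconvolution.

Only centroided MS1 data are modelled: a run is an RT-ordered list of scans,
each a sparse list of (m/z, intensity) centroids.  Two on-disk forms are
supported: a JSON fixture (bit-stable, human-readable, used by the test
suite) and a minimal mzML subset (MS1 centroid spectra, 64-bit uncompressed
binary arrays) written and read with the standard library so that runs can be
exchanged with mainstream tools.
"""

from __future__ import annotations

import base64
import json
import struct
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .adduct_search import TheoreticalIonSeries
from .proteoforms import PROTON

__all__ = [
    "Scan",
    "MSRun",
    "XIC",
    "CoelutionEvidence",
    "DeconvolutionResult",
    "read_run",
    "write_run",
    "extract_xic",
    "detect_coelution",
    "deconvolute",
    "infer_charge_from_isotopes",
]


class RunFormatError(ValueError):
    """Malformed or unsupported LC-MS input."""


@dataclass
class Scan:
    rt: float  # retention time, minutes
    mz: np.ndarray  # sorted ascending
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise RunFormatError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise RunFormatError("negative intensity")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class MSRun:
    scans: list[Scan]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.scans:
            raise RunFormatError("empty run")
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            warnings.warn("scans not strictly RT-ordered; repairing", stacklevel=2)
            self.scans = sorted(self.scans, key=lambda s: s.rt)

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def rt(self) -> np.ndarray:
        cached = self.__dict__.get("_rt")
        if cached is None:
            cached = np.array([s.rt for s in self.scans])
            self.__dict__["_rt"] = cached
        return cached

    def _peak_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All centroids of the run sorted by m/z, with their scan numbers.

        Built lazily and cached; lets an XIC be extracted with one binary
        search instead of a pass over every scan.
        """
        cached = self.__dict__.get("_index")
        if cached is None:
            mz = np.concatenate([s.mz for s in self.scans]) if self.scans else np.array([])
            intensity = np.concatenate([s.intensity for s in self.scans])
            scan_of = np.concatenate(
                [np.full(s.mz.size, i, dtype=np.intp) for i, s in enumerate(self.scans)]
            )
            order = np.argsort(mz, kind="stable")
            cached = (mz[order], intensity[order], scan_of[order])
            self.__dict__["_index"] = cached
        return cached


@dataclass
class XIC:
    """Extracted ion chromatogram for one target m/z window."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    @property
    def apex_index(self) -> int:
        return int(np.argmax(self.intensity))

    @property
    def apex_rt(self) -> float:
        return float(self.rt[self.apex_index])

    @property
    def apex_intensity(self) -> float:
        return float(self.intensity[self.apex_index])


@dataclass
class CoelutionEvidence:
    """Apex agreement of several charge-state XICs of one candidate species."""

    apex_rt_by_charge: dict[int, float]
    rt_spread: float
    n_charges_found: int
    summed_intensity: float
    accepted: bool
    median_apex_rt: float | None = None


@dataclass
class DeconvolutionResult:
    """Neutral monoisotopic mass inferred from multiply charged signals."""

    monoisotopic_mass: float
    supporting_charges: list[int]
    per_charge_mass: dict[int, float]
    dispersion: float


def write_run(run: MSRun, path: str | Path, format: str = "json") -> None:
    """Write a centroided run as a JSON fixture or minimal mzML."""
    path = Path(path)
    if format == "json":
        payload = {
            "format": "katglink-msrun-fixture-v1",
            "metadata": run.metadata,
            "scans": [
                {"rt": s.rt, "mz": s.mz.tolist(), "intensity": s.intensity.tolist()}
                for s in run.scans
            ],
        }
        path.write_text(json.dumps(payload))
    elif format == "mzml":
        _write_mzml(run, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_run(path: str | Path, format: str | None = None) -> MSRun:
    """Read a run from a JSON fixture or the minimal mzML subset.

    The format is sniffed from the file when not given.  Profile-mode mzML
    spectra are rejected: peak-pick upstream, only centroided data are
    supported.
    """
    path = Path(path)
    if format is None:
        head = path.read_text(errors="replace")[:200].lstrip()
        format = "json" if head.startswith("{") else "mzml"
    if format in ("json", "fixture"):
        try:
            payload = json.loads(path.read_text())
            scans = [
                Scan(rt=s["rt"], mz=np.array(s["mz"]), intensity=np.array(s["intensity"]))
                for s in payload["scans"]
            ]
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise RunFormatError(f"{path}: not a run fixture ({exc})") from None
        return MSRun(scans=scans, metadata=payload.get("metadata", {}))
    if format == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unknown format {format!r}")


_MZML_NS = "http://psi.hupo.org/ms/mzml"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_RT = "MS:1000016"


def _encode_f64(values: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def _decode_f64(text: str, n: int) -> np.ndarray:
    raw = base64.b64decode(text)
    return np.array(struct.unpack(f"<{n}d", raw))


def _write_mzml(run: MSRun, path: Path) -> None:
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        f'<mzML xmlns="{_MZML_NS}" version="1.1.0">',
        f'  <run id="{run.metadata.get("id", "run")}">',
        f'    <spectrumList count="{len(run.scans)}">',
    ]
    for i, scan in enumerate(run.scans):
        mz64, int64 = _encode_f64(scan.mz), _encode_f64(scan.intensity)
        lines += [
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{scan.mz.size}">',
            f'        <cvParam accession="{_ACC_CENTROID}" name="centroid spectrum"/>',
            '        <scanList count="1"><scan>',
            f'          <cvParam accession="{_ACC_RT}" name="scan start time" value="{scan.rt!r}" unitName="minute"/>',
            "        </scan></scanList>",
            '        <binaryDataArrayList count="2">',
            f'          <binaryDataArray><cvParam accession="{_ACC_MZ_ARRAY}" name="m/z array"/>'
            f"<binary>{mz64}</binary></binaryDataArray>",
            f'          <binaryDataArray><cvParam accession="{_ACC_INT_ARRAY}" name="intensity array"/>'
            f"<binary>{int64}</binary></binaryDataArray>",
            "        </binaryDataArrayList>",
            "      </spectrum>",
        ]
    lines += ["    </spectrumList>", "  </run>", "</mzML>", ""]
    path.write_text("\n".join(lines))


def _read_mzml(path: Path) -> MSRun:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise RunFormatError(f"{path}: malformed XML ({exc})") from None
    ns = {"m": _MZML_NS}
    scans = []
    for spectrum in tree.iter(f"{{{_MZML_NS}}}spectrum"):
        accessions = {cv.get("accession") for cv in spectrum.iter(f"{{{_MZML_NS}}}cvParam")}
        if _ACC_PROFILE in accessions:
            raise RunFormatError(
                f"{path}: profile-mode spectrum found; centroid the data first "
                "(only centroided MS1 spectra are supported)"
            )
        n = int(spectrum.get("defaultArrayLength", 0))
        rt = 0.0
        for cv in spectrum.iter(f"{{{_MZML_NS}}}cvParam"):
            if cv.get("accession") == _ACC_RT:
                rt = float(cv.get("value"))
                if cv.get("unitName", "minute").lower() in ("second", "seconds"):
                    rt /= 60.0
        mz = intensity = None
        for bda in spectrum.iter(f"{{{_MZML_NS}}}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{{{_MZML_NS}}}cvParam")}
            binary = bda.find("m:binary", ns)
            values = _decode_f64(binary.text or "", n)
            if _ACC_MZ_ARRAY in accs:
                mz = values
            elif _ACC_INT_ARRAY in accs:
                intensity = values
        if mz is None or intensity is None:
            raise RunFormatError(f"{path}: spectrum missing m/z or intensity array")
        scans.append(Scan(rt=rt, mz=mz, intensity=intensity))
    if not scans:
        raise RunFormatError(f"{path}: empty run")
    return MSRun(scans=scans, metadata={"source": str(path)})


def extract_xic(run: MSRun, mz: float, tol_ppm: float = 10.0) -> XIC:
    """Sum, per scan, the intensity of centroids within tol_ppm of ``mz``."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    half = mz * tol_ppm * 1e-6
    all_mz, all_intensity, scan_of = run._peak_index()
    a = np.searchsorted(all_mz, mz - half, side="left")
    b = np.searchsorted(all_mz, mz + half, side="right")
    trace = np.bincount(
        scan_of[a:b], weights=all_intensity[a:b], minlength=len(run.scans)
    )
    return XIC(target_mz=mz, tol_ppm=tol_ppm, rt=run.rt, intensity=trace)


def _apex_above_floor(xic: XIC, floor_factor: float = 3.0) -> bool:
    nonzero = xic.intensity[xic.intensity > 0]
    if nonzero.size == 0:
        return False
    # robust floor: apex must clear 3x the median nonzero trace intensity
    return xic.apex_intensity > floor_factor * float(np.median(nonzero))


def detect_coelution(
    run: MSRun,
    series: TheoreticalIonSeries,
    tol_ppm: float = 10.0,
    rt_tol: float = 0.2,
    min_charges: int = 2,
) -> CoelutionEvidence:
    """Test whether several charge-state XICs of one species reach apex together.

    For each theoretical ion form an XIC is extracted; apexes that clear the
    noise floor are collected and the species is accepted when at least
    ``min_charges`` of them lie within ``rt_tol`` minutes of their median.
    """
    apexes: dict[int, float] = {}
    summed = 0.0
    for z in series.charges:
        xic = extract_xic(run, series.mz_for(z), tol_ppm)
        if _apex_above_floor(xic):
            apexes[z] = xic.apex_rt
            summed += xic.apex_intensity
    if not apexes:
        return CoelutionEvidence({}, 0.0, 0, 0.0, False)
    rts = np.array(list(apexes.values()))
    median_rt = float(np.median(rts))
    coeluting = {z: rt for z, rt in apexes.items() if abs(rt - median_rt) <= rt_tol}
    rts_all = np.array(list(apexes.values()))
    spread = float(rts_all.max() - rts_all.min())
    accepted = len(coeluting) >= min_charges
    return CoelutionEvidence(
        apex_rt_by_charge=apexes,
        rt_spread=spread,
        n_charges_found=len(apexes),
        summed_intensity=summed,
        accepted=accepted,
        median_apex_rt=float(np.median(list(coeluting.values()))) if coeluting else median_rt,
    )


def deconvolute(
    run: MSRun,
    series: TheoreticalIonSeries,
    evidence: CoelutionEvidence,
    tol_ppm: float = 10.0,
    correct_isotope_misassignment: bool = False,
) -> DeconvolutionResult:
    """Estimate the neutral monoisotopic mass from the coeluting charge states.

    In the scan nearest the median apex RT, the most intense centroid within
    tolerance of each supporting ion form is read off and inverted to a
    neutral mass (z * m/z - z * proton); the per-charge estimates are
    aggregated by their median, with the max deviation reported as dispersion.

    With ``correct_isotope_misassignment`` the windows one isotope above and
    below the target (+-1.00335/z) are searched too and the inverted mass is
    shifted back by the corresponding whole isotope; off by default, since
    theory and the generator both target the monoisotopic peak.
    """
    from .proteoforms import ISOTOPE_SPACING

    if not evidence.accepted and evidence.n_charges_found == 0:
        raise ValueError("no supporting peaks: evidence is empty")
    rts = run.rt
    scan = run.scans[int(np.argmin(np.abs(rts - evidence.median_apex_rt)))]
    per_charge: dict[int, float] = {}
    for z in sorted(evidence.apex_rt_by_charge):
        offsets = (-1, 0, 1) if correct_isotope_misassignment else (0,)
        best_intensity, best_mass = 0.0, None
        for k in offsets:
            target = series.mz_for(z) + k * ISOTOPE_SPACING / z
            half = target * tol_ppm * 1e-6
            a = np.searchsorted(scan.mz, target - half, side="left")
            b = np.searchsorted(scan.mz, target + half, side="right")
            if b <= a:
                continue
            idx = a + int(np.argmax(scan.intensity[a:b]))
            if scan.intensity[idx] > best_intensity:
                best_intensity = float(scan.intensity[idx])
                best_mass = z * float(scan.mz[idx]) - z * PROTON - k * ISOTOPE_SPACING
        if best_mass is None:
            continue  # degraded: drop this charge
        per_charge[z] = best_mass
    if not per_charge:
        raise ValueError("no supporting peaks within tolerance in the apex scan")
    estimates = np.array(list(per_charge.values()))
    estimate = float(np.median(estimates))
    return DeconvolutionResult(
        monoisotopic_mass=estimate,
        supporting_charges=sorted(per_charge),
        per_charge_mass=per_charge,
        dispersion=float(np.max(np.abs(estimates - estimate))),
    )


def infer_charge_from_isotopes(
    mz: np.ndarray,
    max_spacing_irregularity: float = 0.2,
    assignment_tolerance: float = 0.05,
) -> int:
    """Charge from the spacing of consecutive isotope peaks in an m/z window.

    z = round(1.00335 / median spacing).  Raises when individual spacings
    deviate from their median by more than ``max_spacing_irregularity``
    (mixed or missing peaks), or when the median spacing is not within
    ``assignment_tolerance`` of 1.00335/z for the nearest integer z (the
    window sits between two charge hypotheses).
    """
    from .proteoforms import ISOTOPE_SPACING

    mz = np.sort(np.asarray(mz, dtype=float))
    if mz.size < 2:
        raise ValueError("need at least 2 isotope peaks")
    spacings = np.diff(mz)
    med = float(np.median(spacings))
    if np.any(np.abs(spacings - med) / med > max_spacing_irregularity):
        raise ValueError("ambiguous charge: irregular isotope spacing in window")
    z = max(1, round(ISOTOPE_SPACING / med))
    implied = ISOTOPE_SPACING / z
    if abs(med - implied) / implied > assignment_tolerance:
        raise ValueError(
            f"ambiguous charge: median spacing {med:.5f} Th is not close to "
            f"1.00335/z for any integer z"
        )
    return z
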
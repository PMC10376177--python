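"""End-to-end targeted adduct search: configuration, orchestration, CLI, reports.

The search composes the library stages in the order a targeted crosslink
analysis runs them: tryptic digestion of the protein, enumeration of
candidate crosslinked peptide combinations for the adduct sites, theoretical
ion series per candidate, XIC coelution detection across charge states in
the LC-MS run, charge deconvolution to a neutral monoisotopic mass, and
finally mass matching against the bond-corrected theoretical value.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd

from . import __version__
from .adduct_search import (
    AdductSpec,
    CrosslinkCandidate,
    MatchReport,
    enumerate_candidates,
    ion_series,
    match_observed,
)
from .kinetics import AssayContext, fit_linear_rate, melt_analysis, specific_activity
from .ms_signal import MSRun, detect_coelution, deconvolute, read_run, write_run
from .proteoforms import (
    DEFAULT_MODS,
    ModificationScheme,
    digest,
    read_fasta,
)
from .synthetic_data import (
    NoiseModel,
    PlantedSpecies,
    simulate_run,
)

logger = logging.getLogger("katglink")

__all__ = ["PipelineConfig", "RunReport", "search_adduct", "cli"]


@dataclass
class PipelineConfig:
    """Resolved configuration of one targeted search."""

    fasta_path: str
    protein_id: str
    sites: str  # "M244,Y218,W90"-style
    run_path: str
    out_dir: str = "."
    enzyme: str = "trypsin"
    max_missed: int = 2
    z_min: int = 3
    z_max: int = 8
    tol_ppm: float = 10.0
    rt_tol_min: float = 0.2
    min_charges: int = 2
    mass_tol_da: float = 0.05
    include_noncontiguous: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tol_ppm", "rt_tol_min", "mass_tol_da"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        flat: dict = {}
        for key, value in data.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        return cls(**flat)

    def validate_paths(self) -> None:
        for p in (self.fasta_path, self.run_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)

    def digest_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Everything one search produced, ready to serialise."""

    config: PipelineConfig
    matches: list[MatchReport]
    rejected: list[dict]
    n_candidates: int
    provenance: dict = field(default_factory=dict)

    @property
    def accepted(self) -> list[MatchReport]:
        return [m for m in self.matches if m.accepted]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.matches:
            rows.append(
                {
                    "candidate": m.candidate.label(),
                    "sites": ",".join(map(str, m.candidate.site_positions)),
                    "n_peptides": m.candidate.n_peptides,
                    "bond_count": m.candidate.bond_count,
                    "naive_sum_mass": round(m.candidate.naive_sum_mass, 5),
                    "corrected_mass": round(m.candidate.corrected_mass, 5),
                    "observed_mass": round(m.observed_mass, 5),
                    "rounded_observed": m.rounded_observed,
                    "delta_to_naive": round(m.delta_to_naive, 5),
                    "delta_to_corrected": round(m.delta_to_corrected, 5),
                    "inferred_bond_count": m.inferred_bond_count,
                    "accepted": m.accepted,
                }
            )
        for r in self.rejected:
            rows.append(r)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "matches.tsv", sep="\t", index=False)
        summary = {
            "n_candidates": self.n_candidates,
            "n_accepted": len(self.accepted),
            "accepted": [
                {
                    "candidate": m.candidate.label(),
                    "observed_mass": m.observed_mass,
                    "rounded_observed": m.rounded_observed,
                    "inferred_bond_count": m.inferred_bond_count,
                }
                for m in self.accepted
            ],
            "provenance": self.provenance,
            "config": self.config.__dict__,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, default=str))


def search_adduct(
    config: PipelineConfig,
    run: MSRun | None = None,
    mods: ModificationScheme = DEFAULT_MODS,
) -> RunReport:
    """Run the full targeted crosslink search described by ``config``."""
    logger.info("stage: load inputs")
    records = {r.id: r for r in read_fasta(config.fasta_path)}
    if config.protein_id not in records:
        raise KeyError(f"protein {config.protein_id!r} not in {config.fasta_path}")
    protein = records[config.protein_id]
    spec = AdductSpec.parse(config.protein_id, config.sites)
    spec.validate_against(protein)
    if run is None:
        run = read_run(config.run_path)

    logger.info("stage: digest")
    peptides = digest(protein, config.enzyme, config.max_missed)

    logger.info("stage: enumerate candidates")
    candidates = enumerate_candidates(
        peptides, spec, mods, include_noncontiguous=config.include_noncontiguous
    )

    logger.info("stage: XIC coelution + deconvolution over %d candidates", len(candidates))
    matches: list[MatchReport] = []
    rejected: list[dict] = []
    for cand in candidates:
        # XIC targets are computed for both mass hypotheses: the bond-corrected
        # mass and the naive sum (targets are calculated disregarding bond
        # losses, so a species lacking the crosslink is still detected and can
        # then be rejected on its mass delta).
        evidence = None
        series = None
        hypotheses = [cand.corrected_mass]
        if cand.bond_count > 0:
            hypotheses.append(cand.naive_sum_mass)
        for neutral_mass in hypotheses:
            trial_series = ion_series(neutral_mass, config.z_min, config.z_max)
            trial = detect_coelution(
                run, trial_series, config.tol_ppm, config.rt_tol_min, config.min_charges
            )
            if trial.accepted:
                evidence, series = trial, trial_series
                break
        if evidence is None:
            logger.debug("candidate %s: no coelution", cand.label())
            evidence = trial  # for the charge count in the reason string
            rejected.append(
                {
                    "candidate": cand.label(),
                    "sites": ",".join(map(str, cand.site_positions)),
                    "n_peptides": cand.n_peptides,
                    "bond_count": cand.bond_count,
                    "naive_sum_mass": round(cand.naive_sum_mass, 5),
                    "corrected_mass": round(cand.corrected_mass, 5),
                    "accepted": False,
                    "reason": f"no coelution ({evidence.n_charges_found} charges found)",
                }
            )
            continue
        result = deconvolute(run, series, evidence, config.tol_ppm)
        matches.append(
            match_observed(
                result.monoisotopic_mass, cand, config.mass_tol_da, evidence=evidence
            )
        )
    report = RunReport(
        config=config,
        matches=matches,
        rejected=rejected,
        n_candidates=len(candidates),
        provenance={"config_hash": config.digest_hash(), "version": __version__},
    )
    logger.info(
        "search finished: %d candidates, %d matched, %d accepted",
        len(candidates),
        len(matches),
        len(report.accepted),
    )
    return report


# ---------------------------------------------------------------- CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging to stderr")
def cli(verbose: bool) -> None:
    """Targeted search for covalent Met-Tyr-Trp peptide adducts in LC-MS data."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command("digest")
@click.option("--fasta", required=True, type=click.Path(exists=True))
@click.option("--max-missed", default=2, show_default=True)
@click.option("--out", type=click.Path(), default=None)
def cli_digest(fasta: str, max_missed: int, out: str | None) -> None:
    """In-silico tryptic digestion of every protein in a FASTA file."""
    from .proteoforms import peptide_monoisotopic_mass

    rows = []
    for record in read_fasta(fasta):
        for pep in digest(record, max_missed=max_missed):
            rows.append(
                {
                    "protein": record.id,
                    "start": pep.start,
                    "end": pep.end,
                    "sequence": pep.sequence,
                    "missed_cleavages": pep.missed_cleavages,
                    "monoisotopic_mass": round(peptide_monoisotopic_mass(pep), 5),
                }
            )
    frame = pd.DataFrame(rows)
    _emit(frame, out)


@cli.command("candidates")
@click.option("--fasta", required=True, type=click.Path(exists=True))
@click.option("--protein", "protein_id", default=None, help="defaults to first record")
@click.option("--sites", required=True, help='e.g. "M244,Y218,W90"')
@click.option("--max-missed", default=2, show_default=True)
@click.option("--out", type=click.Path(), default=None)
def cli_candidates(
    fasta: str, protein_id: str | None, sites: str, max_missed: int, out: str | None
) -> None:
    """Enumerate crosslink candidates with naive and bond-corrected masses."""
    records = read_fasta(fasta)
    record = records[0] if protein_id is None else next(r for r in records if r.id == protein_id)
    spec = AdductSpec.parse(record.id, sites)
    spec.validate_against(record)
    peptides = digest(record, max_missed=max_missed)
    rows = [
        {
            "candidate": c.label(),
            "sites": ",".join(map(str, c.site_positions)),
            "n_peptides": c.n_peptides,
            "bond_count": c.bond_count,
            "naive_sum_mass": round(c.naive_sum_mass, 5),
            "corrected_mass": round(c.corrected_mass, 5),
        }
        for c in enumerate_candidates(peptides, spec)
    ]
    _emit(pd.DataFrame(rows), out)


@cli.command("simulate")
@click.option("--seed", default=0, show_default=True)
@click.option("--mass", "masses", multiple=True, type=float, required=True)
@click.option("--rt", "rts", multiple=True, type=float, help="one per mass, minutes")
@click.option("--charges", default="4,5,6", show_default=True)
@click.option("--run-length", default=60.0, show_default=True)
@click.option("--scan-interval", default=0.05, show_default=True)
@click.option("--noise-peaks", default=0, show_default=True)
@click.option("--out", required=True, type=click.Path())
@click.option("--format", "fmt", default="json", type=click.Choice(["json", "mzml"]))
def cli_simulate(
    seed: int,
    masses: tuple[float, ...],
    rts: tuple[float, ...],
    charges: str,
    run_length: float,
    scan_interval: float,
    noise_peaks: int,
    out: str,
    fmt: str,
) -> None:
    """Generate a synthetic centroided run with planted species."""
    zs = tuple(int(z) for z in charges.split(","))
    rt_list = list(rts) if rts else [run_length / 2.0] * len(masses)
    species = [
        PlantedSpecies(mass=m, charges=zs, rt_center=rt, rt_sigma=0.1, abundance=1e6)
        for m, rt in zip(masses, rt_list)
    ]
    run, truth = simulate_run(
        species,
        scan_interval=scan_interval,
        run_length=run_length,
        noise=NoiseModel(peaks_per_scan=noise_peaks, seed=seed),
    )
    write_run(run, out, format=fmt)
    truth.to_csv(Path(out).with_suffix(".truth.tsv"), sep="\t", index=False)
    click.echo(f"wrote {out} ({len(run)} scans, {len(species)} planted species)")


@cli.command("search")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--fasta", type=click.Path(exists=True), default=None)
@click.option("--protein", "protein_id", default=None)
@click.option("--sites", default=None)
@click.option("--run", "run_path", type=click.Path(exists=True), default=None)
@click.option("--out-dir", default="katglink-out", show_default=True)
def cli_search(
    config_path: str | None,
    fasta: str | None,
    protein_id: str | None,
    sites: str | None,
    run_path: str | None,
    out_dir: str,
) -> None:
    """Run the full targeted adduct search and write TSV + JSON reports."""
    if config_path:
        config = PipelineConfig.from_toml(config_path)
        if fasta:
            config.fasta_path = fasta
        if run_path:
            config.run_path = run_path
        if out_dir:
            config.out_dir = out_dir
    else:
        if not (fasta and sites and run_path):
            raise click.UsageError("need --config or all of --fasta/--sites/--run")
        if protein_id is None:
            protein_id = read_fasta(fasta)[0].id
        config = PipelineConfig(
            fasta_path=fasta,
            protein_id=protein_id,
            sites=sites,
            run_path=run_path,
            out_dir=out_dir,
        )
    config.validate_paths()
    report = search_adduct(config)
    report.write(config.out_dir)
    click.echo(
        f"{report.n_candidates} candidates, {len(report.accepted)} accepted; "
        f"reports in {config.out_dir}"
    )
    sys.exit(0 if report.accepted else 1)


@cli.command("kinetics")
@click.option("--trace", required=True, type=click.Path(exists=True), help="CSV: time_min,absorbance")
@click.option("--epsilon", required=True, type=float)
@click.option("--epsilon-unit", default="mM-1cm-1", type=click.Choice(["mM-1cm-1", "M-1cm-1"]))
@click.option("--path-cm", default=1.0, show_default=True)
@click.option("--volume-ml", default=1.0, show_default=True)
@click.option("--enzyme-mg", required=True, type=float)
@click.option("--substrate", default="substrate")
def cli_kinetics(
    trace: str,
    epsilon: float,
    epsilon_unit: str,
    path_cm: float,
    volume_ml: float,
    enzyme_mg: float,
    substrate: str,
) -> None:
    """Specific activity (U/mg) from an absorbance time course."""
    frame = pd.read_csv(trace)
    fit = fit_linear_rate(frame)
    ctx = AssayContext(
        substrate=substrate,
        epsilon=epsilon,
        epsilon_unit=epsilon_unit,
        path_cm=path_cm,
        volume_ml=volume_ml,
        enzyme_mg=enzyme_mg,
    )
    result = specific_activity(fit.slope, ctx)
    click.echo(
        f"slope {fit.slope:.5f} dA/min (R2 {fit.r_squared:.4f}, "
        f"window {fit.window[0]:.2f}-{fit.window[1]:.2f} min); "
        f"{result.specific_activity:.4f} U/mg"
    )


@cli.command("melt")
@click.option("--curve", required=True, type=click.Path(exists=True), help="CSV: temperature_C,ratio")
def cli_melt(curve: str) -> None:
    """Tm and onset temperature from a fluorescence-ratio melting curve."""
    frame = pd.read_csv(curve)
    result = melt_analysis(frame)
    click.echo(f"Tm {result.tm:.1f} C, onset {result.onset:.1f} C")


def _emit(frame: pd.DataFrame, out: str | None) -> None:
    if out:
        frame.to_csv(out, sep="\t", index=False)
        click.echo(f"wrote {out} ({len(frame)} rows)")
    else:
        click.echo(frame.to_csv(sep="\t", index=False), nl=False)
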
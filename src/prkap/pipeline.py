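"""End-to-end experiment orchestration and the command-line interface.

Experiments run at configurable (desk) scale: length x salt sweeps of
probe chains against one receptor, and fixed-mass comparisons where arms
hold the total number of PR repeat units constant while trading copy
number against chain length.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cg_builder import (
    BindingSiteSet,
    CGModel,
    RegionAnnotation,
    build_polypr,
    model_missing_regions,
    parse_calpha_trace,
)
from .contact_analysis import compute_contact_results, scalar_uncertainty
from .forcefield import ForceFieldParams
from .simulator import (
    ChainSpec,
    SimulationConfig,
    Trajectory,
    read_trajectory,
    run_simulation,
    write_trajectory,
)
from .synthetic_data import SolenoidSpec, generate_toy_solenoid

log = logging.getLogger("prkap")

__all__ = ["ExperimentConfig", "run_length_salt_sweep",
           "run_fixed_mass_comparison", "cli"]


@dataclass
class ExperimentConfig:
    solenoid: SolenoidSpec = field(default_factory=SolenoidSpec)
    receptor_model: str | None = None  # optional path to a CGModel JSON
    regions: str | None = None  # TSV paths when receptor_model is used
    sites: str | None = None
    pr_lengths: list = field(default_factory=lambda: [7, 20, 35, 50])
    salts_mM: list = field(default_factory=lambda: [100.0, 200.0])
    seeds: list = field(default_factory=lambda: [0, 1, 2, 3, 4])
    copies: int = 1
    n_steps: int = 200000
    save_interval: int = 500
    box: float = 12.0
    timestep: float = 0.02
    friction: float = 0.02
    temperature: float = 300.0
    equilibration_fraction: float = 0.2
    outdir: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.solenoid, dict):
            self.solenoid = SolenoidSpec(**self.solenoid)

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        text = source.read() if hasattr(source, "read") else open(source).read()
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def load_receptor(self):
        if self.receptor_model is not None:
            model = CGModel.from_json(Path(self.receptor_model).read_text())
            annotation = (RegionAnnotation.from_tsv(self.regions)
                          if self.regions else None)
            sites = BindingSiteSet.from_tsv(self.sites) if self.sites else None
            return model, annotation, sites
        return generate_toy_solenoid(self.solenoid)


def _single_run(receptor, annotation, sites, length: int, salt: float,
                seed: int, copies: int, config: ExperimentConfig) -> dict:
    params = ForceFieldParams(salt_mM=salt, temperature=config.temperature)
    probe = build_polypr(length, seed=seed + 7919)
    sim = SimulationConfig(
        chains=[ChainSpec(receptor, "receptor"), ChainSpec(probe, "pr", copies)],
        temperature=config.temperature, timestep=config.timestep,
        friction=config.friction, box=config.box, n_steps=config.n_steps,
        save_interval=config.save_interval, seed=seed,
        equilibration_fraction=config.equilibration_fraction)
    traj = run_simulation(sim, params)
    res = compute_contact_results(
        traj, annotation, sites,
        equilibration_fraction=config.equilibration_fraction)
    row = {
        "length": length, "salt_mM": salt, "seed": seed, "copies": copies,
        "n_pr": length * copies,
        "ncpr_receptor": receptor.ncpr(),
        "ct": res.ct, "ct_normalized": res.ct_normalized, "pb": res.pb,
        "n_contact_sites": len(res.contact_site_set),
        "ct_err": res.uncertainty.get("ct", np.nan),
        "pb_err": res.uncertainty.get("pb", np.nan),
    }
    if res.ncontact_by_region is not None:
        for k, v in res.ncontact_by_region.items():
            row[f"ncontact_{k}"] = v
    if res.nshared_by_class is not None:
        for k, v in res.nshared_by_class.items():
            row[f"nshared_{k}"] = np.nan if v is None else v
    return row


def run_length_salt_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """One row per (length, salt, seed); failed runs recorded with status."""
    receptor, annotation, sites = config.load_receptor()
    rows = []
    for salt in config.salts_mM:
        for length in config.pr_lengths:
            for seed in config.seeds:
                try:
                    row = _single_run(receptor, annotation, sites, int(length),
                                      float(salt), int(seed), config.copies,
                                      config)
                    row["status"] = "ok"
                except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                    log.error("run failed (length=%s salt=%s seed=%s): %s",
                              length, salt, seed, exc)
                    row = {"length": int(length), "salt_mM": float(salt),
                           "seed": int(seed), "status": f"failed: {exc}"}
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config.config_hash()
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "sweep.tsv", sep="\t", index=False)
        _aggregate_sweep(df).to_csv(out / "sweep_aggregate.tsv", sep="\t",
                                    index=False)
    return df


def _aggregate_sweep(df: pd.DataFrame) -> pd.DataFrame:
    ok = df[df["status"] == "ok"]
    rows = []
    for (length, salt), grp in ok.groupby(["length", "salt_mM"]):
        row = {"length": length, "salt_mM": salt, "n_seeds": len(grp)}
        for col in ("ct", "ct_normalized", "pb"):
            row[f"{col}_mean"] = grp[col].mean()
            row[f"{col}_halfsd"] = (scalar_uncertainty(grp[col].to_numpy())
                                    if len(grp) >= 2 else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_fixed_mass_comparison(config: ExperimentConfig, arms) -> pd.DataFrame:
    """Compare arms of equal total PR repeat number n_PR.

    ``arms`` is a list of (copies, length) pairs; copies * length must be
    identical across arms.
    """
    n_prs = {int(c) * int(l) for c, l in arms}
    if len(n_prs) != 1:
        raise ValueError(f"arms have unequal total repeat numbers: {sorted(n_prs)}")
    receptor, annotation, sites = config.load_receptor()
    rows = []
    for copies, length in arms:
        for salt in config.salts_mM:
            for seed in config.seeds:
                row = _single_run(receptor, annotation, sites, int(length),
                                  float(salt), int(seed), int(copies), config)
                row["status"] = "ok"
                rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["config_hash"] = config.config_hash()
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "fixed_mass.tsv", sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

import click


@click.group()
@click.version_option(__version__, prog_name="prkap")
def cli():
    """Coarse-grained poly-PR / transport-receptor simulation toolkit."""
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s")


@cli.command("build")
@click.option("--pdb", type=click.Path(exists=True), default=None,
              help="PDB structure to coarse-grain.")
@click.option("--chain", default="A", show_default=True)
@click.option("--polypr", type=int, default=None,
              help="Build a (PR)^n chain instead of parsing a structure.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cli_build(pdb, chain, polypr, seed, out):
    """Build a CG model from a PDB chain or as poly-PR."""
    if (pdb is None) == (polypr is None):
        raise click.UsageError("provide exactly one of --pdb or --polypr")
    if polypr is not None:
        model = build_polypr(polypr, seed=seed)
    else:
        trace = parse_calpha_trace(Path(pdb).read_text(), chain)
        model = model_missing_regions(trace, seed=seed)
    model.to_json(out)
    click.echo(f"wrote {out}: {model.n_beads} beads, NCPR {model.ncpr():+.4f}")


@cli.command("make-toy")
@click.option("--spec", "spec_path", type=click.Path(exists=True), default=None,
              help="YAML file of SolenoidSpec fields (defaults if omitted).")
@click.option("--out", type=click.Path(), required=True)
def cli_make_toy(spec_path, out):
    """Generate a toy solenoid receptor with annotations and sites."""
    spec = SolenoidSpec(**(yaml.safe_load(open(spec_path)) if spec_path else {}))
    model, annotation, sites = generate_toy_solenoid(spec)
    outdir = Path(out)
    outdir.mkdir(parents=True, exist_ok=True)
    model.to_json(outdir / "receptor.json")
    annotation.to_tsv(outdir / "regions.tsv")
    sites.to_tsv(outdir / "sites.tsv")
    click.echo(f"wrote toy receptor ({model.n_beads} beads, "
               f"NCPR {model.ncpr():+.4f}) to {outdir}")


@cli.command("simulate")
@click.option("--config", "config_path", type=click.Path(exists=True),
              required=True, help="YAML run configuration.")
@click.option("--out", type=click.Path(), required=True)
@click.option("--log", "log_path", type=click.Path(), default=None)
def cli_simulate(config_path, out, log_path):
    """Run Langevin dynamics from a YAML config.

    Config keys: receptor (model JSON path), polypr (repeat count),
    copies, salt_mM, plus any SimulationConfig field.
    """
    cfg = yaml.safe_load(open(config_path))
    chains = []
    if "receptor" in cfg:
        chains.append(ChainSpec(CGModel.from_json(
            Path(cfg.pop("receptor")).read_text()), "receptor"))
    copies = int(cfg.pop("copies", 1))
    if "polypr" in cfg:
        chains.append(ChainSpec(build_polypr(int(cfg.pop("polypr")),
                                             seed=int(cfg.get("seed", 0))),
                                "pr", copies))
    params = ForceFieldParams(salt_mM=float(cfg.pop("salt_mM", 200.0)),
                              temperature=float(cfg.get("temperature", 300.0)))
    sim = SimulationConfig(chains=chains, **cfg)
    traj = run_simulation(sim, params)
    write_trajectory(traj, out)
    if log_path:
        with open(log_path, "w") as fh:
            fh.write(f"prkap {__version__}\nconfig: {json.dumps(cfg)}\n"
                     f"frames: {traj.n_frames}\n")
    click.echo(f"wrote {traj.n_frames} frames to {out}")


@cli.command("analyze")
@click.option("--traj", "traj_path", type=click.Path(exists=True), required=True)
@click.option("--regions", type=click.Path(exists=True), default=None)
@click.option("--sites", type=click.Path(exists=True), default=None)
@click.option("--equilibration-fraction", type=float, default=0.2,
              show_default=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--tsv-dir", type=click.Path(), default=None,
              help="Also write one TSV per statistic into this directory.")
def cli_analyze(traj_path, regions, sites, equilibration_fraction, out, tsv_dir):
    """Compute contact statistics for a trajectory."""
    traj = read_trajectory(traj_path)
    annotation = RegionAnnotation.from_tsv(regions) if regions else None
    site_set = BindingSiteSet.from_tsv(sites) if sites else None
    res = compute_contact_results(traj, annotation, site_set,
                                  equilibration_fraction=equilibration_fraction)
    res.to_json(out)
    if tsv_dir:
        res.to_tsv_dir(tsv_dir)
    click.echo(f"Ct={res.ct:.2f} Pb={res.pb:.3f} sites={len(res.contact_site_set)}")


@cli.command("sweep")
@click.option("--config", "config_path", type=click.Path(exists=True),
              required=True)
@click.option("--out", type=click.Path(), required=True)
def cli_sweep(config_path, out):
    """Run a length x salt sweep from an experiment YAML."""
    config = ExperimentConfig.from_yaml(config_path)
    config.outdir = out
    df = run_length_salt_sweep(config)
    n_failed = int((df["status"] != "ok").sum())
    click.echo(f"{len(df)} runs, {n_failed} failed; tables in {out}")
    if n_failed:
        sys.exit(1)
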
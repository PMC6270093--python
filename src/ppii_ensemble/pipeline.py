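"""Pipeline orchestration: pool -> selection -> analysis -> cross-validation.

A :class:`RunConfig` fully determines a run; rerunning with the same config
and seed reproduces every numeric output.  Each stage writes its artifacts
under one run directory and the final ``report.json`` records the config
hash, seed, per-stage wall times and headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import analysis, hydro, io, sampler, selector
from .peptide import SequenceSpec

__all__ = ["RunConfig", "RunReport", "run_pipeline", "demo_config"]

log = logging.getLogger("ppii_ensemble")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.  ``seed`` is mandatory."""

    sequence: str = "Ac-PHNPGYPHNPGY-NH2"
    seed: int = 0
    pool_size: int = 5000
    ensemble_size: int = 100
    basin_library: str = "default"
    # restraints: either file paths, or synthesized from a ground truth
    noe_file: str | None = None
    j_file: str | None = None
    shift_target_file: str | None = None
    ground_truth_ppii: list[float] | None = None
    ground_truth_size: int = 300
    include_shifts: bool = True
    # analysis configuration
    superpose_range: tuple[int, int] = (3, 10)
    cluster_range: tuple[int, int] | None = None
    bead_radius: float = hydro.DEFAULT_BEAD_RADIUS
    experimental_rh: float | None = None
    # schedule
    t_start: float = 1.0
    t_end: float = 1e-3
    stages: int = 20
    proposals_per_member: float = 50.0
    outdir: str = "run"
    write_pool: bool = False

    def schedule(self) -> selector.Schedule:
        return selector.Schedule(self.t_start, self.t_end, self.stages,
                                 self.proposals_per_member)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("noe_file", "j_file", "shift_target_file"):
            val = getattr(cfg, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"{key}: {val} does not exist")
        if isinstance(cfg.superpose_range, list):
            cfg.superpose_range = tuple(cfg.superpose_range)
        if isinstance(cfg.cluster_range, list):
            cfg.cluster_range = tuple(cfg.cluster_range)
        return cfg

    def to_yaml(self, path):
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class RunReport:
    config_hash: str
    seed: int
    outputs: dict = field(default_factory=dict)
    ppii_per_residue: list = field(default_factory=list)
    ppii_overall: float = float("nan")
    n_clusters: int = 0
    cluster_within_rmsd: dict = field(default_factory=dict)
    rh_cross_validation: dict = field(default_factory=dict)
    selection_score: float = float("nan")
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def demo_config(outdir="run-demo", seed=0, pool_size=1200, ensemble_size=60,
                ground_truth_size=200) -> RunConfig:
    """A small synthetic end-to-end configuration (ground-truth demo)."""
    seq = SequenceSpec.from_string("Ac-PHNPGYPHNPGY-NH2")
    target = [0.20 if r == "PRO" else 0.12 for r in seq.residues]
    return RunConfig(seed=seed, pool_size=pool_size,
                     ensemble_size=ensemble_size, ground_truth_ppii=target,
                     ground_truth_size=ground_truth_size, outdir=outdir)


def _stage(report, name, t0):
    dt = time.time() - t0
    report.stage_seconds[name] = round(dt, 2)
    log.info("stage %-12s %6.1fs", name, dt)
    return time.time()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute genpool -> restraints -> select -> analyze -> hydro.

    Any stage failure aborts with the stage name in the exception message.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    config.to_yaml(outdir / "config.yaml")
    report.outputs["config"] = str(outdir / "config.yaml")

    seq = SequenceSpec.from_string(config.sequence)
    if config.basin_library != "default":
        raise ValueError("only the built-in 'default' basin library is "
                         "currently supported in configs")
    lib = sampler.default_library()
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in root.spawn(4)]

    t0 = time.time()
    stage = "genpool"
    try:
        pool = sampler.generate_pool(seq, config.pool_size, lib=lib,
                                     rng_seed=seeds[0])
        if config.write_pool:
            io.write_multimodel_pdb(outdir / "pool.pdb", pool)
            report.outputs["pool"] = str(outdir / "pool.pdb")
        t0 = _stage(report, stage, t0)

        stage = "restraints"
        target_rh = None
        if config.noe_file or config.j_file or config.shift_target_file:
            rs = io.read_restraint_set(config.noe_file, config.j_file,
                                       config.shift_target_file)
        else:
            target = config.ground_truth_ppii
            if target is None:
                raise ValueError("no restraint files and no ground truth "
                                 "profile to synthesize from")
            truth = sampler.GroundTruth(np.asarray(target, dtype=float),
                                        size=config.ground_truth_size)
            truth_ens = sampler.make_ground_truth_ensemble(
                seq, truth, lib=lib, rng_seed=seeds[1])
            obs, rs = sampler.synthesize_observables(truth_ens,
                                                     rng_seed=seeds[2])
            io.write_noe_table(outdir / "restraints_noe.txt", rs.noes)
            io.write_j_table(outdir / "restraints_j.txt", rs.j_targets)
            io.write_shift_targets(outdir / "restraints_shifts.csv",
                                   rs.shift_targets)
            io.write_diffusion_series(outdir / "diffusion.csv", obs.diffusion)
            report.outputs["restraints"] = str(outdir / "restraints_noe.txt")
            # reference Rh from the synthetic diffusion decay
            d_fit, _ = hydro.fit_diffusion_decay(obs.diffusion)
            target_rh = hydro.stokes_einstein_rh(
                d_fit, obs.diffusion.temperature_K,
                obs.diffusion.viscosity_mPas)
        t0 = _stage(report, stage, t0)

        stage = "select"
        result = selector.select_ensemble(
            pool, rs, size=config.ensemble_size, rng_seed=seeds[3],
            schedule=config.schedule(), include_shifts=config.include_shifts)
        report.selection_score = result.score
        io.write_multimodel_pdb(outdir / "selected.pdb", result.ensemble)
        result.violations.to_csv(outdir / "violations.csv", index=False)
        report.outputs["selected"] = str(outdir / "selected.pdb")
        report.outputs["violations"] = str(outdir / "violations.csv")
        t0 = _stage(report, stage, t0)

        stage = "analyze"
        prof = analysis.ppii_profile(result.ensemble)
        report.ppii_per_residue = [round(float(x), 4)
                                   for x in prof.per_residue]
        report.ppii_overall = round(prof.overall, 4)
        import pandas as pd
        pd.DataFrame({"residue_index": np.arange(1, len(seq) + 1),
                      "residue": seq.residues,
                      "ppii_fraction": prof.per_residue}).to_csv(
            outdir / "ppii_profile.csv", index=False)
        tree = analysis.cluster_ensemble(
            result.ensemble, superpose_range=config.superpose_range,
            rmsd_range=config.cluster_range)
        stats = analysis.cluster_stats(tree, result.ensemble)
        report.n_clusters = tree.n_clusters
        report.cluster_within_rmsd = {
            str(c): round(float(v.mean()), 3)
            for c, v in stats["within"].items()}
        pd.DataFrame({"member": np.arange(len(result.ensemble)),
                      "pool_index": result.indices,
                      "cluster": tree.labels}).to_csv(
            outdir / "clusters.csv", index=False)
        report.outputs["ppii_profile"] = str(outdir / "ppii_profile.csv")
        report.outputs["clusters"] = str(outdir / "clusters.csv")
        t0 = _stage(report, stage, t0)

        stage = "hydro"
        ref_rh = (config.experimental_rh if config.experimental_rh
                  else target_rh)
        if ref_rh is not None:
            report.rh_cross_validation = {
                k: (round(v, 4) if isinstance(v, float) else v)
                for k, v in selector.cross_validate_rh(
                    result, ref_rh, config.bead_radius).items()}
        pool_rh = hydro.ensemble_rh(
            pool.subset(range(min(len(pool), 500))), config.bead_radius)
        report.rh_cross_validation["coil_pool_rh_mean"] = round(pool_rh[0], 4)
        report.rh_cross_validation["coil_pool_rh_sd"] = round(pool_rh[1], 4)
        t0 = _stage(report, stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report.to_json(outdir / "report.json")
    report.outputs["report"] = str(outdir / "report.json")
    return report
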
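"""End-to-end orchestration: simulate/load -> filter -> ratios -> scan ->
bootstrap -> joint CI -> cohort stats -> permutation tests.

Driven by a structured config (YAML via the CLI, or a plain dict); every
random stage consumes an explicit seed from the config and all outputs plus
their parameters and SHA-256 checksums are listed in a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import ancestry, cohort, intervals, io, likelihood, permutation, simulate

log = logging.getLogger("segdrive")

__all__ = ["RunConfig", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration (see module docstring).

    ``simulation`` is a list of per-cross simulation blocks (keyword
    arguments of :class:`segdrive.simulate.SimulationConfig`); alternatively
    ``inputs`` lists dicts with leaf/pollen count-table paths per cross.
    """

    outdir: str = "segdrive_out"
    simulation: list[dict] = dataclasses.field(default_factory=list)
    inputs: list[dict] = dataclasses.field(default_factory=list)
    map_path: str | None = None
    q_low: float = 0.05
    q_high: float = 0.95
    min_gap_bp: int = 100
    window_snps: int = 1000
    error_rate: float = 0.005
    min_effect: float = 0.02
    effect_mode: str = "difference"
    grid_thin: int = 1
    bootstrap_B: int = 100
    bootstrap_seed: int = 0
    joint_chroms: list[str] = dataclasses.field(default_factory=list)
    effects_path: str | None = None  # None -> packaged 14-cross fixture
    run_cohort_stats: bool = True
    run_permutation_tests: bool = True
    n_genomewide: int = 100_000
    n_pairwise: int = 100_000
    perm_seed: int = 17
    stages: list[str] = dataclasses.field(
        default_factory=lambda: ["crosses", "stats"])

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_cross(cfg: RunConfig, spec: dict, outdir: Path):
    if "seed" in spec or "distorters" in spec:  # simulation block
        sim = simulate.SimulationConfig(**spec)
        leaf, pollen, truth = simulate.simulate_cross(sim)
        truth.to_json(outdir / f"{pollen.cross_id}.truth.json")
        return leaf, pollen
    leaf = io.read_count_table(spec["leaf"], "leaf", spec["cross_id"])
    pollen = io.read_count_table(spec["pollen"], "pollen", spec["cross_id"])
    return leaf, pollen


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the manifest dict (also written
    to ``<outdir>/manifest.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": dataclasses.asdict(config), "outputs": [], "calls": [],
    }

    def emit(path: Path, stage: str) -> None:
        manifest["outputs"].append(
            {"stage": stage, "path": str(path), "sha256": _sha256(path)})

    gmap = io.read_genetic_map(config.map_path) if config.map_path else None

    if "crosses" in config.stages:
        for spec in list(config.simulation) + list(config.inputs):
            leaf, pollen = _load_cross(config, dict(spec), outdir)
            cid = pollen.cross_id
            n0 = leaf.n_sites
            leaf_f, pollen_f = ancestry.apply_site_filters(
                leaf, pollen, config.q_low, config.q_high, config.min_gap_bp)
            log.info("%s: %d sites -> %d after filters", cid, n0, leaf_f.n_sites)
            for t in (leaf_f, pollen_f):
                p = outdir / f"{cid}.{t.tissue}.filtered.tsv"
                io.write_count_table(t, p)
                emit(p, "filter")

            ratios = ancestry.window_ratios(leaf_f, pollen_f, config.window_snps)
            p = outdir / f"{cid}.windows.tsv"
            ratios.write_tsv(p)
            emit(p, "ratios")

            cross_map = gmap
            if cross_map is None:
                # fall back to each table's own pos_cM anchors
                anchors = {
                    c: (sub["pos_bp"].to_numpy(float), sub["pos_cM"].to_numpy(float))
                    for c, sub in pollen_f.data.groupby("chrom", sort=False)}
                cross_map = io.GeneticMap(anchors)
            model = likelihood.LikelihoodModel(
                genetic_map=cross_map, error_rate=config.error_rate,
                grid_thin=config.grid_thin)
            boots = {}
            for chrom in pollen_f.chromosomes():
                scan = likelihood.scan_chromosome(pollen_f, leaf_f, model, chrom=chrom)
                eff = likelihood.call_effect(scan, config.min_effect,
                                             config.effect_mode)
                p = outdir / f"{cid}.chr{chrom}.scan.tsv"
                scan.profile.to_csv(p, sep="\t", index=False)
                emit(p, "scan")
                manifest["calls"].append({
                    "cross": cid, "chrom": str(chrom),
                    "ml_pos_bp": scan.ml_pos_bp, "effect": eff})
                log.info("%s chr%s: ml_pos=%d effect=%+.2f", cid, chrom,
                         scan.ml_pos_bp, eff)
                if eff != 0.0:
                    res = intervals.bootstrap_ci(
                        pollen_f, leaf_f, model, B=config.bootstrap_B,
                        seed=config.bootstrap_seed, chrom=chrom,
                        keep_profiles=str(chrom) in [str(c) for c in config.joint_chroms])
                    boots.setdefault(str(chrom), []).append(res)
                    p = outdir / f"{cid}.chr{chrom}.bootstrap.tsv"
                    np.savetxt(p, res.positions, fmt="%d",
                               header="replicate_ml_pos_bp")
                    emit(p, "bootstrap")
                    manifest["calls"][-1].update(
                        {"ci_lo": res.ci_lo, "ci_hi": res.ci_hi})

    if "stats" in config.stages:
        if config.effects_path:
            matrix = io.read_effect_matrix(config.effects_path)
            _, meta = io.load_f1_effect_matrix()
        else:
            matrix, meta = io.load_f1_effect_matrix()
        if config.run_cohort_stats:
            report = cohort.group_report(matrix, meta)
            p = outdir / "group_tests.tsv"
            report.to_csv(p, sep="\t", index=False)
            emit(p, "group-tests")
            manifest["group_tests"] = report.to_dict("records")
        if config.run_permutation_tests:
            spec_g = permutation.PermutationSpec(
                n_permutations=config.n_genomewide, seed=config.perm_seed)
            gres = permutation.genomewide_nonindependence(matrix, spec_g)
            spec_p = permutation.PermutationSpec(
                n_permutations=config.n_pairwise, seed=config.perm_seed)
            pres = permutation.pairwise_interaction_test(matrix, meta, spec_p)
            p = outdir / "perm_tests.tsv"
            pres.table.to_csv(p, sep="\t", index=False)
            emit(p, "perm-tests")
            manifest["permutation"] = {
                "genomewide": dataclasses.asdict(gres),
                "pairwise_excluded": pres.excluded_crosses,
                "pairwise_seed": pres.seed,
                "pairwise_n": pres.n_permutations,
            }

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
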
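"""Synthetic leaf/pollen count tables with known ground truth.

The generator emulates the data structure of bulk-gamete sequencing of an F1
hybrid: phased ancestry-informative SNPs along each chromosome, somatic
(leaf) read ratios centred on 1/2, and germline (pollen) ratios skewed
around a distorting locus according to

    f_p = 0.5 + k (1 - 2 r(d_p)),    r = Haldane recombination fraction,

with symmetric sequencing error ``e`` and binomial read sampling at a
negative-binomial (or fixed) per-site depth.

Two generative modes are provided:

``marginal`` (default)
    Per-site counts are drawn independently from the marginal maternal-read
    probability. This is the generative process matched to the composite
    (per-site independent) likelihood used for inference.
``linked``
    Whole recombinant gametes are simulated (crossovers as a Poisson process
    on the genetic map, viability selection at the distorter), then reads
    are sampled from the surviving gamete pool. Sites then share the
    linkage correlations of real data; used to stress-test the composite
    likelihood.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import COUNT_COLUMNS, EffectMatrix, GeneticMap, SiteCountTable
from .likelihood import recomb_fraction

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_cross",
    "simulate_effect_matrix",
]


@dataclasses.dataclass
class SimulationConfig:
    """Stated world for one simulated cross.

    Parameters
    ----------
    n_sites:
        Ancestry-informative sites per chromosome.
    chrom_length_bp:
        Physical chromosome length (positions are uniform on [1, length]).
    map_length_morgans:
        Genetic length per chromosome; positions map linearly unless
        ``genetic_map`` is supplied.
    distorters:
        Mapping chromosome label -> (position_bp, k). At most one distorter
        per chromosome; |k| <= 0.5.
    error_rate:
        Symmetric per-read sequencing error, in [0, 0.5).
    depth_mean, depth_dispersion:
        Per-site depth model. ``depth_dispersion="fixed"`` gives constant
        depth; a positive float is the negative-binomial size parameter
        (variance = mean + mean^2 / dispersion). Depth is clamped at >= 1 so
        every site carries at least one read.
    n_chromosomes:
        Chromosomes are labelled "1".."n".
    mode:
        "marginal" or "linked" (see module docstring).
    n_gametes:
        Surviving gamete pool size in linked mode.
    """

    n_sites: int = 5000
    chrom_length_bp: int = 20_000_000
    map_length_morgans: float = 1.0
    distorters: Mapping[str, tuple[float, float]] = dataclasses.field(default_factory=dict)
    error_rate: float = 0.005
    depth_mean: float = 100.0
    depth_dispersion: float | str = 5.0
    n_chromosomes: int = 1
    seed: int = 0
    mode: str = "marginal"
    n_gametes: int = 2000
    genetic_map: GeneticMap | None = None
    site_positions: Mapping[str, Sequence[int]] | None = None

    def __post_init__(self) -> None:
        if self.n_sites <= 0 or self.chrom_length_bp <= 0 or self.n_chromosomes <= 0:
            raise ValueError("n_sites, chrom_length_bp, n_chromosomes must be positive")
        if self.map_length_morgans <= 0:
            raise ValueError("map_length_morgans must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error rate must lie in [0, 0.5)")
        if self.depth_mean <= 0:
            raise ValueError("depth must be positive")
        if self.depth_dispersion != "fixed" and float(self.depth_dispersion) <= 0:
            raise ValueError("depth dispersion must be positive or 'fixed'")
        if self.mode not in ("marginal", "linked"):
            raise ValueError("mode must be 'marginal' or 'linked'")
        self.distorters = {str(c): (float(p), float(k))
                           for c, (p, k) in dict(self.distorters).items()}
        for chrom, (pos, k) in self.distorters.items():
            if abs(k) > 0.5:
                raise ValueError(f"chrom {chrom}: |k| must be <= 0.5, got {k}")
            if not 1 <= pos <= self.chrom_length_bp:
                raise ValueError(f"chrom {chrom}: distorter position {pos} outside "
                                 f"[1, {self.chrom_length_bp}]")

    @property
    def chromosomes(self) -> list[str]:
        return [str(c) for c in range(1, self.n_chromosomes + 1)]

    def map(self) -> GeneticMap:
        if self.genetic_map is not None:
            return self.genetic_map
        return GeneticMap.linear(self.chrom_length_bp, self.map_length_morgans,
                                 self.chromosomes)


@dataclasses.dataclass
class TruthRecord:
    """Ground truth for parameter-recovery tests.

    ``distorters`` maps chromosome -> (position_bp, position_morgans, k);
    ``transmission`` maps chromosome -> per-site maternal transmission
    probabilities f_p (before sequencing error). At the distorter itself
    f = 0.5 + k.
    """

    distorters: dict[str, tuple[float, float, float]]
    transmission: dict[str, np.ndarray]
    seed: int
    mode: str

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "mode": self.mode,
            "distorters": {c: {"pos_bp": p, "pos_morgans": m, "k": k}
                           for c, (p, m, k) in self.distorters.items()},
            "transmission": {c: np.asarray(v).tolist()
                             for c, v in self.transmission.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            distorters={c: (d["pos_bp"], d["pos_morgans"], d["k"])
                        for c, d in payload["distorters"].items()},
            transmission={c: np.asarray(v) for c, v in payload["transmission"].items()},
            seed=payload["seed"],
            mode=payload["mode"],
        )


def _draw_depth(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    if cfg.depth_dispersion == "fixed":
        return np.full(n, int(round(cfg.depth_mean)), dtype=int)
    theta = float(cfg.depth_dispersion)
    p = theta / (theta + cfg.depth_mean)
    return np.maximum(rng.negative_binomial(theta, p, size=n), 1)


def _site_grid(cfg: SimulationConfig, rng: np.random.Generator, chrom: str
               ) -> np.ndarray:
    if cfg.site_positions is not None and chrom in cfg.site_positions:
        pos = np.asarray(cfg.site_positions[chrom], dtype=int)
        if (np.diff(pos) <= 0).any():
            raise ValueError("supplied site positions must be strictly increasing")
        return pos
    # uniform placement without duplicates
    pos = rng.choice(cfg.chrom_length_bp, size=cfg.n_sites, replace=False) + 1
    pos.sort()
    return pos


def _linked_pool_freq(cfg: SimulationConfig, rng: np.random.Generator,
                      site_morgans: np.ndarray, dist_morgans: float | None,
                      k: float) -> np.ndarray:
    """Maternal-ancestry frequency per site in a pool of surviving gametes."""
    L = cfg.map_length_morgans
    freq_count = np.zeros(len(site_morgans))
    accepted = 0
    p_max = 0.5 + abs(k)
    while accepted < cfg.n_gametes:
        batch = max(64, cfg.n_gametes)
        for _ in range(batch):
            n_co = rng.poisson(L)
            breaks = np.sort(rng.uniform(0.0, L, size=n_co))
            start = rng.integers(0, 2)  # 1 = maternal
            # ancestry at x: start flipped once per crossover before x
            anc_sites = (start + np.searchsorted(breaks, site_morgans)) % 2
            if dist_morgans is None:
                keep = True
            else:
                anc_i = (start + np.searchsorted(breaks, dist_morgans)) % 2
                surv = 0.5 + k if anc_i == 1 else 0.5 - k
                keep = rng.random() < surv / p_max
            if keep:
                freq_count += anc_sites
                accepted += 1
                if accepted >= cfg.n_gametes:
                    break
    return freq_count / cfg.n_gametes


def simulate_cross(cfg: SimulationConfig
                   ) -> tuple[SiteCountTable, SiteCountTable, TruthRecord]:
    """Generate matched leaf and pollen count tables plus ground truth.

    Identical configs (including seed) produce identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    gmap = cfg.map()
    frames_leaf, frames_pollen = [], []
    truth_d: dict[str, tuple[float, float, float]] = {}
    truth_f: dict[str, np.ndarray] = {}
    e = cfg.error_rate
    for chrom in cfg.chromosomes:
        pos_bp = _site_grid(cfg, rng, chrom)
        morg = gmap.morgans(chrom, pos_bp)
        n = len(pos_bp)
        if chrom in cfg.distorters:
            dist_bp, k = cfg.distorters[chrom]
            dist_m = float(gmap.morgans(chrom, dist_bp))
        else:
            dist_bp = k = None
            dist_m = None
        if cfg.mode == "marginal" or dist_m is None:
            if dist_m is None:
                f = np.full(n, 0.5)
            else:
                f = 0.5 + k * (1.0 - 2.0 * recomb_fraction(np.abs(morg - dist_m)))
        else:
            f = _linked_pool_freq(cfg, rng, morg, dist_m, k)
        q_pollen = f * (1.0 - e) + (1.0 - f) * e
        q_leaf = 0.5  # 0.5 (1-e) + 0.5 e
        depth_leaf = _draw_depth(cfg, rng, n)
        depth_pollen = _draw_depth(cfg, rng, n)
        mat_leaf = rng.binomial(depth_leaf, q_leaf)
        mat_pollen = rng.binomial(depth_pollen, q_pollen)
        cm = morg * 100.0
        frames_leaf.append(pd.DataFrame({
            "chrom": chrom, "pos_bp": pos_bp, "pos_cM": cm,
            "mat_count": mat_leaf, "pat_count": depth_leaf - mat_leaf}))
        frames_pollen.append(pd.DataFrame({
            "chrom": chrom, "pos_bp": pos_bp, "pos_cM": cm,
            "mat_count": mat_pollen, "pat_count": depth_pollen - mat_pollen}))
        if dist_m is not None:
            truth_d[chrom] = (float(dist_bp), dist_m, float(k))
        truth_f[chrom] = f
    leaf = SiteCountTable(pd.concat(frames_leaf, ignore_index=True)[COUNT_COLUMNS],
                          tissue="leaf", cross_id=f"sim{cfg.seed}")
    pollen = SiteCountTable(pd.concat(frames_pollen, ignore_index=True)[COUNT_COLUMNS],
                            tissue="pollen", cross_id=f"sim{cfg.seed}")
    truth = TruthRecord(distorters=truth_d, transmission=truth_f,
                        seed=cfg.seed, mode=cfg.mode)
    return leaf, pollen, truth


def simulate_effect_matrix(n_crosses: int, distorted_slots: Sequence[int],
                           k_pool: Sequence[float], seed: int,
                           n_chromosomes: int = 8) -> EffectMatrix:
    """Random effect matrices for permutation-test null fixtures.

    Each cross ``i`` receives exactly ``distorted_slots[i]`` nonzero entries
    on randomly chosen chromosomes, with values drawn without replacement
    from ``k_pool``.
    """
    if len(distorted_slots) != n_crosses:
        raise ValueError("need one slot count per cross")
    slots = [int(s) for s in distorted_slots]
    if any(s < 0 or s > n_chromosomes for s in slots):
        raise ValueError(f"slot counts must lie in [0, {n_chromosomes}]")
    total = sum(slots)
    if total > len(k_pool):
        raise ValueError(f"k_pool has {len(k_pool)} values for {total} slots")
    rng = np.random.default_rng(seed)
    values = rng.permutation(np.asarray(k_pool, dtype=float))[:total]
    out = np.zeros((n_crosses, n_chromosomes))
    pos = 0
    for i, s in enumerate(slots):
        cols = rng.choice(n_chromosomes, size=s, replace=False)
        out[i, cols] = values[pos:pos + s]
        pos += s
    df = pd.DataFrame(out, index=[f"sim{i:02d}" for i in range(n_crosses)],
                      columns=[str(c) for c in range(1, n_chromosomes + 1)])
    return EffectMatrix(df)
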
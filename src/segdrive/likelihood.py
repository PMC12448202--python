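"""Maximum-likelihood scan for segregation-distorter position and effect size.

Model
-----
At a candidate distorting locus *i* with distortion coefficient ``k``
(signed deviation of the maternal transmission probability from 1/2), a
surviving gamete carries the maternal allele at a linked site *p* with
probability

    f_p = (0.5 + k)(1 - r) + (0.5 - k) r = 0.5 + k (1 - 2 r)

where ``r = r(d)`` is the recombination fraction at map distance ``d``
Morgans between *p* and *i* (Haldane, no interference). With a symmetric
per-read error rate ``e``, a read maps to the maternal haplotype with
probability

    q_p = f_p (1 - e) + (1 - f_p) e = 0.5 + k (1 - 2 r)(1 - 2 e).

Site read counts are modelled as independent binomials (a composite
likelihood: linkage correlations between sites are ignored for point
estimation). The distorter scan fits ``k`` separately to pollen (germline)
and leaf (somatic) counts at every candidate position and ranks candidates
by the likelihood-ratio statistic

    Lambda(i) = 2 [ l_pollen(k_hat_pollen; i) - l_pollen(k_hat_leaf; i) ]

i.e. the somatic fit serves as the null controlling residual mapping bias.
The called position is the argmax of Lambda; the called effect is the
leaf-corrected difference of fitted coefficients, rounded to two decimals
and thresholded.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy

from .io import GeneticMap, SiteCountTable

__all__ = [
    "LikelihoodModel",
    "DistortionScan",
    "recomb_fraction",
    "maternal_read_prob",
    "chromosome_loglik",
    "fit_k",
    "ChromosomeScanner",
    "scan_chromosome",
    "call_effect",
]

K_EPS = 1e-6  # fitted k is confined to [-0.5 + K_EPS, 0.5 - K_EPS]


def recomb_fraction(d):
    """Haldane recombination fraction for a map distance ``d`` in Morgans.

    r(d) = (1 - exp(-2 d)) / 2; monotone, r(0) = 0, r -> 1/2 as d -> inf.
    """
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d))
    return float(r) if r.ndim == 0 else r


def maternal_read_prob(k, r, e):
    """Probability that a read at a site maps to the maternal haplotype.

    Collapses the four transmission x error outcomes
    (0.5+k)(1-r)(1-e), (0.5-k) r (1-e), (0.5-k)(1-r) e, (0.5+k) r e
    to ``0.5 + k (1 - 2 r)(1 - 2 e)``.
    """
    k = np.asarray(k, dtype=float)
    r = np.asarray(r, dtype=float)
    if (np.abs(k) > 0.5).any():
        raise ValueError("|k| must be <= 0.5")
    if (r < 0).any() or (r > 0.5).any():
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if not 0.0 <= e < 0.5:
        raise ValueError("error rate must lie in [0, 0.5)")
    q = 0.5 + k * (1.0 - 2.0 * r) * (1.0 - 2.0 * e)
    return float(q) if q.ndim == 0 else q


@dataclasses.dataclass
class LikelihoodModel:
    """Scan configuration: genetic map, sequencing error, candidate grid.

    Parameters
    ----------
    genetic_map:
        Physical -> genetic coordinate mapping used for recombination
        distances between sites and candidate loci.
    error_rate:
        Fixed symmetric per-read error probability, shared by both tissues
        of a cross (default 0.005). Leaf deviations from 1/2 absorb error
        plus residual mapping bias through the leaf ``k`` fit.
    grid_thin:
        Candidate-grid thinning: every ``grid_thin``-th retained site is a
        candidate position (1 = every ancestry-informative site).
    site_bin_cM:
        Optional aggregation of sites into genetic-position bins of this
        width (cM) for the likelihood sums: sites in a bin are treated as
        sitting at the bin's mean genetic position, which is exact up to
        the sub-bin variation in recombination distance (relative coupling
        error < bin width in Morgans). 0 (default) disables binning. A
        speed knob for bootstrap-heavy runs; candidate positions are never
        binned.
    min_sites:
        Minimum number of sites required to scan a chromosome.
    """

    genetic_map: GeneticMap
    error_rate: float = 0.005
    grid_thin: int = 1
    site_bin_cM: float = 0.0
    min_sites: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.grid_thin < 1:
            raise ValueError("grid_thin must be >= 1")
        if self.site_bin_cM < 0:
            raise ValueError("site_bin_cM must be >= 0")


@dataclasses.dataclass
class DistortionScan:
    """Result of a per-chromosome distorter scan.

    ``profile`` has one row per candidate position with the pollen and leaf
    fitted coefficients, the pollen log-likelihood at both, and the ratio
    statistic ``lam``; ``ml_index`` indexes the argmax row (smallest position
    on ties).
    """

    chrom: str
    profile: pd.DataFrame  # pos_bp, pos_cM, k_pollen, k_leaf, ll_pollen_kp, ll_pollen_kl, lam
    ml_index: int

    @property
    def ml_pos_bp(self) -> int:
        return int(self.profile["pos_bp"].iloc[self.ml_index])

    @property
    def k_pollen_ml(self) -> float:
        return float(self.profile["k_pollen"].iloc[self.ml_index])

    @property
    def k_leaf_ml(self) -> float:
        return float(self.profile["k_leaf"].iloc[self.ml_index])

    @property
    def lambda_ml(self) -> float:
        return float(self.profile["lam"].iloc[self.ml_index])


# ---------------------------------------------------------------------------
# Internal vectorized machinery
#
# For a fixed candidate the read probability is q_p = 0.5 + k c_p with
# c_p = exp(-2 d_p) (1 - 2 e)  [note 1 - 2 r(d) = exp(-2 d) under Haldane],
# so the log-likelihood is concave in k and Newton iteration with clipping
# to the k bounds converges monotonically from any start.
# ---------------------------------------------------------------------------

def _coupling(site_morgans: np.ndarray, cand_morgans: np.ndarray, e: float
              ) -> np.ndarray:
    """c[g, p] = (1 - 2 r(d_gp)) (1 - 2 e) for candidate g, site p."""
    d = np.abs(site_morgans[None, :] - cand_morgans[:, None])
    return np.exp(-2.0 * d) * (1.0 - 2.0 * e)


def _newton_fit(c: np.ndarray, a: np.ndarray, b: np.ndarray,
                k0: np.ndarray | None = None, tol: float = 1e-8,
                max_iter: int = 80) -> np.ndarray:
    """Maximize sum_p a_p log(0.5 + k c_gp) + b_p log(0.5 - k c_gp) over k,
    per candidate row g, on [-0.5 + K_EPS, 0.5 - K_EPS].

    ``a = w * mat``, ``b = w * pat`` fold in resampling weights.
    """
    lo, hi = -0.5 + K_EPS, 0.5 - K_EPS
    k = np.zeros(c.shape[0]) if k0 is None else np.clip(np.asarray(k0, float).copy(), lo, hi)
    active = np.arange(c.shape[0])  # rows still iterating
    for _ in range(max_iter):
        ca = c[active]
        ka = k[active]
        q = 0.5 + ka[:, None] * ca
        iq = 1.0 / q
        i1q = 1.0 / (1.0 - q)
        p1 = a * iq
        p2 = b * i1q
        grad = ((p1 - p2) * ca).sum(axis=1)
        hess = -((p1 * iq + p2 * i1q) * ca * ca).sum(axis=1)
        step = grad / np.minimum(hess, -1e-300)  # hess < 0 whenever any count > 0
        k_new = np.clip(ka - step, lo, hi)
        delta = np.abs(k_new - ka)
        k[active] = k_new
        active = active[delta > tol]
        if active.size == 0:
            break
    return k


def _loglik_at(c: np.ndarray, a: np.ndarray, b: np.ndarray, k: np.ndarray
               ) -> np.ndarray:
    """sum_p a_p log q + b_p log(1-q) per candidate row (no binomial-coeff
    constant).

    q is strictly inside (0, 1) for |k| < 0.5 (and for |k| = 0.5 with e > 0),
    so plain logs are safe there; xlogy guards the boundary case |k| = 0.5,
    e = 0 where a site with q = 0 or 1 and zero count must contribute 0.
    """
    q = 0.5 + np.asarray(k, float)[:, None] * c
    if q.min() > 0.0 and q.max() < 1.0:
        return a @ np.log(q).T + b @ np.log1p(-q).T
    return (xlogy(a, q) + xlogy(b, 1.0 - q)).sum(axis=1)


def _site_arrays(table: SiteCountTable, chrom) -> tuple[np.ndarray, ...]:
    sub = table.data[table.data["chrom"] == chrom]
    mat = sub["mat_count"].to_numpy(float)
    pat = sub["pat_count"].to_numpy(float)
    pos_bp = sub["pos_bp"].to_numpy(int)
    return pos_bp, sub["pos_cM"].to_numpy(float) / 100.0, mat, pat


def _log_binom_const(mat: np.ndarray, pat: np.ndarray,
                     w: np.ndarray | None = None) -> float:
    n = mat + pat
    lc = gammaln(n + 1.0) - gammaln(mat + 1.0) - gammaln(pat + 1.0)
    return float((lc if w is None else w * lc).sum())


def _single_chrom(table: SiteCountTable, chrom):
    if chrom is None:
        chroms = table.chromosomes()
        if len(chroms) != 1:
            raise ValueError("table spans multiple chromosomes; pass chrom=")
        return chroms[0]
    return chrom


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def chromosome_loglik(table: SiteCountTable, i_bp: float, k: float,
                      model: LikelihoodModel, chrom=None) -> float:
    """Composite log-likelihood of all site counts on a chromosome given a
    distorter of effect ``k`` at physical position ``i_bp``.

    Every site contributes through linkage:
    ``sum_p log Binom(mat_p; mat_p + pat_p, q_p)`` with
    ``q_p = maternal_read_prob(k, r(d_p), e)``.
    """
    if abs(k) > 0.5:
        raise ValueError("|k| must be <= 0.5")
    chrom = _single_chrom(table, chrom)
    pos_bp, morg, mat, pat = _site_arrays(table, chrom)
    if len(pos_bp) == 0:
        raise ValueError(f"no sites on chromosome {chrom!r}")
    cand = np.atleast_1d(model.genetic_map.morgans(chrom, i_bp)).astype(float)
    c = _coupling(morg, cand, model.error_rate)
    ll = _loglik_at(c, mat, pat, np.array([k]))[0]
    return ll + _log_binom_const(mat, pat)


def fit_k(table: SiteCountTable, i_bp: float, model: LikelihoodModel,
          chrom=None) -> tuple[float, float]:
    """Maximum-likelihood distortion coefficient at candidate position
    ``i_bp`` and its log-likelihood, on the bounded interval
    ``[-0.5 + 1e-6, 0.5 - 1e-6]``."""
    chrom = _single_chrom(table, chrom)
    pos_bp, morg, mat, pat = _site_arrays(table, chrom)
    if len(pos_bp) == 0:
        raise ValueError(f"no sites on chromosome {chrom!r}")
    cand = np.atleast_1d(model.genetic_map.morgans(chrom, i_bp)).astype(float)
    c = _coupling(morg, cand, model.error_rate)
    k_hat = _newton_fit(c, mat, pat)
    ll = _loglik_at(c, mat, pat, k_hat)[0] + _log_binom_const(mat, pat)
    return float(k_hat[0]), float(ll)


class ChromosomeScanner:
    """Reusable scan workspace for one chromosome of one cross.

    Precomputes the candidate grid and the candidate-by-site coupling
    matrix ``c`` (which depends only on positions and the error rate), so
    repeated scans under different site-resampling weights — the bootstrap
    inner loop — pay only the Newton iterations. Warm starts reuse the
    previous fit, which for resampled data is a few iterations from the
    solution.
    """

    def __init__(self, pollen: SiteCountTable, leaf: SiteCountTable,
                 model: LikelihoodModel, chrom=None, block: int = 2048):
        chrom = _single_chrom(pollen, chrom)
        pos_bp, morg, mat_p, pat_p = _site_arrays(pollen, chrom)
        pos_bp_l, _, mat_l, pat_l = _site_arrays(leaf, chrom)
        if len(pos_bp) < model.min_sites:
            raise ValueError(f"chromosome {chrom!r} has {len(pos_bp)} sites; "
                             f"need >= {model.min_sites}")
        if len(pos_bp_l) != len(pos_bp) or (pos_bp_l != pos_bp).any():
            raise ValueError("pollen and leaf tables must share the same site "
                             "set (use intersect_sites first)")
        self.chrom = str(chrom)
        self.model = model
        self.pos_bp, self.morg = pos_bp, morg
        self.mat_p, self.pat_p = mat_p, pat_p
        self.mat_l, self.pat_l = mat_l, pat_l
        self.cand_idx = np.arange(0, len(pos_bp), model.grid_thin)
        if model.site_bin_cM > 0:
            binw = model.site_bin_cM / 100.0  # Morgans
            raw = np.floor(morg / binw).astype(int)
            _, self._bin_of_site = np.unique(raw, return_inverse=True)
            nb = self._bin_of_site.max() + 1
            site_morg = (np.bincount(self._bin_of_site, weights=morg,
                                     minlength=nb)
                         / np.bincount(self._bin_of_site, minlength=nb))
        else:
            self._bin_of_site = None
            site_morg = morg
        self._n_terms = len(site_morg)
        self._blocks = []
        for start in range(0, len(self.cand_idx), block):
            sel = self.cand_idx[start:start + block]
            self._blocks.append(
                (slice(start, start + len(sel)),
                 _coupling(site_morg, morg[sel], model.error_rate)))
        self._last_kp: np.ndarray | None = None
        self._last_kl: np.ndarray | None = None

    @property
    def n_sites(self) -> int:
        return len(self.pos_bp)

    def scan(self, weights: np.ndarray | None = None,
             warm_start: bool = True) -> DistortionScan:
        w = None if weights is None else np.asarray(weights, float)
        if w is not None and (w.shape != self.mat_p.shape or (w < 0).any()):
            raise ValueError("weights must be non-negative, one per site")
        mul = (lambda x: x) if w is None else (lambda x: w * x)
        if self._bin_of_site is None:
            agg = mul
        else:
            def agg(x):
                return np.bincount(self._bin_of_site, weights=mul(x),
                                   minlength=self._n_terms)
        ap, bp_ = agg(self.mat_p), agg(self.pat_p)
        al, bl = agg(self.mat_l), agg(self.pat_l)
        const_p = _log_binom_const(self.mat_p, self.pat_p, w)

        G = len(self.cand_idx)
        k_pol, k_lea = np.empty(G), np.empty(G)
        ll_kp, ll_kl = np.empty(G), np.empty(G)
        init_p = self._last_kp if warm_start else None
        init_l = self._last_kl if warm_start else None
        for sl, c in self._blocks:
            kp = _newton_fit(c, ap, bp_, None if init_p is None else init_p[sl])
            kl = _newton_fit(c, al, bl, None if init_l is None else init_l[sl])
            k_pol[sl], k_lea[sl] = kp, kl
            ll_kp[sl] = _loglik_at(c, ap, bp_, kp) + const_p
            ll_kl[sl] = _loglik_at(c, ap, bp_, kl) + const_p
        self._last_kp, self._last_kl = k_pol, k_lea

        lam = np.maximum(2.0 * (ll_kp - ll_kl), 0.0)
        profile = pd.DataFrame({
            "pos_bp": self.pos_bp[self.cand_idx],
            "pos_cM": self.morg[self.cand_idx] * 100.0,
            "k_pollen": k_pol,
            "k_leaf": k_lea,
            "ll_pollen_kp": ll_kp,
            "ll_pollen_kl": ll_kl,
            "lam": lam,
        })
        ml_index = int(np.argmax(lam))  # first (smallest bp) argmax on ties
        return DistortionScan(chrom=self.chrom, profile=profile,
                              ml_index=ml_index)


def scan_chromosome(pollen: SiteCountTable, leaf: SiteCountTable,
                    model: LikelihoodModel, chrom=None,
                    weights: np.ndarray | None = None) -> DistortionScan:
    """Fit ``k`` to pollen and leaf counts at every candidate position and
    locate the distorter as the argmax of the germline-vs-somatic likelihood
    ratio.

    Parameters
    ----------
    weights:
        Optional per-site non-negative multiplicities (bootstrap resampling
        weights, aligned with the chromosome's sites in both tissues). The
        candidate grid always stays the full (thinned) site grid so that
        profiles from different resamples are comparable.
    """
    return ChromosomeScanner(pollen, leaf, model, chrom=chrom).scan(weights)


def call_effect(scan: DistortionScan, min_effect: float = 0.02,
                mode: str = "difference") -> float:
    """Signed effect size called from a completed scan.

    ``mode="difference"`` (default) reports the pollen-fit minus leaf-fit
    coefficient at the ML position — the somatic fit acts as the null
    controlling shared mapping bias; ``mode="pollen"`` reports the raw
    germline coefficient. The value is rounded to 2 decimals and set to 0
    when below ``min_effect`` in magnitude.
    """
    if mode == "difference":
        eff = scan.k_pollen_ml - scan.k_leaf_ml
    elif mode == "pollen":
        eff = scan.k_pollen_ml
    else:
        raise ValueError("mode must be 'difference' or 'pollen'")
    eff = round(eff, 2)
    return eff if abs(eff) >= min_effect else 0.0
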
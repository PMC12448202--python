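"""Site filters and descriptive ancestry-ratio summaries.

The ancestry proportion at a site is the fraction of reads mapping to the
maternal haplotype, mat / (mat + pat) — near 1/2 in somatic tissue, skewed
in pollen at and around a distorter. Filters mirror the variant-site
hygiene applied upstream of distorter mapping: depth-quantile trimming
(against structural variants and repeats) and removal of proximal site
pairs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import CountTableError, SiteCountTable, intersect_sites

__all__ = [
    "WindowedRatios",
    "filter_depth_quantiles",
    "filter_proximal_sites",
    "apply_site_filters",
    "ancestry_proportion",
    "window_ratios",
]


def filter_depth_quantiles(table: SiteCountTable, q_low: float = 0.05,
                           q_high: float = 0.95) -> SiteCountTable:
    """Remove sites whose total depth falls strictly below the ``q_low`` or
    strictly above the ``q_high`` depth quantile of this table.

    Quantiles use linear interpolation between order statistics and are
    computed on the input table (per sample).
    """
    if table.n_sites == 0:
        raise CountTableError("empty table")
    if not 0.0 <= q_low < q_high <= 1.0:
        raise ValueError("need 0 <= q_low < q_high <= 1")
    depth = table.depth
    lo = np.quantile(depth, q_low)
    hi = np.quantile(depth, q_high)
    keep = (depth >= lo) & (depth <= hi)
    if not keep.any():
        raise CountTableError("depth filter removed every site")
    return table.subset(keep)


def filter_proximal_sites(table: SiteCountTable, min_gap_bp: int = 100
                          ) -> SiteCountTable:
    """Remove every site lying within ``min_gap_bp`` (strictly less) of
    another site on the same chromosome; both members of a close pair are
    removed. A gap of exactly ``min_gap_bp`` is kept.
    """
    if table.n_sites == 0:
        return table
    keep_parts = []
    for chrom, sub in table.data.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        gap_prev = np.diff(pos, prepend=pos[0] - 2 * min_gap_bp)
        gap_next = np.diff(pos, append=pos[-1] + 2 * min_gap_bp)
        keep_parts.append(pd.Series((gap_prev >= min_gap_bp) & (gap_next >= min_gap_bp),
                                    index=sub.index))
    keep = pd.concat(keep_parts).reindex(table.data.index)
    return SiteCountTable(table.data[keep.to_numpy()].copy(),
                          tissue=table.tissue, cross_id=table.cross_id)


def apply_site_filters(leaf: SiteCountTable, pollen: SiteCountTable,
                       q_low: float = 0.05, q_high: float = 0.95,
                       min_gap_bp: int = 100
                       ) -> tuple[SiteCountTable, SiteCountTable]:
    """Standard per-tissue filtering followed by re-intersection of the
    retained site sets (depth quantiles are per sample, the proximity rule
    is positional and shared)."""
    leaf_f = filter_depth_quantiles(leaf, q_low, q_high)
    pollen_f = filter_depth_quantiles(pollen, q_low, q_high)
    leaf_f = filter_proximal_sites(leaf_f, min_gap_bp)
    pollen_f = filter_proximal_sites(pollen_f, min_gap_bp)
    return intersect_sites(leaf_f, pollen_f)


def ancestry_proportion(mat_count, pat_count):
    """Maternal read proportion mat / (mat + pat); errors on zero depth."""
    mat = np.asarray(mat_count, dtype=float)
    pat = np.asarray(pat_count, dtype=float)
    total = mat + pat
    if (total <= 0).any():
        raise ValueError("zero total depth")
    out = mat / total
    return float(out) if out.ndim == 0 else out


@dataclasses.dataclass
class WindowedRatios:
    """Per-window mean ancestry proportions and pollen-minus-leaf difference.

    Windows are non-overlapping runs of ``window_snps`` consecutive sites
    within a chromosome (the last window of a chromosome may be short).
    """

    table: pd.DataFrame  # chrom, start_bp, end_bp, n_sites, leaf_mean, pollen_mean, difference
    window_snps: int

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def plot(self, path=None):  # pragma: no cover - visual convenience
        """Figure in the windowed-ratio style: per-tissue window means plus
        their difference, one panel row per chromosome."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        chroms = list(dict.fromkeys(self.table["chrom"]))
        fig, axes = plt.subplots(len(chroms), 1, squeeze=False,
                                 figsize=(8, 2.2 * len(chroms)))
        for ax, chrom in zip(axes[:, 0], chroms):
            sub = self.table[self.table["chrom"] == chrom]
            mid = (sub["start_bp"] + sub["end_bp"]) / 2e6
            ax.plot(mid, sub["leaf_mean"], color="firebrick", label="leaf")
            ax.plot(mid, sub["pollen_mean"], color="steelblue", label="pollen")
            ax.plot(mid, sub["difference"], color="seagreen", label="difference")
            ax.axhline(0.5, ls="--", c="gray", lw=0.7)
            ax.axhline(0.0, ls=":", c="gray", lw=0.7)
            ax.set_ylabel(f"chr {chrom}")
        axes[-1, 0].set_xlabel("position (Mb)")
        axes[0, 0].legend(ncol=3, fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def window_ratios(leaf: SiteCountTable, pollen: SiteCountTable,
                  window_snps: int = 1000) -> WindowedRatios:
    """Mean per-site ancestry proportion per tissue in non-overlapping
    windows of ``window_snps`` consecutive shared sites; difference is
    pollen minus leaf (sign matches the maternal-positive k convention)."""
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    if len(leaf.data) != len(pollen.data) or \
            (leaf.data["pos_bp"].to_numpy() != pollen.data["pos_bp"].to_numpy()).any() or \
            (leaf.data["chrom"].to_numpy() != pollen.data["chrom"].to_numpy()).any():
        raise ValueError("leaf and pollen tables must share the same site set")
    rows = []
    for chrom, sub_l in leaf.data.groupby("chrom", sort=False):
        sub_p = pollen.data[pollen.data["chrom"] == chrom]
        prop_l = ancestry_proportion(sub_l["mat_count"], sub_l["pat_count"])
        prop_p = ancestry_proportion(sub_p["mat_count"], sub_p["pat_count"])
        pos = sub_l["pos_bp"].to_numpy()
        for start in range(0, len(pos), window_snps):
            sl = slice(start, start + window_snps)
            lm = float(np.mean(prop_l[sl]))
            pm = float(np.mean(prop_p[sl]))
            rows.append((chrom, int(pos[sl][0]), int(pos[sl][-1]),
                         len(pos[sl]), lm, pm, pm - lm))
    table = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                        "n_sites", "leaf_mean", "pollen_mean",
                                        "difference"])
    return WindowedRatios(table=table, window_snps=window_snps)
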
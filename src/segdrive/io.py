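"""Readers, writers and packaged fixtures for count tables, genetic maps,
effect matrices and cross metadata.

The central container is :class:`SiteCountTable`: per-site maternal/paternal
read counts for one tissue (leaf or pollen) of one F1 cross, at phased
ancestry-informative SNPs. Positions are 1-based physical coordinates
(``pos_bp``) paired with genetic-map coordinates in centiMorgans (``pos_cM``).

The packaged fixtures transcribe the published effect-size matrix for 14
*Arabidopsis halleri* x *A. lyrata* F1 hybrids (8 chromosomes each, signed
distortion coefficients k, 0 = no distorter called) and the associated cross
metadata (cross group WR/BR/BS, mother and father IDs).
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SiteCountTable",
    "GeneticMap",
    "EffectMatrix",
    "CrossMetadata",
    "read_count_table",
    "write_count_table",
    "read_genetic_map",
    "load_f1_effect_matrix",
    "read_effect_matrix",
    "write_effect_matrix",
    "intersect_sites",
    "read_phased_vcf_counts",
]

COUNT_COLUMNS = ["chrom", "pos_bp", "pos_cM", "mat_count", "pat_count"]

CHROMOSOMES = [str(c) for c in range(1, 9)]


class CountTableError(ValueError):
    """Malformed or invariant-violating count-table input."""


@dataclasses.dataclass
class SiteCountTable:
    """Per-site phased read counts for one tissue of one cross.

    Parameters
    ----------
    data:
        DataFrame with columns ``chrom, pos_bp, pos_cM, mat_count, pat_count``,
        sorted by (chrom, pos_bp), with pos_bp strictly increasing and pos_cM
        non-decreasing within each chromosome.
    tissue:
        ``"leaf"`` (somatic) or ``"pollen"`` (germline).
    cross_id:
        Identifier of the F1 cross, e.g. ``"BS09"``.
    """

    data: pd.DataFrame
    tissue: str = "pollen"
    cross_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise CountTableError(f"missing columns: {missing}")
        if self.tissue not in ("leaf", "pollen"):
            raise CountTableError(f"tissue must be 'leaf' or 'pollen', got {self.tissue!r}")
        if (df["mat_count"] < 0).any() or (df["pat_count"] < 0).any():
            bad = df.index[(df["mat_count"] < 0) | (df["pat_count"] < 0)][0]
            raise CountTableError(f"negative count at row {bad + 1}")
        for chrom, sub in df.groupby("chrom", sort=False):
            dp = np.diff(sub["pos_bp"].to_numpy())
            if (dp <= 0).any():
                i = sub.index[int(np.argmax(dp <= 0)) + 1]
                raise CountTableError(
                    f"pos_bp not strictly increasing on chrom {chrom} at row {i + 1}"
                )
            dc = np.diff(sub["pos_cM"].to_numpy())
            if (dc < 0).any():
                i = sub.index[int(np.argmax(dc < 0)) + 1]
                raise CountTableError(
                    f"pos_cM decreasing on chrom {chrom} at row {i + 1}"
                )

    # -- convenience accessors used throughout the scan code ---------------
    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def depth(self) -> np.ndarray:
        return (self.data["mat_count"] + self.data["pat_count"]).to_numpy()

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.data["chrom"]))

    def for_chrom(self, chrom) -> "SiteCountTable":
        sub = self.data[self.data["chrom"] == chrom]
        if sub.empty:
            raise KeyError(f"no sites on chromosome {chrom!r}")
        return SiteCountTable(sub.copy(), tissue=self.tissue, cross_id=self.cross_id)

    def subset(self, mask_or_idx) -> "SiteCountTable":
        sub = self.data.loc[mask_or_idx] if np.asarray(mask_or_idx).dtype == bool else self.data.iloc[mask_or_idx]
        return SiteCountTable(sub.copy(), tissue=self.tissue, cross_id=self.cross_id)


def read_count_table(path, tissue: str, cross_id: str) -> SiteCountTable:
    """Read a tab-separated count table (header: chrom, pos_bp, pos_cM,
    mat_count, pat_count).

    Invariant violations are rejected with the 1-based data row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise CountTableError(f"{path}: missing columns {missing}")
    df["chrom"] = df["chrom"].astype(str)
    for col in ("pos_bp", "mat_count", "pat_count"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 1 if len(bad) else "?"
            raise CountTableError(f"{path}: non-numeric {col} at row {row}")
        df[col] = df[col].astype(int)
    df["pos_cM"] = df["pos_cM"].astype(float)
    try:
        return SiteCountTable(df, tissue=tissue, cross_id=cross_id)
    except CountTableError as err:
        raise CountTableError(f"{path}: {err}") from None


def write_count_table(table: SiteCountTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Monotone physical (bp) -> genetic (cM) coordinate mapping per chromosome.

    Built from anchor points; positions between anchors are linearly
    interpolated, positions outside the anchor range are linearly extrapolated
    from the terminal segments (clamped at 0 cM).
    """

    def __init__(self, anchors: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.ndim != 1 or bp.shape != cm.shape or len(bp) < 1:
                raise ValueError(f"chrom {chrom}: need >= 1 anchor point")
            if len(bp) == 1:  # degenerate: constant genetic position
                bp = np.array([bp[0], bp[0] + 1.0])
                cm = np.array([cm[0], cm[0]])
            if (np.diff(bp) <= 0).any():
                raise ValueError(f"chrom {chrom}: pos_bp must be strictly increasing")
            if (np.diff(cm) < 0).any():
                raise ValueError(f"chrom {chrom}: pos_cM must be non-decreasing")
            self._anchors[str(chrom)] = (bp, cm)

    @classmethod
    def linear(cls, chrom_length_bp: int, map_length_morgans: float,
               chromosomes: Iterable = ("1",)) -> "GeneticMap":
        """Uniform recombination rate: ``map_length_morgans`` over the full
        chromosome length, identical for every chromosome listed."""
        anchors = {
            str(c): (np.array([1.0, float(chrom_length_bp)]),
                     np.array([0.0, 100.0 * map_length_morgans]))
            for c in chromosomes
        }
        return cls(anchors)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in ("chrom", "pos_bp", "pos_cM"):
            if col not in df.columns:
                raise ValueError(f"{path}: genetic map needs column {col}")
        anchors = {
            str(chrom): (sub["pos_bp"].to_numpy(float), sub["pos_cM"].to_numpy(float))
            for chrom, sub in df.groupby("chrom", sort=False)
        }
        return cls(anchors)

    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def cM(self, chrom, pos_bp) -> np.ndarray:
        """Genetic position (cM) of physical position(s) on a chromosome."""
        bp, cm = self._anchors[str(chrom)]
        pos = np.asarray(pos_bp, dtype=float)
        out = np.interp(pos, bp, cm)
        # linear extrapolation beyond terminal anchors, clamped at 0
        lo_slope = (cm[1] - cm[0]) / (bp[1] - bp[0])
        hi_slope = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        out = np.where(pos < bp[0], cm[0] + (pos - bp[0]) * lo_slope, out)
        out = np.where(pos > bp[-1], cm[-1] + (pos - bp[-1]) * hi_slope, out)
        return np.maximum(out, 0.0)

    def morgans(self, chrom, pos_bp) -> np.ndarray:
        return self.cM(chrom, pos_bp) / 100.0


def read_genetic_map(path) -> GeneticMap:
    return GeneticMap.from_tsv(path)


# ---------------------------------------------------------------------------
# Effect matrix + cross metadata
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class EffectMatrix:
    """Signed distortion effect sizes k per cross (rows) and chromosome
    (columns ``"1"``..``"8"``); 0 marks chromosomes with no called distorter.

    Sign convention: distortion toward maternal alleles is positive, toward
    paternal alleles negative.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.columns = [str(c) for c in self.values.columns]
        if (self.values.abs() > 0.5).any().any():
            raise ValueError("|k| must be <= 0.5")

    @property
    def crosses(self) -> list[str]:
        return list(self.values.index)

    @property
    def chrom_labels(self) -> list[str]:
        return list(self.values.columns)

    def to_array(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def n_distorted(self) -> pd.Series:
        """Number of distorted (nonzero) chromosomes per cross."""
        return (self.values != 0).sum(axis=1)

    def restrict(self, crosses: Iterable[str]) -> "EffectMatrix":
        return EffectMatrix(self.values.loc[list(crosses)])


@dataclasses.dataclass
class CrossMetadata:
    """Cross ID -> group (WR/BR/BS), mother ID, father ID."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"cross_id", "group", "mother", "father"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"metadata needs columns {sorted(need)}")
        if self.table[["mother", "father"]].isna().any().any():
            raise ValueError("parent IDs must be nonempty")
        bad = ~self.table["group"].isin(["WR", "BR", "BS"])
        if bad.any():
            raise ValueError(f"unknown group labels: {self.table['group'][bad].tolist()}")
        self.table = self.table.set_index("cross_id", drop=False)

    def groups(self) -> pd.Series:
        return self.table["group"]

    def crosses_in(self, labels: Iterable[str]) -> list[str]:
        labels = set(labels)
        return [c for c in self.table.index if self.table.loc[c, "group"] in labels]

    def parents(self, cross_id: str) -> tuple[str, str]:
        row = self.table.loc[cross_id]
        return str(row["mother"]), str(row["father"])

    def shared_parent_crosses(self) -> list[str]:
        """Crosses sharing at least one parent ID with another cross."""
        out = []
        for c in self.table.index:
            mine = set(self.parents(c))
            for other in self.table.index:
                if other == c:
                    continue
                if mine & set(self.parents(other)):
                    out.append(c)
                    break
        return out


def _data_path(name: str):
    return resources.files("segdrive") / "data" / name


def load_f1_effect_matrix() -> tuple[EffectMatrix, CrossMetadata]:
    """Load the packaged effect-size matrix and cross metadata for the 14
    published *A. halleri* x *A. lyrata* F1 hybrids.

    The effect matrix is a verbatim transcription of the published
    per-chromosome estimates (29 nonzero entries). In the metadata, only two
    parent IDs are published (Pais09, the mother of BR01 and father of BR02;
    Hall2.2, shared by BS08 and BS09) — all other parent IDs are synthetic
    placeholders of the form ``<cross>.m`` / ``<cross>.f`` and carry no
    information beyond being distinct.
    """
    with resources.as_file(_data_path("f1_effect_sizes.tsv")) as p:
        matrix = read_effect_matrix(p)
    with resources.as_file(_data_path("f1_cross_metadata.tsv")) as p:
        meta = CrossMetadata(pd.read_csv(p, sep="\t", comment="#", dtype=str))
    return matrix, meta


def read_effect_matrix(path) -> EffectMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="cross_id")
    return EffectMatrix(df.astype(float))


def write_effect_matrix(matrix: EffectMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="cross_id")


# ---------------------------------------------------------------------------
# Site intersection
# ---------------------------------------------------------------------------

def intersect_sites(leaf: SiteCountTable, pollen: SiteCountTable
                    ) -> tuple[SiteCountTable, SiteCountTable]:
    """Restrict both tissues to the common (chrom, pos_bp) site set.

    Mirrors the analysis convention of using the intersection of retained
    ancestry-informative sites shared between pollen and leaf samples.
    """
    if leaf.cross_id != pollen.cross_id:
        raise ValueError(
            f"cross mismatch: {leaf.cross_id!r} vs {pollen.cross_id!r}"
        )
    key = ["chrom", "pos_bp"]
    common = pd.merge(leaf.data[key], pollen.data[key], on=key)
    if common.empty:
        raise CountTableError("empty site intersection between leaf and pollen")
    lmask = pd.MultiIndex.from_frame(leaf.data[key]).isin(
        pd.MultiIndex.from_frame(common))
    pmask = pd.MultiIndex.from_frame(pollen.data[key]).isin(
        pd.MultiIndex.from_frame(common))
    out_leaf = SiteCountTable(leaf.data[lmask].copy(), tissue=leaf.tissue,
                              cross_id=leaf.cross_id)
    out_pollen = SiteCountTable(pollen.data[pmask].copy(), tissue=pollen.tissue,
                                cross_id=pollen.cross_id)
    return out_leaf, out_pollen


# ---------------------------------------------------------------------------
# Optional VCF ingestion (convenience; not used by the simulation pipeline)
# ---------------------------------------------------------------------------

def read_phased_vcf_counts(path, sample: str, tissue: str, cross_id: str,
                           genetic_map: GeneticMap | None = None
                           ) -> SiteCountTable:
    """Build a :class:`SiteCountTable` from a phased VCF.

    Expects phased genotypes (``GT`` with ``|``) where haplotype 0 is maternal
    and haplotype 1 paternal, plus per-allele depths in ``AD``. Heterozygous
    phased sites only; others are skipped. Genetic positions come from
    ``genetic_map`` when given, else are set to 0.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("cyvcf2 is required for VCF ingestion") from err

    vcf = VCF(str(path))
    try:
        si = vcf.samples.index(sample)
    except ValueError:
        raise KeyError(f"sample {sample!r} not in {path}") from None
    rows = []
    for var in vcf:
        gt = var.genotypes[si]
        if len(gt) < 3 or not gt[2]:  # unphased
            continue
        a0, a1 = gt[0], gt[1]
        if a0 == a1 or a0 < 0 or a1 < 0:
            continue
        ad = var.format("AD")
        if ad is None:
            continue
        depths = ad[si]
        mat, pat = int(depths[a0]), int(depths[a1])
        if mat < 0 or pat < 0:
            continue
        rows.append((str(var.CHROM), int(var.POS), mat, pat))
    df = pd.DataFrame(rows, columns=["chrom", "pos_bp", "mat_count", "pat_count"])
    if genetic_map is not None:
        df["pos_cM"] = [
            float(genetic_map.cM(c, p)) for c, p in zip(df["chrom"], df["pos_bp"])
        ]
    else:
        df["pos_cM"] = 0.0
    df = df[COUNT_COLUMNS]
    return SiteCountTable(df, tissue=tissue, cross_id=cross_id)
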
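"""Core data types, TSV I/O, marker quality control and map-comparison statistics.

Genetic maps are ordered collections of linkage groups; genotype matrices hold
the two homozygous classes of a biparental RIL/DH population coded 0/1 with
NaN for missing calls.  Heterozygous calls, which are transient in such
populations, are converted to missing on input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneticMap",
    "GenotypeMatrix",
    "MapSummary",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_physical_map",
    "qc_filter_markers",
    "spearman_collinearity",
    "consistent_order_proportion",
    "map_summary",
]

MISSING = np.nan


@dataclass
class GeneticMap:
    """An ordered linkage map: one or more groups of (marker, cM position).

    ``table`` has columns ``marker``, ``chromosome``, ``position_cM`` and is
    ordered by group then position.  Positions within a group are
    non-decreasing; ``normalize()`` shifts every group to start at 0 cM.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position_cM"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if self.table["marker"].duplicated().any():
            dups = self.table.loc[self.table["marker"].duplicated(), "marker"]
            raise ValueError(f"duplicate marker names in map: {list(dups[:5])}")
        pos = self.table["position_cM"].to_numpy(float)
        if not np.all(np.isfinite(pos)) or (pos < 0).any():
            raise ValueError("map positions must be finite and non-negative")
        for _, grp in self.table.groupby("chromosome", sort=False):
            p = grp["position_cM"].to_numpy(float)
            if (np.diff(p) < -1e-9).any():
                raise ValueError("positions within a group must be non-decreasing")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_positions(
        cls, markers: Sequence[str], positions: Sequence[float], chromosome: str = "1"
    ) -> "GeneticMap":
        return cls(
            pd.DataFrame(
                {
                    "marker": list(markers),
                    "chromosome": chromosome,
                    "position_cM": np.asarray(positions, float),
                }
            )
        )

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    @property
    def markers(self) -> list[str]:
        return list(self.table["marker"])

    def group(self, chromosome: str) -> pd.DataFrame:
        return self.table[self.table["chromosome"] == chromosome].reset_index(drop=True)

    def positions(self, chromosome: str) -> np.ndarray:
        return self.group(chromosome)["position_cM"].to_numpy(float)

    def chromosome_of(self) -> dict[str, str]:
        return dict(zip(self.table["marker"], self.table["chromosome"]))

    def normalize(self) -> "GeneticMap":
        """Shift each group so its first marker sits at 0 cM."""
        tab = self.table.copy()
        tab["position_cM"] = tab.groupby("chromosome", sort=False)[
            "position_cM"
        ].transform(lambda p: p - p.iloc[0])
        return GeneticMap(tab)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GenotypeMatrix:
    """Lines x markers genotype codes for one RIL/DH population.

    Codes: 0.0 = parent-1 homozygote, 1.0 = parent-2 homozygote, NaN = missing.
    """

    lines: list[str]
    markers: list[str]
    codes: np.ndarray  # float array, shape (n_lines, n_markers)
    population_type: str = "RIL_selfing"  # or "DH"

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.lines), len(self.markers)):
            raise ValueError("codes shape inconsistent with line/marker lists")
        legal = np.isnan(self.codes) | (self.codes == 0) | (self.codes == 1)
        if not legal.all():
            bad = np.unique(self.codes[~legal])
            raise ValueError(f"illegal genotype codes: {bad}")
        if len(set(self.lines)) != len(self.lines):
            raise ValueError("duplicate line identifiers")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("duplicate marker names")
        if self.population_type not in ("RIL_selfing", "DH"):
            raise ValueError(f"unknown population type {self.population_type!r}")

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def column(self, marker: str) -> np.ndarray:
        return self.codes[:, self.markers.index(marker)]

    def subset_markers(self, keep: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.markers.index(m) for m in keep]
        return GenotypeMatrix(
            list(self.lines), list(keep), self.codes[:, idx], self.population_type
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.lines, columns=self.markers)


@dataclass
class MapSummary:
    """Per-group and total map summary statistics (Table-2-style)."""

    per_group: pd.DataFrame  # chromosome, length_cM, n_markers, n_bins, mean/max bin distance, n_gaps
    total: dict = field(default_factory=dict)


@dataclass
class QCReport:
    removed: pd.DataFrame  # marker, reason, statistic
    n_input: int
    n_retained: int


# ---------------------------------------------------------------------------
# I/O


def read_genotypes(
    path,
    *,
    sep: str = "\t",
    alleles: Mapping[str, float] | None = None,
    het_to_missing: bool = True,
    population_type: str = "RIL_selfing",
) -> GenotypeMatrix:
    """Read a genotype table: header of marker names, first column line IDs.

    Default allele symbols are ``A`` (parent 1), ``B`` (parent 2), ``H``
    (heterozygote) and ``-`` (missing); ``H`` becomes missing when
    ``het_to_missing`` is set, mirroring how residual heterozygotes are
    treated in inbred-line panels.
    """
    header = pd.read_csv(path, sep=sep, header=None, nrows=1, dtype=str)
    if hasattr(path, "seek"):
        path.seek(0)
    names = list(header.iloc[0, 1:])
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker columns in genotype file")
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"empty genotype file: {path}")
    df.columns = names
    if df.index.duplicated().any():
        raise ValueError("duplicate line identifiers in genotype file")
    if df.isna().any().any():
        raise ValueError("ragged or incomplete rows in genotype file")
    symbol_map = {"A": 0.0, "B": 1.0, "-": MISSING}
    if alleles:
        symbol_map = dict(alleles)
    symbol_map = dict(symbol_map)
    symbol_map["H"] = MISSING if het_to_missing else symbol_map.get("H", MISSING)
    values = df.to_numpy()
    seen = set(np.unique(values))
    unknown = seen - set(symbol_map)
    if unknown:
        raise ValueError(f"unknown allele symbols: {sorted(unknown)}")
    codes = np.vectorize(lambda s: symbol_map[s], otypes=[float])(values)
    return GenotypeMatrix(list(df.index), list(df.columns), codes, population_type)


def write_genotypes(geno: GenotypeMatrix, path, *, sep: str = "\t") -> None:
    rev = {0.0: "A", 1.0: "B"}
    out = np.full(geno.codes.shape, "-", dtype=object)
    for code, sym in rev.items():
        out[geno.codes == code] = sym
    pd.DataFrame(out, index=geno.lines, columns=geno.markers).to_csv(
        path, sep=sep, index_label="line"
    )


def read_map(path, *, sep: str = "\t") -> GeneticMap:
    """Read a map TSV with columns marker, chromosome, position_cM."""
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    df.columns = ["marker", "chromosome", "position_cM"] + list(df.columns[3:])
    df = df.sort_values(["chromosome", "position_cM"], kind="stable")
    return GeneticMap(df[["marker", "chromosome", "position_cM"]])


def write_map(gmap: GeneticMap, path, *, sep: str = "\t") -> None:
    gmap.normalize().table.to_csv(path, sep=sep, index=False)


def read_physical_map(path, *, sep: str = "\t") -> pd.DataFrame:
    """Physical map TSV: marker, chromosome, position_bp."""
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str})
    df.columns = ["marker", "chromosome", "position_bp"] + list(df.columns[3:])
    bp = df["position_bp"].to_numpy()
    if (bp <= 0).any():
        raise ValueError("physical positions must be positive")
    return df[["marker", "chromosome", "position_bp"]]


# ---------------------------------------------------------------------------
# Quality control


def qc_filter_markers(
    geno: GenotypeMatrix,
    *,
    max_missing: float = 0.10,
    min_maf: float = 0.30,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove markers by missingness then minor-allele frequency.

    A marker is removed when its missing fraction strictly exceeds
    ``max_missing``; among the survivors, when its minor-allele frequency
    (over non-missing calls) is strictly below ``min_maf``.  Both thresholds
    are strict, so ties at exactly 10% missing or MAF 0.30 are retained.
    """
    codes = geno.codes
    n = geno.n_lines
    missing_frac = np.isnan(codes).sum(axis=0) / n
    n_obs = n - np.isnan(codes).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p1 = np.nansum(codes, axis=0) / np.where(n_obs > 0, n_obs, 1)
    maf = np.minimum(p1, 1 - p1)
    maf = np.where(n_obs > 0, maf, 0.0)

    removed_rows = []
    keep = []
    for j, m in enumerate(geno.markers):
        if missing_frac[j] > max_missing:
            removed_rows.append((m, "missing_fraction", float(missing_frac[j])))
        elif maf[j] < min_maf:
            removed_rows.append((m, "maf", float(maf[j])))
        else:
            keep.append(m)
    report = QCReport(
        removed=pd.DataFrame(removed_rows, columns=["marker", "reason", "statistic"]),
        n_input=geno.n_markers,
        n_retained=len(keep),
    )
    if not keep:
        warnings.warn("all markers removed by QC filtering", stacklevel=2)
        filtered = GenotypeMatrix(
            list(geno.lines), [], np.empty((n, 0)), geno.population_type
        )
    else:
        filtered = geno.subset_markers(keep)
    return filtered, report


# ---------------------------------------------------------------------------
# Map comparison statistics


def _common(order_a: Sequence[str], order_b: Sequence[str]) -> list[str]:
    in_b = set(order_b)
    return [m for m in order_a if m in in_b]


def spearman_collinearity(order_a: Sequence[str], order_b: Sequence[str]) -> float:
    """Spearman rank correlation of two marker orders on their common markers.

    Ties (markers sharing a position would share a rank upstream) get
    mid-ranks.  Requires at least three common markers.
    """
    common = _common(order_a, order_b)
    if len(common) < 3:
        raise ValueError(f"need >=3 common markers, got {len(common)}")
    rank_b = {m: i for i, m in enumerate(order_b)}
    ra = np.arange(len(common), dtype=float)
    rb = np.array([rank_b[m] for m in common], dtype=float)
    rho, _ = stats.spearmanr(ra, rb)
    return float(rho)


def _lis_length(seq: np.ndarray) -> int:
    """Longest strictly increasing subsequence, O(n log n) patience sorting."""
    tails: list[float] = []
    for x in seq:
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if tails[mid] < x:
                lo = mid + 1
            else:
                hi = mid
        if lo == len(tails):
            tails.append(x)
        else:
            tails[lo] = x
    return len(tails)


def consistent_order_proportion(
    genetic_order: Sequence[str], physical_order: Sequence[str]
) -> float:
    """Fraction of common markers arranged consistently with the physical map.

    Computed as the longest subsequence of the genetic order that is monotone
    in physical position, divided by the number of common markers.  The map
    strand is arbitrary, so the orientation (increasing or decreasing) that
    maximizes the statistic is used.
    """
    common = _common(genetic_order, physical_order)
    if not common:
        raise ValueError("no common markers between genetic and physical orders")
    phys_rank = {m: i for i, m in enumerate(physical_order)}
    seq = np.array([phys_rank[m] for m in common], dtype=float)
    best = max(_lis_length(seq), _lis_length(-seq))
    return best / len(common)


def _bin_positions(pos: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Unique cM positions (bin positions) of one group."""
    if len(pos) == 0:
        return pos
    keep = np.concatenate([[True], np.diff(pos) > tol])
    return pos[keep]


def map_summary(gmap: GeneticMap, *, gap_threshold: float = 15.0) -> MapSummary:
    """Length, marker/bin counts, adjacent-bin distances and long gaps.

    A bin is a maximal set of markers at an identical cM position; gaps are
    distances between adjacent bins exceeding ``gap_threshold``.
    """
    rows = []
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        bins = _bin_positions(pos)
        length = float(bins[-1] - bins[0]) if len(bins) else 0.0
        bd = np.diff(bins)
        rows.append(
            {
                "chromosome": chrom,
                "length_cM": length,
                "n_markers": len(pos),
                "n_bins": len(bins),
                "mean_bin_distance_cM": float(bd.mean()) if len(bd) else 0.0,
                "max_bin_distance_cM": float(bd.max()) if len(bd) else 0.0,
                "n_gaps": int((bd > gap_threshold).sum()),
            }
        )
    per_group = pd.DataFrame(rows)
    tot_bins = int(per_group["n_bins"].sum())
    tot_len = float(per_group["length_cM"].sum())
    n_groups = len(per_group)
    total = {
        "length_cM": tot_len,
        "n_markers": int(per_group["n_markers"].sum()),
        "n_bins": tot_bins,
        "mean_bin_distance_cM": (
            tot_len / (tot_bins - n_groups) if tot_bins > n_groups else 0.0
        ),
        "max_bin_distance_cM": float(per_group["max_bin_distance_cM"].max())
        if n_groups
        else 0.0,
        "n_gaps": int(per_group["n_gaps"].sum()),
    }
    return MapSummary(per_group=per_group, total=total)
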
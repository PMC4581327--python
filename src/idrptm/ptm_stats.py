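"""Statistical core: per-400-aa densities, site-count binning, one-tailed
Pearson inference, Benjamini-Hochberg FDR, and the Rd/o enrichment ratio.

The central quantity is Rd/o = (Nd/Ld) / (No/Lo): the density of PTM sites
per disordered residue relative to their density per ordered residue, pooled
over a proteome. Rd/o = 1 means a modification shows no structural
preference; values above 1 mean enrichment in intrinsically disordered
regions.

The binning procedure groups proteins by their predicted site count (0, 1,
..., with counts at or above a cap pooled into a final ">=K" bin, K = 7 by
default), takes the mean disorder content per bin, and tests the Pearson
correlation of mean disorder against bin index with a one-tailed Student-t
transform, t = r * sqrt(n-2) / sqrt(1-r^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

DEFAULT_BIN_CAP = 7

#: The eight per-protein parameters correlated against disorder content.
PARAMETERS = (
    "phospho_S",
    "phospho_T",
    "phospho_Y",
    "ogly",
    "ngly",
    "pest",
    "ubiquitination",
    "tm_helix",
)

#: Parameters anchored to single residues; only these enter Rd/o
#: (region-type parameters — PEST, transmembrane helices — do not).
SITE_PARAMETERS = ("phospho_S", "phospho_T", "phospho_Y", "ogly", "ngly", "ubiquitination")


class NotComputable(ValueError):
    """A statistic is undefined on this input (too few bins, zero variance...)."""


# ---------------------------------------------------------------------------
# Densities


def density_per_400(count: int | float, length: int) -> float:
    """Sites per uniform 400-residue length: count * 400 / length."""
    if length <= 0:
        raise ValueError("length must be positive")
    return count * 400.0 / length


def pooled_density_per_400(counts: Sequence[float], lengths: Sequence[int]) -> float:
    """Proteome-level density: total sites * 400 / total residues.

    This is length-pooled, not the mean of per-protein densities; a
    1-site/100-aa protein plus an empty 300-aa protein pool to 1.0 per 400.
    """
    total_len = int(np.sum(lengths))
    if total_len <= 0:
        raise ValueError("total length must be positive")
    return float(np.sum(counts)) * 400.0 / total_len


def mean_density_per_400(counts: Sequence[float], lengths: Sequence[int]) -> float:
    """Alternative normalisation: mean of per-protein densities."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("lengths must be positive")
    return float(np.mean(counts * 400.0 / lengths))


# ---------------------------------------------------------------------------
# Binning and correlation


@dataclass(frozen=True)
class Bin:
    label: str  # "0", "1", ..., ">=7"
    index: int  # numeric x value used for the correlation
    n_proteins: int
    mean_disorder: float


@dataclass
class BinSeries:
    parameter: str
    bins: list[Bin]
    cap: int = DEFAULT_BIN_CAP

    @property
    def n_proteins(self) -> int:
        return sum(b.n_proteins for b in self.bins)

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([b.index for b in self.bins], dtype=float)
        y = np.array([b.mean_disorder for b in self.bins], dtype=float)
        return x, y


@dataclass
class CorrelationResult:
    r: float
    n: int
    p_one_tailed: float
    direction: str  # positive | negative
    fdr: float | None = None


def bin_by_site_count(
    counts: Sequence[int],
    disorder: Sequence[float],
    *,
    parameter: str = "?",
    cap: int = DEFAULT_BIN_CAP,
) -> BinSeries:
    """Group proteins by site count into bins 0..cap-1 plus a pooled >=cap bin.

    ``counts[i]`` and ``disorder[i]`` describe protein i. Empty bins are
    dropped, so the series may hold fewer than cap+1 points. Each retained
    bin carries the arithmetic mean of its members' disorder content.
    """
    counts = np.asarray(counts, dtype=int)
    disorder = np.asarray(disorder, dtype=float)
    if counts.shape != disorder.shape:
        raise ValueError("counts and disorder must align")
    if (counts < 0).any():
        raise ValueError("negative site counts")
    bins: list[Bin] = []
    capped = np.minimum(counts, cap)
    for idx in range(cap + 1):
        members = disorder[capped == idx]
        if members.size == 0:
            continue
        label = str(idx) if idx < cap else f">={cap}"
        bins.append(
            Bin(label=label, index=idx, n_proteins=int(members.size),
                mean_disorder=float(members.mean()))
        )
    return BinSeries(parameter=parameter, bins=bins, cap=cap)


def pearson_one_tailed(
    series: BinSeries | tuple[Sequence[float], Sequence[float]],
) -> CorrelationResult:
    """One-tailed Pearson inference over the bin series.

    x is the numeric bin index (the pooled >=K bin takes the value K), y the
    per-bin mean disorder content. The statistic is t = r*sqrt(n-2)/
    sqrt(1-r^2) against Student t with n-2 degrees of freedom; the one-tailed
    p is the upper tail at |t|, reported for the observed direction of r.
    """
    if isinstance(series, BinSeries):
        x, y = series.xy()
    else:
        x = np.asarray(series[0], dtype=float)
        y = np.asarray(series[1], dtype=float)
    n = len(x)
    if n < 3:
        raise NotComputable(f"need at least 3 bin points, got {n}")
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise NotComputable("zero variance; correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    p = one_tailed_p_from_r(r, n)
    return CorrelationResult(
        r=r, n=n, p_one_tailed=p, direction="positive" if r >= 0 else "negative"
    )


def one_tailed_p_from_r(r: float, n: int) -> float:
    """Upper-tail Student-t probability of |r| with n-2 degrees of freedom."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise NotComputable("need n >= 3")
    if abs(r) == 1.0:
        return 0.0
    t = abs(r) * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(stats.t.sf(t, n - 2))


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sort ascending, q(i) = p(i) * m / i, enforce monotonicity from the
    largest rank downwards, cap at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out.tolist()


# ---------------------------------------------------------------------------
# Rd/o


@dataclass
class RdoResult:
    """Counts behind the disordered/ordered enrichment ratio.

    Nd, No: PTM sites anchored on disordered / ordered residues.
    Ld, Lo: pooled disordered / ordered residue counts.
    rdo = (Nd/Ld)/(No/Lo); inf when No = 0 with Nd > 0, nan when undefined.
    """

    nd: int
    ld: int
    no: int
    lo: int

    @property
    def rdo(self) -> float:
        if self.ld == 0 or self.lo == 0:
            return math.nan
        if self.no == 0:
            return math.inf if self.nd > 0 else math.nan
        return (self.nd / self.ld) / (self.no / self.lo)

    def __add__(self, other: "RdoResult") -> "RdoResult":
        return RdoResult(
            nd=self.nd + other.nd, ld=self.ld + other.ld,
            no=self.no + other.no, lo=self.lo + other.lo,
        )


def rdo_from_counts(nd: int, ld: int, no: int, lo: int) -> RdoResult:
    for name, v in (("nd", nd), ("ld", ld), ("no", no), ("lo", lo)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    return RdoResult(nd=nd, ld=ld, no=no, lo=lo)


def rdo(
    site_positions: Mapping[str, Sequence[int]],
    masks: Mapping[str, np.ndarray],
) -> RdoResult:
    """Rd/o over a proteome from site anchors and per-residue disorder masks.

    ``site_positions`` maps protein_id -> 1-based anchor positions of counted
    sites; ``masks`` maps protein_id -> 0/1 disorder vectors. Every protein
    with a mask contributes its residues to Ld/Lo whether or not it has
    sites; every anchor must index into its protein's mask.
    """
    nd = no = ld = lo = 0
    for pid, mask in masks.items():
        mask = np.asarray(mask)
        d = int(mask.sum())
        ld += d
        lo += len(mask) - d
        for pos in site_positions.get(pid, ()):
            if not 1 <= pos <= len(mask):
                raise ValueError(f"{pid}: site position {pos} outside mask")
            if mask[pos - 1]:
                nd += 1
            else:
                no += 1
    unknown = set(site_positions) - set(masks)
    if unknown:
        raise ValueError(f"sites for proteins without masks: {sorted(unknown)[:3]}")
    return RdoResult(nd=nd, ld=ld, no=no, lo=lo)


def group_aggregate(
    per_species: Mapping[str, RdoResult],
    grouping: Mapping[str, str],
    *,
    total_label: str = "Total",
) -> dict[str, RdoResult]:
    """Pool species-level Rd/o components into group-level and total results.

    Pooling adds Nd, Ld, No, Lo across the group's proteomes and recomputes
    the ratio — it is NOT the mean of per-species ratios.
    """
    if not per_species:
        raise ValueError("no species results to aggregate")
    missing = set(per_species) - set(grouping)
    if missing:
        raise ValueError(f"species without a group: {sorted(missing)}")
    out: dict[str, RdoResult] = {}
    for species, result in per_species.items():
        group = grouping[species]
        out[group] = out[group] + result if group in out else result
        out[total_label] = out[total_label] + result if total_label in out else result
    return out
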
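"""Redundancy clustering and the species-specific / common cluster contrast.

Protein clusters serve two purposes in the analysis: removing near-duplicate
sequences before any statistics (representatives of clusters built at 90%
identity / 90% match length), and classifying proteins as species-specific
(cluster confined to one species) versus common (cluster covering the whole
species panel) for the conservation contrast.

Clustering here is deliberately simple and exact: pairwise global alignment
(match +1, mismatch 0, gap -1 by default), an edge whenever both the percent
identity and the percent match-length thresholds are met, and connected
components as clusters. The partition — not the clustering engine — is what
the downstream analysis consumes, and external cluster assignments (e.g.
genuine ortholog groups) can be loaded from TSV instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import networkx as nx
import numpy as np
from Bio import Align
from scipy import stats

from .proteome import ProteinRecord

CATEGORIES = ("specific", "common", "intermediate")


@dataclass
class IdentityParams:
    """Thresholds and scoring for the identity graph.

    pi_cutoff: minimum percent identity over aligned residue pairs.
    pmatch_cutoff: minimum percent of the shorter sequence covered by
    aligned residue pairs.
    """

    pi_cutoff: float = 90.0
    pmatch_cutoff: float = 90.0
    match_score: float = 1.0
    mismatch_score: float = 0.0
    # affine gaps: a cheap linear gap (open = extend) lets the optimal
    # alignment scatter a short sequence's residues across a long one,
    # manufacturing ~100% identity between unrelated proteins of very
    # different lengths; a distinct opening cost keeps alignments contiguous
    open_gap_score: float = -5.0
    extend_gap_score: float = -1.0

    def __post_init__(self) -> None:
        for v in (self.pi_cutoff, self.pmatch_cutoff):
            if not 0 < v <= 100:
                raise ValueError("cutoffs must be in (0, 100]")


@dataclass
class ClusterAssignment:
    cluster_id: str
    members: set[tuple[str, str]]  # (species_id, protein_id)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")

    @property
    def species_set(self) -> set[str]:
        return {sp for sp, _ in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterCatalog:
    """A partition of proteins into clusters (singletons included)."""

    clusters: list[ClusterAssignment] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for cl in self.clusters:
            overlap = seen & cl.members
            if overlap:
                raise ValueError(f"proteins in more than one cluster: {overlap}")
            seen |= cl.members
        self._member_index = {m: cl.cluster_id for cl in self.clusters for m in cl.members}

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    @property
    def members(self) -> set[tuple[str, str]]:
        return set(self._member_index)

    def cluster_of(self, species_id: str, protein_id: str) -> str:
        return self._member_index[(species_id, protein_id)]


def _aligner(params: IdentityParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    aligner.open_gap_score = params.open_gap_score
    aligner.extend_gap_score = params.extend_gap_score
    return aligner


def global_identity(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    params: IdentityParams | None = None,
) -> tuple[float, float]:
    """(pi, pmatch) of two sequences under exact global alignment.

    pi = identical aligned residue pairs / aligned residue pairs x 100;
    pmatch = aligned residue pairs / length of the shorter sequence x 100.
    Symmetric in its arguments (the pair is canonically ordered before
    aligning so co-optimal alignments cannot break symmetry).
    """
    params = params or IdentityParams()
    sa = a.sequence if isinstance(a, ProteinRecord) else a
    sb = b.sequence if isinstance(b, ProteinRecord) else b
    if not sa or not sb:
        raise ValueError("sequences must be non-empty")
    if sb < sa:
        sa, sb = sb, sa
    alignment = _aligner(params).align(sa, sb)[0]
    identities = 0
    matched_cols = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        matched_cols += a1 - a0
        identities += sum(
            1 for x, y in zip(sa[a0:a1], sb[b0:b1]) if x == y
        )
    pi = 100.0 * identities / matched_cols if matched_cols else 0.0
    pmatch = 100.0 * matched_cols / min(len(sa), len(sb))
    return pi, pmatch


def _edit_distance_prefilter(sa: str, sb: str, params: IdentityParams) -> bool:
    """Cheap, rigorous screen: can this pair possibly meet both thresholds?

    An edge needs an alignment with identities >= (pi/100)*(pmatch/100) *
    min_len. In any alignment of sequences of lengths la, lb the number of
    identical pairs is at most (la + lb - d) / 2 where d is the unit-cost
    edit distance, so pairs with d > la + lb - 2*required can be discarded
    without alignment.
    """
    la, lb = len(sa), len(sb)
    required = (params.pi_cutoff / 100.0) * (params.pmatch_cutoff / 100.0) * min(la, lb)
    k = la + lb - 2 * required
    if k < 0:
        return False
    res = edlib.align(sa, sb, mode="NW", task="distance", k=int(math.floor(k)))
    return res["editDistance"] != -1


def build_clusters(
    records: Sequence[ProteinRecord], params: IdentityParams | None = None
) -> ClusterCatalog:
    """Single-linkage clusters over the pi/pmatch threshold graph.

    An edge joins two proteins iff pi >= pi_cutoff and pmatch >=
    pmatch_cutoff; clusters are connected components, so similarity is
    transitively closed. Every record lands in exactly one cluster;
    unconnected records form singletons. Identical sequences are joined by a
    hash shortcut without alignment.
    """
    if not records:
        raise ValueError("no records to cluster")
    params = params or IdentityParams()
    keys = [(r.species_id, r.protein_id) for r in records]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (species_id, protein_id) among records")
    graph = nx.Graph()
    graph.add_nodes_from(keys)
    # exact-duplicate shortcut: identical sequences always satisfy 100/100
    by_seq: dict[str, list[int]] = {}
    for idx, rec in enumerate(records):
        by_seq.setdefault(rec.sequence, []).append(idx)
    rep_of_seq = {seq: idxs[0] for seq, idxs in by_seq.items()}
    for seq, idxs in by_seq.items():
        for other in idxs[1:]:
            graph.add_edge(keys[idxs[0]], keys[other])
    uniques = sorted(rep_of_seq.values())
    for ia, ib in itertools.combinations(uniques, 2):
        sa, sb = records[ia].sequence, records[ib].sequence
        if not _edit_distance_prefilter(sa, sb, params):
            continue
        pi, pmatch = global_identity(sa, sb, params)
        if pi >= params.pi_cutoff and pmatch >= params.pmatch_cutoff:
            graph.add_edge(keys[ia], keys[ib])
    clusters = [
        ClusterAssignment(cluster_id=f"c{i:05d}", members=set(component))
        for i, component in enumerate(
            sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
        )
    ]
    return ClusterCatalog(clusters=clusters)


def select_representatives(
    catalog: ClusterCatalog, records: Sequence[ProteinRecord]
) -> list[ProteinRecord]:
    """One representative per cluster: the longest member, ties broken by
    lexicographically smallest protein_id. Output follows catalog order."""
    index = {(r.species_id, r.protein_id): r for r in records}
    missing = catalog.members - set(index)
    if missing:
        raise ValueError(f"catalog members without records: {sorted(missing)[:3]}")
    reps = []
    for cluster in catalog:
        members = [index[m] for m in cluster.members]
        members.sort(key=lambda r: (-len(r), r.protein_id))
        reps.append(members[0])
    return reps


def redundancy_content(n_before: int, n_after: int) -> float:
    """Fraction of sequences removed by redundancy filtering."""
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    if not 0 <= n_after <= n_before:
        raise ValueError("need 0 <= n_after <= n_before")
    return (n_before - n_after) / n_before


def classify_clusters(
    catalog: ClusterCatalog, panel: Iterable[str]
) -> dict[str, str]:
    """Map cluster_id -> specific | common | intermediate.

    A cluster confined to a single species (including singletons) is
    species-specific; a cluster covering every species of the panel is
    common; anything in between is intermediate and excluded from the
    specific/common contrast.
    """
    panel_set = set(panel)
    out: dict[str, str] = {}
    for cluster in catalog:
        sp = cluster.species_set
        if not sp <= panel_set:
            raise ValueError(
                f"cluster {cluster.cluster_id} has species outside the panel: {sp - panel_set}"
            )
        if len(sp) == 1:
            out[cluster.cluster_id] = "specific"
        elif sp == panel_set:
            out[cluster.cluster_id] = "common"
        else:
            out[cluster.cluster_id] = "intermediate"
    return out


def category_counts(categories: Mapping[str, str]) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for cat in categories.values():
        counts[cat] += 1
    return counts


@dataclass
class ContrastResult:
    mean_specific: float
    mean_common: float
    ratio_s_over_c: float
    p_one_tailed: float
    n_specific: int
    n_common: int
    method: str


def category_contrast(
    specific_values: Sequence[float],
    common_values: Sequence[float],
    *,
    method: str = "welch",
    n_permutations: int = 20000,
    rng: np.random.Generator | None = None,
) -> ContrastResult:
    """Specific-vs-common location contrast.

    ratio = mean(specific) / mean(common); the one-tailed p tests the
    direction specific > common, by default with Welch's unequal-variance
    two-sample t-test. ``method='permutation'`` uses a label-permutation
    test of the mean difference instead (exhaustive when fewer than
    ``n_permutations`` distinct label assignments exist).
    """
    xs = np.asarray(specific_values, dtype=float)
    xc = np.asarray(common_values, dtype=float)
    if len(xs) == 0 or len(xc) == 0:
        raise ValueError("both categories must be non-empty")
    mean_s, mean_c = float(xs.mean()), float(xc.mean())
    if mean_c == 0:
        raise ZeroDivisionError("mean of common category is zero; ratio undefined")
    if method == "welch":
        res = stats.ttest_ind(xs, xc, equal_var=False, alternative="greater")
        p = float(res.pvalue)
    elif method == "permutation":
        res = stats.permutation_test(
            (xs, xc),
            lambda a, b, axis=-1: np.mean(a, axis=axis) - np.mean(b, axis=axis),
            alternative="greater",
            n_resamples=n_permutations,
            vectorized=True,
            rng=rng if rng is not None else np.random.default_rng(0),
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ContrastResult(
        mean_specific=mean_s,
        mean_common=mean_c,
        ratio_s_over_c=mean_s / mean_c,
        p_one_tailed=p,
        n_specific=len(xs),
        n_common=len(xc),
        method=method,
    )


# ---------------------------------------------------------------------------
# Catalog I/O


def write_cluster_table(catalog: ClusterCatalog, path: str | Path) -> None:
    """One row per member: cluster_id, species_id, protein_id."""
    with open(path, "w") as out:
        out.write("cluster_id\tspecies_id\tprotein_id\n")
        for cluster in catalog:
            for sp, pid in sorted(cluster.members):
                out.write(f"{cluster.cluster_id}\t{sp}\t{pid}\n")


def read_cluster_table(path: str | Path) -> ClusterCatalog:
    """Load an external cluster assignment (e.g. genuine ortholog groups)."""
    groups: dict[str, set[tuple[str, str]]] = {}
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["cluster_id", "species_id", "protein_id"]:
            raise ValueError(f"unexpected cluster table header: {header}")
        for line in handle:
            cid, sp, pid = line.rstrip("\n").split("\t")
            groups.setdefault(cid, set()).add((sp, pid))
    clusters = [
        ClusterAssignment(cluster_id=cid, members=members)
        for cid, members in sorted(groups.items())
    ]
    return ClusterCatalog(clusters=clusters)


def write_category_table(
    catalog: ClusterCatalog, categories: Mapping[str, str], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("cluster_id\tn_members\tn_species\tcategory\n")
        for cluster in catalog:
            out.write(
                f"{cluster.cluster_id}\t{len(cluster)}\t{len(cluster.species_set)}\t"
                f"{categories[cluster.cluster_id]}\n"
            )
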
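"""Per-residue disorder masks and externally predicted sites/segments.

This module is the join point between sequences and predictions made by
external tools: per-residue disorder calls (DISOPRED/RONN role), site
predictions (phosphorylation in the Musite role, ubiquitination with scores
in the UbPred role, N-glycosylation in the NetNGlyc role) and segment
predictions (signal peptides in the SignalP role, transmembrane helices in
the TMHMM role). Nothing here re-implements those predictors — annotation
tables are consumed, validated against the sequences, and carried through
the statistics.

All coordinates are 1-based inclusive, matching the residue numbering the
upstream predictors report. Converters to 0-based half-open exist only at
internal boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .proteome import ProteinRecord, Proteome

logger = logging.getLogger(__name__)

SITE_TYPES = ("phospho_S", "phospho_T", "phospho_Y", "ubiquitination", "ngly_external")
SEGMENT_TYPES = ("tm_helix", "signal_peptide", "pest_external")
MASK_SOURCES = ("disopred", "ronn", "synthetic", "other")

#: Residue each site type must sit on (X never qualifies).
SITE_RESIDUE = {
    "phospho_S": "S",
    "phospho_T": "T",
    "phospho_Y": "Y",
    "ubiquitination": "K",
    "ngly_external": "N",
}

# UbPred medium-confidence band, both ends inclusive.
UBIQUITIN_SCORE_LOW = 0.69
UBIQUITIN_SCORE_HIGH = 0.84


class AnnotationError(ValueError):
    """An annotation row contradicts the sequence it annotates."""


@dataclass
class DisorderMask:
    """Binary per-residue disorder call; 1 = disordered."""

    protein_id: str
    mask: np.ndarray  # uint8 vector, one entry per residue
    source: str = "other"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.ndim != 1 or len(self.mask) == 0:
            raise ValueError("mask must be a non-empty 1-D vector")
        if self.source not in MASK_SOURCES:
            raise ValueError(f"unknown mask source {self.source!r}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")

    def __len__(self) -> int:
        return len(self.mask)


@dataclass(frozen=True)
class SiteAnnotation:
    protein_id: str
    site_type: str
    position: int  # 1-based
    score: float | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based; got %d" % self.position)


@dataclass(frozen=True)
class SegmentAnnotation:
    protein_id: str
    segment_type: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.segment_type not in SEGMENT_TYPES:
            raise ValueError(f"unknown segment_type {self.segment_type!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment interval ({self.start}, {self.end})")


@dataclass
class AnnotatedProtein:
    """A sequence joined with its disorder mask, sites, and segments."""

    record: ProteinRecord
    mask: DisorderMask
    sites: list[SiteAnnotation] = field(default_factory=list)
    segments: list[SegmentAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.record)
        if len(self.mask) != n:
            raise AnnotationError(
                f"{self.record.protein_id}: mask length {len(self.mask)} != sequence length {n}"
            )
        for site in self.sites:
            _check_site(site, self.record.sequence)
        tm = []
        for seg in self.segments:
            if seg.end > n:
                raise AnnotationError(
                    f"{seg.protein_id}: segment end {seg.end} beyond length {n}"
                )
            if seg.segment_type == "tm_helix":
                tm.append((seg.start, seg.end))
        tm.sort()
        for (s1, e1), (s2, e2) in zip(tm, tm[1:]):
            if s2 <= e1:
                raise AnnotationError(
                    f"{self.record.protein_id}: overlapping tm_helix segments"
                )

    def site_count(self, site_type: str) -> int:
        return sum(1 for s in self.sites if s.site_type == site_type)

    def segment_count(self, segment_type: str) -> int:
        return sum(1 for s in self.segments if s.segment_type == segment_type)

    @property
    def disorder_content(self) -> float:
        return disorder_content(self.mask)


def _check_site(site: SiteAnnotation, sequence: str) -> None:
    if site.position > len(sequence):
        raise AnnotationError(
            f"{site.protein_id}: position {site.position} beyond length {len(sequence)}"
        )
    expected = SITE_RESIDUE[site.site_type]
    actual = sequence[site.position - 1]
    if actual != expected:
        raise AnnotationError(
            f"{site.protein_id}: {site.site_type} at position {site.position} "
            f"sits on {actual!r}, expected {expected!r}"
        )


# ---------------------------------------------------------------------------
# Table I/O


@dataclass
class LoadReport:
    """What a lenient load kept and what it rejected."""

    n_loaded: int
    n_rejected: int
    reasons: list[str] = field(default_factory=list)


def load_site_table(
    path: str | Path, proteome: Proteome, *, strict: bool = True
) -> tuple[list[SiteAnnotation], LoadReport]:
    """Load a TSV of predicted sites (protein_id, site_type, position, score).

    In strict mode any invalid row (unknown protein, out-of-bounds position,
    residue-type mismatch) aborts the load; in lenient mode such rows are
    skipped and counted in the returned report.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "site_type", "position"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"site table missing columns {required - set(df.columns)}")
    seqs = {rec.protein_id: rec.sequence for rec in proteome}
    sites: list[SiteAnnotation] = []
    report = LoadReport(0, 0)
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        if score is not None and pd.isna(score):
            score = None
        try:
            site = SiteAnnotation(
                protein_id=row.protein_id,
                site_type=row.site_type,
                position=int(row.position),
                score=None if score is None else float(score),
            )
            if site.protein_id not in seqs:
                raise AnnotationError(f"unknown protein_id {site.protein_id!r}")
            _check_site(site, seqs[site.protein_id])
        except (ValueError, AnnotationError) as exc:
            if strict:
                raise AnnotationError(str(exc)) from exc
            report.n_rejected += 1
            report.reasons.append(str(exc))
            continue
        sites.append(site)
        report.n_loaded += 1
    if report.n_rejected:
        logger.warning("site table %s: %d row(s) rejected", path, report.n_rejected)
    return sites, report


def write_site_table(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    rows = sorted(sites, key=lambda s: (s.protein_id, s.position, s.site_type))
    with open(path, "w") as out:
        out.write("protein_id\tsite_type\tposition\tscore\n")
        for s in rows:
            score = "" if s.score is None else f"{s.score:g}"
            out.write(f"{s.protein_id}\t{s.site_type}\t{s.position}\t{score}\n")


def load_segment_table(
    path: str | Path, proteome: Proteome, *, strict: bool = True
) -> tuple[list[SegmentAnnotation], LoadReport]:
    """Load a TSV of predicted segments (protein_id, segment_type, start, end)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    lengths = {rec.protein_id: len(rec) for rec in proteome}
    segments: list[SegmentAnnotation] = []
    report = LoadReport(0, 0)
    for row in df.itertuples(index=False):
        try:
            seg = SegmentAnnotation(
                protein_id=row.protein_id,
                segment_type=row.segment_type,
                start=int(row.start),
                end=int(row.end),
            )
            if seg.protein_id not in lengths:
                raise AnnotationError(f"unknown protein_id {seg.protein_id!r}")
            if seg.end > lengths[seg.protein_id]:
                raise AnnotationError(
                    f"{seg.protein_id}: segment end {seg.end} beyond sequence"
                )
        except (ValueError, AnnotationError) as exc:
            if strict:
                raise AnnotationError(str(exc)) from exc
            report.n_rejected += 1
            report.reasons.append(str(exc))
            continue
        segments.append(seg)
        report.n_loaded += 1
    return segments, report


def write_segment_table(segments: Iterable[SegmentAnnotation], path: str | Path) -> None:
    rows = sorted(segments, key=lambda s: (s.protein_id, s.start, s.segment_type))
    with open(path, "w") as out:
        out.write("protein_id\tsegment_type\tstart\tend\n")
        for s in rows:
            out.write(f"{s.protein_id}\t{s.segment_type}\t{s.start}\t{s.end}\n")


def load_mask_table(
    path: str | Path, proteome: Proteome, *, source: str = "other", strict: bool = True
) -> dict[str, DisorderMask]:
    """Load disorder masks from TSV.

    Two dialects are accepted and normalised at load:

    * compact — columns ``protein_id``, ``mask`` where mask is a 0/1 string,
      one character per residue;
    * long — columns ``protein_id``, ``position``, ``state`` with one row per
      residue, state one of {0, 1, '.', '*', 'O', 'D'} ('*'/'D'/1 mean
      disordered), the dialect per-residue disorder listings export to.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    lengths = {rec.protein_id: len(rec) for rec in proteome}
    masks: dict[str, DisorderMask] = {}
    if "mask" in df.columns:
        for row in df.itertuples(index=False):
            vec = np.frombuffer(row.mask.encode(), dtype=np.uint8) - ord("0")
            masks[row.protein_id] = DisorderMask(row.protein_id, vec, source=source)
    elif {"position", "state"}.issubset(df.columns):
        disordered_states = {"1", "*", "D"}
        for pid, sub in df.groupby("protein_id", sort=False):
            if pid not in lengths:
                if strict:
                    raise AnnotationError(f"unknown protein_id {pid!r} in mask table")
                continue
            vec = np.zeros(lengths[pid], dtype=np.uint8)
            pos = sub["position"].astype(int).to_numpy()
            if pos.min() < 1 or pos.max() > lengths[pid]:
                raise AnnotationError(f"{pid}: mask positions out of bounds")
            state = sub["state"].astype(str).str.strip().isin(disordered_states)
            vec[pos - 1] = state.to_numpy().astype(np.uint8)
            masks[pid] = DisorderMask(pid, vec, source=source)
    else:
        raise AnnotationError("mask table needs either a 'mask' or 'position'/'state' columns")
    for pid, mask in masks.items():
        if pid in lengths and len(mask) != lengths[pid]:
            raise AnnotationError(
                f"{pid}: mask length {len(mask)} != sequence length {lengths[pid]}"
            )
        if pid not in lengths and strict:
            raise AnnotationError(f"unknown protein_id {pid!r} in mask table")
    return masks


def write_mask_table(masks: Iterable[DisorderMask], path: str | Path) -> None:
    rows = sorted(masks, key=lambda m: m.protein_id)
    with open(path, "w") as out:
        out.write("protein_id\tmask\n")
        for m in rows:
            out.write(f"{m.protein_id}\t{''.join(map(str, m.mask.tolist()))}\n")


# ---------------------------------------------------------------------------
# Derived quantities


def filter_ubiquitination(
    sites: Sequence[SiteAnnotation],
    low: float = UBIQUITIN_SCORE_LOW,
    high: float = UBIQUITIN_SCORE_HIGH,
    *,
    strict: bool = True,
) -> list[SiteAnnotation]:
    """Keep ubiquitination sites in the medium-confidence band [low, high].

    Both band ends are inclusive. Non-ubiquitination sites pass through
    untouched. A ubiquitination site without a score is an error in strict
    mode and is dropped otherwise.
    """
    kept: list[SiteAnnotation] = []
    for site in sites:
        if site.site_type != "ubiquitination":
            kept.append(site)
            continue
        if site.score is None:
            if strict:
                raise AnnotationError(
                    f"{site.protein_id}: ubiquitination site at {site.position} has no score"
                )
            continue
        if low <= site.score <= high:
            kept.append(site)
    return kept


def disorder_content(mask: DisorderMask) -> float:
    """Fraction of residues called disordered: disordered residues / length."""
    return float(mask.mask.sum()) / len(mask)


def split_residues(mask: DisorderMask) -> tuple[int, int]:
    """(Ld, Lo): disordered and ordered residue counts; Ld + Lo = length."""
    ld = int(mask.mask.sum())
    return ld, len(mask) - ld


def iter_annotated(
    proteome: Proteome,
    masks: dict[str, DisorderMask],
    sites: Sequence[SiteAnnotation] = (),
    segments: Sequence[SegmentAnnotation] = (),
) -> Iterator[AnnotatedProtein]:
    """Join a proteome with its masks/sites/segments into AnnotatedProteins.

    Every record must have a mask; sites and segments are optional per
    protein.
    """
    by_prot_sites: dict[str, list[SiteAnnotation]] = {}
    for s in sites:
        by_prot_sites.setdefault(s.protein_id, []).append(s)
    by_prot_segs: dict[str, list[SegmentAnnotation]] = {}
    for s in segments:
        by_prot_segs.setdefault(s.protein_id, []).append(s)
    for rec in proteome:
        if rec.protein_id not in masks:
            raise AnnotationError(f"no disorder mask for {rec.protein_id!r}")
        yield AnnotatedProtein(
            record=rec,
            mask=masks[rec.protein_id],
            sites=by_prot_sites.get(rec.protein_id, []),
            segments=by_prot_segs.get(rec.protein_id, []),
        )
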
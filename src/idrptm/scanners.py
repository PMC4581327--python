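"""Sequence-defined feature scanners.

Three predictors are defined purely by the sequence, so they are implemented
here rather than consumed as external annotation tables:

* the plant hydroxyproline O-glycosylation consensus
  ``[A/S/T/V]-P(1,4)-X(0,10)-[A/S/T/V]-P(1,4)``;
* the N-glycosylation sequon ``N-X-S/T`` (X any residue except proline),
  combined with a secretory-pathway gate (signal peptide or membrane
  anchoring) since N-glycosylation happens in the ER lumen;
* PEST regions: stretches of >= 12 residues between positively charged
  flanks, enriched in P, E/D, S/T, scored with the classic PEST-find score
  (corrected DEPST mass percent against a Kyte-Doolittle-derived
  hydrophobicity index) and reported above a +5 threshold.

Coordinates in all returned matches are 1-based inclusive. The residue X
never satisfies a literal residue class; it may only occupy the wildcard
spacer of the O-glycosylation consensus or pad a PEST region.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

OGLY_FIRST = frozenset("ASTV")  # residue class opening each half of the motif
OGLY_MAX_P = 4
OGLY_MAX_SPACER = 10

POSITIVE_FLANKS = frozenset("KRH")
PEST_MIN_LEN = 12
PEST_THRESHOLD = 5.0

#: Average residue masses (Da, monomer minus water), standard values.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
RESIDUE_MASS["X"] = sum(RESIDUE_MASS.values()) / 20.0  # unknown residue: mean mass

#: Kyte-Doolittle hydropathy linearly transformed to 0..90 (10*KD + 45).
LTKDHI = {
    "I": 90.0, "V": 87.0, "L": 83.0, "F": 73.0, "C": 70.0, "M": 64.0, "A": 63.0,
    "G": 41.0, "T": 38.0, "S": 37.0, "W": 36.0, "Y": 32.0, "P": 29.0, "H": 13.0,
    "E": 10.0, "Q": 10.0, "D": 10.0, "N": 10.0, "K": 6.0, "R": 0.0,
    "X": 45.0,  # KD 0 for unknown residues
}


@dataclass(frozen=True)
class MotifMatch:
    """A scanner hit. start/end/anchor are 1-based inclusive residue indices.

    The anchor is the modified residue: the sequon's N, the first P of an
    O-glycosylation match, or the first residue of a PEST region.
    """

    protein_id: str
    kind: str  # ogly | ngly_sequon | pest
    start: int
    end: int
    anchor: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.anchor <= self.end):
            raise ValueError(f"inconsistent match coordinates {self}")


@dataclass
class SecretoryContext:
    """Signal-peptide / transmembrane evidence for one protein.

    ``signal_end`` is the last residue of the predicted signal peptide
    (used to exclude sequons that are cleaved off before maturity); when the
    annotation does not state it, a conventional 20 residues is assumed.
    """

    has_signal_peptide: bool = False
    tm_segments: Sequence[tuple[int, int]] = ()
    signal_end: int = 20

    def __post_init__(self) -> None:
        segs = sorted(tuple(s) for s in self.tm_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError("tm_segments must be non-overlapping")
        self.tm_segments = segs


# ---------------------------------------------------------------------------
# O-glycosylation consensus


def _p_run(seq: str, i: int) -> int:
    """Length of the literal-P run starting at 0-based i (X breaks the run)."""
    n = 0
    while i + n < len(seq) and seq[i + n] == "P" and n < OGLY_MAX_P:
        n += 1
    return n


def _ogly_match_at(seq: str, i: int) -> tuple[int, int] | None:
    """Best motif instantiation anchored at 0-based offset i, or None.

    Among all valid (p1, spacer, p2) arity combinations the canonical choice
    is the earliest motif end; ties are broken toward longer P runs so the
    match absorbs whole proline blocks. Returns (end_exclusive, p1_len).
    """
    if seq[i] not in OGLY_FIRST:
        return None
    max_p1 = _p_run(seq, i + 1)
    if max_p1 == 0:
        return None
    best: tuple[int, int] | None = None  # (end_exclusive, -p1)
    for p1 in range(1, max_p1 + 1):
        spacer_start = i + 1 + p1
        for x in range(0, OGLY_MAX_SPACER + 1):
            j = spacer_start + x  # second [ASTV]
            if j >= len(seq) or seq[j] not in OGLY_FIRST:
                continue
            p2 = _p_run(seq, j + 1)
            if p2 == 0:
                continue
            end = j + 1 + p2  # greedy-longest second P run
            if best is None or (end, -p1) < best:
                best = (end, -p1)
    if best is None:
        return None
    return best[0], -best[1]


def scan_ogly(
    sequence: str, *, protein_id: str = "?", allow_overlaps: bool = False
) -> list[MotifMatch]:
    """Scan for the plant O-glycosylation consensus.

    Default policy: leftmost, non-overlapping occurrences; at each start the
    canonical instantiation ends as early as possible (so tandem repeats such
    as APAPAPAP yield two four-residue sites, not one spanning site), while
    each P element absorbs its whole run up to four prolines. With
    ``allow_overlaps`` every start position with a valid instantiation is
    reported. Each occurrence counts as one site; the anchor is its first P.
    """
    matches: list[MotifMatch] = []
    i = 0
    n = len(sequence)
    while i < n:
        hit = _ogly_match_at(sequence, i)
        if hit is None:
            i += 1
            continue
        end_excl, _p1 = hit
        matches.append(
            MotifMatch(
                protein_id=protein_id,
                kind="ogly",
                start=i + 1,
                end=end_excl,
                anchor=i + 2,
            )
        )
        i = i + 1 if allow_overlaps else end_excl
    return matches


# ---------------------------------------------------------------------------
# N-glycosylation sequons


def scan_ngly_sequons(sequence: str, *, protein_id: str = "?") -> list[MotifMatch]:
    """All N-X-S/T sequons (X != P); overlapping sequons are all reported."""
    out: list[MotifMatch] = []
    for i in range(len(sequence) - 2):
        if (
            sequence[i] == "N"
            and sequence[i + 1] != "P"
            and sequence[i + 2] in "ST"
        ):
            out.append(
                MotifMatch(
                    protein_id=protein_id,
                    kind="ngly_sequon",
                    start=i + 1,
                    end=i + 3,
                    anchor=i + 1,
                )
            )
    return out


def combine_ngly(
    sequons: Sequence[MotifMatch],
    context: SecretoryContext,
    *,
    gate: str = "signal_or_tm",
    exclude_signal_region: bool = True,
) -> list[MotifMatch]:
    """Count sequons that can plausibly be N-glycosylated.

    A protein enters the secretory pathway if it has a signal peptide or at
    least one transmembrane helix (``gate='signal_or_tm'``, the default) or
    only via a signal peptide (``gate='signal_only'``). Within an admitted
    protein, sequons whose N sits inside a transmembrane helix are excluded
    (buried in the bilayer), as are sequons within the signal peptide itself
    when ``exclude_signal_region`` (cleaved before maturation). Order is
    preserved; the output is always a subset of the input.
    """
    if gate not in ("signal_or_tm", "signal_only"):
        raise ValueError(f"unknown gate {gate!r}")
    admitted = context.has_signal_peptide or (
        gate == "signal_or_tm" and len(context.tm_segments) > 0
    )
    if not admitted:
        return []
    counted: list[MotifMatch] = []
    for sq in sequons:
        if any(s <= sq.anchor <= e for s, e in context.tm_segments):
            continue
        if (
            exclude_signal_region
            and context.has_signal_peptide
            and sq.anchor <= context.signal_end
        ):
            continue
        counted.append(sq)
    return counted


# ---------------------------------------------------------------------------
# PEST regions


def pest_score(segment: str) -> float:
    """Classic PEST-find score of a candidate region.

    score = 0.55 * DEPST - 0.5 * hydrophobicity_index, where DEPST is the
    mass percent of D/E/P/S/T in the segment corrected by one equivalent of
    each class (one D-or-E, one P, one S-or-T; the lightest member present is
    subtracted), and the hydrophobicity index is the mole-fraction-weighted
    mean of the rescaled Kyte-Doolittle hydropathy (10*KD + 45, range 0..90).
    Positive scores above +5 mark possible PEST regions.
    """
    if not segment:
        raise ValueError("empty segment")
    total_mass = sum(RESIDUE_MASS[c] for c in segment)
    depst_mass = sum(RESIDUE_MASS[c] for c in segment if c in "DEPST")
    for cls in ("DE", "P", "ST"):
        present = [RESIDUE_MASS[c] for c in cls if c in segment]
        if present:
            depst_mass -= min(present)
    depst_pct = 100.0 * max(depst_mass, 0.0) / total_mass
    hydro = sum(LTKDHI[c] for c in segment) / len(segment)
    return 0.55 * depst_pct - 0.5 * hydro


def _candidate_regions(sequence: str) -> list[tuple[int, int]]:
    """0-based half-open stretches between positive flanks (K/R/H).

    Sequence termini act as flanks in addition to K/R/H residues.
    """
    flanks = [i for i, c in enumerate(sequence) if c in POSITIVE_FLANKS]
    bounds = [-1] + flanks + [len(sequence)]
    regions = []
    for a, b in zip(bounds, bounds[1:]):
        start, end = a + 1, b
        if end - start >= PEST_MIN_LEN:
            regions.append((start, end))
    return regions


def scan_pest(
    sequence: str, threshold: float = PEST_THRESHOLD, *, protein_id: str = "?"
) -> list[MotifMatch]:
    """Find possible PEST regions.

    Candidate regions are maximal stretches of >= 12 residues between
    positively charged flanks (K, R, H; the sequence termini also act as
    flanks) that contain at least one P, one of D/E and one of S/T. Each
    candidate is scored with :func:`pest_score`; regions scoring strictly
    above ``threshold`` are returned.
    """
    out: list[MotifMatch] = []
    for start, end in _candidate_regions(sequence):
        seg = sequence[start:end]
        if not (
            "P" in seg
            and any(c in seg for c in "DE")
            and any(c in seg for c in "ST")
        ):
            continue
        score = pest_score(seg)
        if score > threshold:
            out.append(
                MotifMatch(
                    protein_id=protein_id,
                    kind="pest",
                    start=start + 1,
                    end=end,
                    anchor=start + 1,
                    score=round(score, 4),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Match table I/O


def write_match_table(matches: Iterable[MotifMatch], path: str | Path) -> None:
    """TSV with fixed column order: protein_id, kind, start, end, anchor, score."""
    with open(path, "w") as out:
        out.write("protein_id\tkind\tstart\tend\tanchor\tscore\n")
        for m in matches:
            score = "" if m.score is None else f"{m.score:g}"
            out.write(f"{m.protein_id}\t{m.kind}\t{m.start}\t{m.end}\t{m.anchor}\t{score}\n")
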
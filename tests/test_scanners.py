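"""Motif scanners versus exhaustive independent oracles."""

import itertools

import numpy as np
import pytest

from idrptm.scanners import (
    LTKDHI,
    RESIDUE_MASS,
    MotifMatch,
    SecretoryContext,
    combine_ngly,
    pest_score,
    scan_ngly_sequons,
    scan_ogly,
    scan_pest,
)

# ---------------------------------------------------------------------------
# Oracles: brute-force re-statements of the scanning rules, kept free of the
# implementation's data structures.


def ogly_instantiations_at(seq: str, s: int):
    """All (end_exclusive, p1) for a valid motif starting at 0-based s."""
    hits = []
    if s >= len(seq) or seq[s] not in "ASTV":
        return hits
    for p1, x, p2 in itertools.product(range(1, 5), range(0, 11), range(1, 5)):
        a2 = s + 1 + p1 + x
        end = a2 + 1 + p2
        if end > len(seq):
            continue
        if (
            all(c == "P" for c in seq[s + 1 : s + 1 + p1])
            and seq[a2] in "ASTV"
            and all(c == "P" for c in seq[a2 + 1 : end])
        ):
            # greedy-longest trailing P run: reject if one more P would fit
            if p2 < 4 and end < len(seq) and seq[end] == "P":
                continue
            hits.append((end, p1))
    return hits


def ogly_oracle(seq: str):
    """Leftmost non-overlapping scan; per start: earliest end, then longest
    leading P run."""
    out = []
    i = 0
    while i < len(seq):
        hits = ogly_instantiations_at(seq, i)
        if not hits:
            i += 1
            continue
        end, _ = min(hits, key=lambda h: (h[0], -h[1]))
        out.append((i + 1, end))
        i = end
    return out


def sequon_oracle(seq: str):
    return [
        i + 1
        for i in range(len(seq))
        if seq[i : i + 3][:1] == "N"
        and len(seq[i : i + 3]) == 3
        and seq[i + 1] != "P"
        and seq[i + 2] in ("S", "T")
    ]


def pest_score_oracle(segment: str) -> float:
    masses = [RESIDUE_MASS[c] for c in segment]
    depst = sum(m for c, m in zip(segment, masses) if c in "DEPST")
    if "D" in segment or "E" in segment:
        depst -= min(RESIDUE_MASS[c] for c in "DE" if c in segment)
    if "P" in segment:
        depst -= RESIDUE_MASS["P"]
    if "S" in segment or "T" in segment:
        depst -= min(RESIDUE_MASS[c] for c in "ST" if c in segment)
    pct = 100.0 * max(depst, 0.0) / sum(masses)
    hydro = float(np.mean([LTKDHI[c] for c in segment]))
    return 0.55 * pct - 0.5 * hydro


def _random_sequences(n, max_len, alphabet, weights, seed):
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    p = np.array(weights, dtype=float)
    p /= p.sum()
    for _ in range(n):
        length = int(rng.integers(3, max_len + 1))
        yield "".join(rng.choice(letters, size=length, p=p))


# ---------------------------------------------------------------------------
# O-glycosylation


class TestScanOgly:
    def test_minimal_motif(self):
        (m,) = scan_ogly("APAP")
        assert (m.start, m.end, m.anchor) == (1, 4, 2)

    def test_no_proline_no_match(self):
        assert scan_ogly("GLGLGLG") == []

    def test_tandem_repeat_two_sites(self):
        ms = scan_ogly("APAPAPAP")
        assert [(m.start, m.end) for m in ms] == [(1, 4), (5, 8)]

    def test_x_never_matches_literals_but_fills_spacer(self):
        assert scan_ogly("XPAP") == []  # X cannot open the motif
        assert scan_ogly("AXAP") == []  # X cannot replace the P run
        (m,) = scan_ogly("APXXAP")  # X may occupy the wildcard spacer
        assert (m.start, m.end) == (1, 6)

    def test_counts_occurrences_not_prolines(self):
        (m,) = scan_ogly("APPPPAPP")
        assert m.end == 8 and len(scan_ogly("APPPPAPP")) == 1

    def test_overlap_mode_reports_every_start(self):
        non = scan_ogly("APAPAP")
        allm = scan_ogly("APAPAP", allow_overlaps=True)
        assert len(allm) >= len(non)
        assert {m.start for m in non} <= {m.start for m in allm}

    def test_matches_never_overlap(self):
        for seq in _random_sequences(200, 120, "PASTVGLK", [5, 3, 3, 3, 2, 2, 1, 1], 7):
            ms = scan_ogly(seq)
            for a, b in zip(ms, ms[1:]):
                assert a.end < b.start

    def test_locality_with_g_spacer(self):
        pairs = zip(
            _random_sequences(100, 60, "PASTVGLK", [5, 3, 3, 3, 2, 2, 1, 1], 11),
            _random_sequences(100, 60, "PASTVGLK", [5, 3, 3, 3, 2, 2, 1, 1], 13),
        )
        for left, right in pairs:
            joined = left + "G" * 15 + right
            assert len(scan_ogly(joined)) == len(scan_ogly(left)) + len(scan_ogly(right))

    def test_equals_enumeration_oracle_on_random_sequences(self):
        n_checked = 0
        for seq in _random_sequences(
            1000, 200, "PASTVGLK", [5, 3, 3, 3, 2, 2, 1, 1], 20240917
        ):
            got = [(m.start, m.end) for m in scan_ogly(seq)]
            assert got == ogly_oracle(seq), seq
            n_checked += 1
        assert n_checked == 1000


# ---------------------------------------------------------------------------
# N-glycosylation sequons


class TestScanSequons:
    def test_simple_sequon(self):
        (m,) = scan_ngly_sequons("ANKSA")
        assert m.anchor == 2

    def test_proline_blocks(self):
        assert scan_ngly_sequons("ANPSA") == []

    def test_overlapping_sequons_all_reported(self):
        assert [m.anchor for m in scan_ngly_sequons("NNSS")] == [1, 2]

    def test_x_blocks_literal_positions_only(self):
        assert scan_ngly_sequons("XNS") == []  # too short for N at 1? N at 2 lacks +2
        assert [m.anchor for m in scan_ngly_sequons("NXS")] == [1]
        assert scan_ngly_sequons("NKX") == []

    def test_equals_brute_force_on_random_sequences(self):
        for seq in _random_sequences(1000, 150, "NPSTAGKL", [3, 2, 3, 3, 2, 2, 1, 1], 99):
            got = [m.anchor for m in scan_ngly_sequons(seq)]
            assert got == sequon_oracle(seq), seq


# ---------------------------------------------------------------------------
# Secretory combination rule


def _sequons(anchors):
    return [
        MotifMatch("p", "ngly_sequon", a, a + 2, a) for a in anchors
    ]


class TestCombineNgly:
    def test_gate_closed_counts_nothing(self):
        out = combine_ngly(_sequons([10, 40]), SecretoryContext())
        assert out == []

    def test_signal_peptide_admits(self):
        out = combine_ngly(
            _sequons([30]), SecretoryContext(has_signal_peptide=True, signal_end=20)
        )
        assert [m.anchor for m in out] == [30]

    def test_tm_segment_excludes_buried_anchor(self):
        ctx = SecretoryContext(tm_segments=[(50, 70)])
        out = combine_ngly(_sequons([30, 55]), ctx)
        assert [m.anchor for m in out] == [30]

    def test_signal_region_cleaved_off(self):
        ctx = SecretoryContext(has_signal_peptide=True, signal_end=20)
        out = combine_ngly(_sequons([5, 30]), ctx)
        assert [m.anchor for m in out] == [30]
        keep_all = combine_ngly(_sequons([5, 30]), ctx, exclude_signal_region=False)
        assert [m.anchor for m in keep_all] == [5, 30]

    def test_output_subset_and_order(self):
        sq = _sequons([3, 25, 60, 90])
        ctx = SecretoryContext(has_signal_peptide=True, tm_segments=[(55, 75)])
        out = combine_ngly(sq, ctx)
        assert [m.anchor for m in out] == [25, 90]

    def test_adding_tm_never_grows_counted_set_when_gate_open(self):
        sq = _sequons([30, 55, 90])
        base = combine_ngly(sq, SecretoryContext(has_signal_peptide=True))
        more = combine_ngly(
            sq, SecretoryContext(has_signal_peptide=True, tm_segments=[(50, 60)])
        )
        assert {m.anchor for m in more} <= {m.anchor for m in base}

    def test_adding_tm_can_open_closed_gate(self):
        sq = _sequons([30])
        assert combine_ngly(sq, SecretoryContext()) == []
        opened = combine_ngly(sq, SecretoryContext(tm_segments=[(50, 70)]))
        assert [m.anchor for m in opened] == [30]

    def test_signal_only_gate_ignores_tm_admission(self):
        sq = _sequons([30])
        assert combine_ngly(sq, SecretoryContext(tm_segments=[(50, 70)]), gate="signal_only") == []


# ---------------------------------------------------------------------------
# PEST


class TestScanPest:
    def test_no_depst_between_flanks(self):
        assert scan_pest("K" + "A" * 12 + "K") == []

    def test_classic_pest_stretch_scores_high(self):
        (m,) = scan_pest("K" + "PESTPESTPEST" + "R")
        assert m.start == 2 and m.end == 13
        assert m.score > 5.0

    def test_no_flanks_uses_termini(self):
        # no K/R/H anywhere: the whole sequence is one candidate region
        ms = scan_pest("PESTPESTPEST")
        assert len(ms) == 1 and ms[0].start == 1 and ms[0].end == 12

    def test_short_stretch_ignored(self):
        assert scan_pest("K" + "PEST" + "K") == []

    def test_missing_class_invalidates(self):
        # no proline between flanks
        assert scan_pest("K" + "ESTESTESTEST" + "K") == []

    def test_hydrophobic_stretch_scores_below_threshold(self):
        assert scan_pest("K" + "ILVILVILVPDS" + "K") == []

    def test_score_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        letters = list("PESTDAGLIVK")
        for _ in range(300):
            seg = "".join(rng.choice(letters, size=int(rng.integers(12, 40))))
            seg = seg.replace("K", "A")  # candidate regions carry no flanks inside
            assert pest_score(seg) == pytest.approx(pest_score_oracle(seg), abs=1e-9)
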
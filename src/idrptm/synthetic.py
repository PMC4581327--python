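"""Synthetic multi-species proteomes with planted, quantitatively controlled
structure.

The generator emulates the statistical structure the analysis assumes so
that every pipeline stage is testable without external data or predictors:

* protein lengths follow a clipped log-normal law (50-4000 aa);
* each protein carries contiguous disordered segments realising a per-protein
  disorder fraction drawn from a Beta law; disordered segments are composed
  preferentially of disorder-promoting residues (A, R, G, Q, S, E, K, P),
  ordered segments of order-promoting ones (I, L, V, C, W, Y, F, N);
* PTM sites are planted on legal residues (S/T/Y, K, N) at per-residue rates
  chosen so the planted disordered-to-ordered density ratio is exactly a
  configured rho — the quantity the Rd/o statistic estimates;
* an optional site-count/disorder slope plants a linear increase of mean
  disorder fraction with site count for the bin-correlation procedure;
* secretory features (hydrophobic signal peptides, transmembrane helices in
  ordered regions) reproduce the negative disorder-TM association;
* protein families are either common (one diverged member in every species)
  or species-specific (one species only, with elevated disorder), mirroring
  the conserved-versus-private cluster contrast;
* a configurable fraction of near-duplicate records (point mutations at a
  small rate) exercises redundancy clustering.

Everything is deterministic given the seed: per-protein random streams are
derived by key-splitting (``SeedSequence([seed, tags...])``) so adding
proteins or species never perturbs existing ones. The generator makes no
attempt at biologically realistic evolution; it plants exactly the effects
the statistics are meant to measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    DisorderMask,
    SegmentAnnotation,
    SiteAnnotation,
    write_mask_table,
    write_segment_table,
    write_site_table,
)
from .proteome import Proteome, ProteinRecord, write_fasta

DISORDER_PROMOTING = "ARGQSEKP"
ORDER_PROMOTING = "ILVCWYFN"

#: Residue composition of disordered segments (disorder-promoting enriched).
_DISORDER_WEIGHTS = {
    "A": 13, "R": 8, "G": 11, "Q": 8, "S": 14, "E": 12, "K": 10, "P": 10,
    "D": 5, "T": 5, "N": 2, "H": 1, "M": 1,
}
#: Residue composition of ordered segments (hydrophobic/aromatic enriched).
_ORDER_WEIGHTS = {
    "I": 9, "L": 12, "V": 10, "C": 3, "W": 2, "Y": 5, "F": 8, "N": 6,
    "A": 8, "G": 7, "T": 7, "S": 6, "D": 4, "E": 4, "K": 4, "R": 3,
    "H": 2, "M": 2, "Q": 2, "P": 1,
}
#: Hydrophobic composition for signal peptides and transmembrane helices.
_HYDROPHOBIC_WEIGHTS = {"L": 30, "A": 20, "V": 15, "I": 12, "F": 10, "M": 5, "W": 3, "G": 5}

SITE_LEGAL_RESIDUE = {
    "phospho_S": "S",
    "phospho_T": "T",
    "phospho_Y": "Y",
    "ubiquitination": "K",
    "ngly_external": "N",
}

UBI_BAND = (0.69, 0.84)


def _comp(weights: dict[str, int]) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(weights), dtype="U1")
    w = np.array([weights[l] for l in letters], dtype=float)
    return letters, w / w.sum()


_DIS_LETTERS, _DIS_P = _comp(_DISORDER_WEIGHTS)
_ORD_LETTERS, _ORD_P = _comp(_ORDER_WEIGHTS)
_HYD_LETTERS, _HYD_P = _comp(_HYDROPHOBIC_WEIGHTS)


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class LengthLaw:
    """Clipped log-normal protein length distribution (residues)."""

    min: int = 50
    max: int = 4000
    median: float = 320.0
    sigma: float = 0.55


@dataclass
class DisorderLaw:
    """Per-protein disorder fraction: Beta(mean*c, (1-mean)*c).

    ``mean`` is the baseline (common-family) mean disorder fraction;
    ``mean_segment_len`` controls the granularity of contiguous disordered
    segments.
    """

    mean: float = 0.20
    concentration: float = 8.0
    mean_segment_len: int = 40


@dataclass
class PtmLaw:
    """Planted density of one PTM type.

    base_per_400: site density per 400 residues in ordered regions.
    rho: planted disordered-to-ordered per-residue density ratio — the
    ground truth the Rd/o statistic should recover.
    """

    base_per_400: float
    rho: float


def default_enrichment() -> dict[str, PtmLaw]:
    """Default planted densities, with enrichment ratios on the scale the
    proteome-wide contrasts report for algae (strong S/T-phosphorylation and
    ubiquitination preference for disorder, weak Y-phosphorylation and
    N-glycosylation preference)."""
    return {
        "phospho_S": PtmLaw(base_per_400=0.5, rho=18.8),
        "phospho_T": PtmLaw(base_per_400=0.4, rho=10.5),
        "phospho_Y": PtmLaw(base_per_400=0.3, rho=1.3),
        "ubiquitination": PtmLaw(base_per_400=0.2, rho=12.5),
        "ngly_external": PtmLaw(base_per_400=0.5, rho=1.2),
    }


@dataclass
class SecretoryLaw:
    signal_fraction: float = 0.25
    signal_len: tuple[int, int] = (15, 30)
    tm_mean_count: float = 0.6
    tm_len: tuple[int, int] = (19, 23)


@dataclass
class FamilyLaw:
    """Split into common (all-species) and species-specific families.

    Specific families get ``specific_disorder_multiplier`` times the baseline
    mean disorder and ``specific_ptm_multiplier`` times the baseline PTM
    rates, planting the conservation contrast.
    """

    common_fraction: float = 0.25
    divergence: float = 0.05
    specific_disorder_multiplier: float = 1.7
    specific_ptm_multiplier: float = 1.0


@dataclass
class RedundancyLaw:
    duplicate_fraction: float = 0.10
    mutation_rate: float = 0.02


@dataclass
class SynthConfig:
    seed: int
    n_species: int = 3
    n_proteins_per_species: int = 300
    length_law: LengthLaw = field(default_factory=LengthLaw)
    disorder_law: DisorderLaw = field(default_factory=DisorderLaw)
    enrichment: dict[str, PtmLaw] = field(default_factory=default_enrichment)
    site_count_disorder_slope: float = 0.0
    secretory: SecretoryLaw = field(default_factory=SecretoryLaw)
    families: FamilyLaw = field(default_factory=FamilyLaw)
    redundancy: RedundancyLaw = field(default_factory=RedundancyLaw)
    ubiquitin_decoy_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name, frac in (
            ("common_fraction", self.families.common_fraction),
            ("duplicate_fraction", self.redundancy.duplicate_fraction),
            ("signal_fraction", self.secretory.signal_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for ptm, law in self.enrichment.items():
            if ptm not in SITE_LEGAL_RESIDUE:
                raise ValueError(f"unknown PTM type {ptm!r}")
            if not (math.isfinite(law.rho) and law.rho >= 0):
                raise ValueError(f"{ptm}: rho must be finite and >= 0")
            if law.base_per_400 < 0:
                raise ValueError(f"{ptm}: base_per_400 must be >= 0")
            # a per-residue probability above 1 is unrealisable
            if law.rho * law.base_per_400 / 400.0 * 25 > 1.0:
                raise ValueError(
                    f"{ptm}: rho * base_per_400 implies more than one site per "
                    "legal residue; reduce the rates"
                )

    def species_ids(self) -> list[str]:
        return [f"sp{i+1:02d}" for i in range(self.n_species)]


# ---------------------------------------------------------------------------
# Primitive planting operations


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def plant_disorder_mask(
    length: int,
    target_fraction: float,
    mean_segment_len: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Contiguous disordered segments realising the target fraction exactly.

    The disordered residue total is round(target * length); it is split into
    roughly ``mean_segment_len``-sized contiguous segments placed at random
    non-overlapping positions (multinomial gaps), so the realised fraction is
    within rounding of the target.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    total_d = int(round(target_fraction * length))
    mask = np.zeros(length, dtype=np.uint8)
    if total_d == 0:
        return mask
    if total_d >= length:
        return np.ones(length, dtype=np.uint8)
    k = max(1, int(round(total_d / max(mean_segment_len, 1))))
    seg_lengths = rng.multinomial(total_d, np.full(k, 1.0 / k))
    seg_lengths = seg_lengths[seg_lengths > 0]
    gaps = rng.multinomial(length - total_d, np.full(len(seg_lengths) + 1, 1.0 / (len(seg_lengths) + 1)))
    pos = 0
    for gap, seg in zip(gaps, seg_lengths):
        pos += int(gap)
        mask[pos : pos + int(seg)] = 1
        pos += int(seg)
    return mask


def plant_sites(
    sequence: str,
    mask: np.ndarray,
    ptm_type: str,
    base_per_400: float,
    rho: float,
    rng: np.random.Generator,
    *,
    rate_multiplier: float = 1.0,
) -> list[int]:
    """Draw site positions (1-based) at planted rates.

    Legal residues of the PTM type are modified independently; the
    per-legal-residue probabilities are scaled so the *expected per-residue
    densities* are ``base/400`` in ordered and ``rho*base/400`` in disordered
    regions regardless of how the residue composition differs between the
    two region types — which makes the planted rho exactly the quantity
    Rd/o = (Nd/Ld)/(No/Lo) estimates.
    """
    legal = SITE_LEGAL_RESIDUE[ptm_type]
    seq_arr = np.frombuffer(sequence.encode(), dtype="S1")
    is_legal = seq_arr == legal.encode()
    mask = np.asarray(mask, dtype=bool)
    positions: list[int] = []
    for region_mask, rate in (
        (~mask, base_per_400 * rate_multiplier / 400.0),
        (mask, rho * base_per_400 * rate_multiplier / 400.0),
    ):
        n_region = int(region_mask.sum())
        idx = np.flatnonzero(is_legal & region_mask)
        if n_region == 0 or len(idx) == 0 or rate == 0.0:
            continue
        if rate > 1.0:
            raise ValueError(
                f"{ptm_type}: planted per-residue rate {rate:.2f} > 1 is unrealisable"
            )
        # count per region is Binomial(region length, rate): the expectation
        # is rate * region length regardless of how many legal residues the
        # region happens to contain, keeping the planted rho exact
        n_sites = int(rng.binomial(n_region, rate))
        chosen = rng.choice(idx, size=min(n_sites, len(idx)), replace=False)
        positions.extend(int(i) + 1 for i in chosen)
    return sorted(positions)


def _place_sites_fixed_count(
    sequence: str,
    mask: np.ndarray,
    ptm_type: str,
    count: int,
    rho: float,
    rng: np.random.Generator,
) -> list[int]:
    """Place exactly ``count`` sites, disordered legal residues weighted rho."""
    legal = SITE_LEGAL_RESIDUE[ptm_type]
    seq_arr = np.frombuffer(sequence.encode(), dtype="S1")
    idx = np.flatnonzero(seq_arr == legal.encode())
    if len(idx) == 0 or count == 0:
        return []
    count = min(count, len(idx))
    weights = np.where(np.asarray(mask, dtype=bool)[idx], max(rho, 1e-9), 1.0)
    chosen = rng.choice(idx, size=count, replace=False, p=weights / weights.sum())
    return sorted(int(i) + 1 for i in chosen)


def _compose_sequence(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    seq = np.empty(len(mask), dtype="U1")
    d = np.asarray(mask, dtype=bool)
    n_d, n_o = int(d.sum()), int((~d).sum())
    if n_d:
        seq[d] = rng.choice(_DIS_LETTERS, size=n_d, p=_DIS_P)
    if n_o:
        seq[~d] = rng.choice(_ORD_LETTERS, size=n_o, p=_ORD_P)
    return seq


def _mutate(seq: np.ndarray, mask: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point substitutions at the given rate, resampling from the composition
    of the residue's own region so region character is preserved."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    d = np.asarray(mask, dtype=bool)
    for i in hit:
        letters, p = (_DIS_LETTERS, _DIS_P) if d[i] else (_ORD_LETTERS, _ORD_P)
        out[i] = rng.choice(letters, p=p)
    return out


# ---------------------------------------------------------------------------
# Whole-proteome generation


@dataclass
class SyntheticProtein:
    record: ProteinRecord
    mask: DisorderMask
    sites: list[SiteAnnotation]
    segments: list[SegmentAnnotation]
    family_id: str
    category: str  # common | specific
    disorder_target: float
    duplicate_of: str | None = None
    true_site_count: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticDataset:
    """Generated proteomes plus ground truth, in the formats the pipeline
    consumes (FASTA + site/segment/mask TSVs when written to disk)."""

    config: SynthConfig
    proteins: dict[str, list[SyntheticProtein]]  # species_id -> proteins

    @property
    def species_ids(self) -> list[str]:
        return list(self.proteins)

    def proteome(self, species_id: str) -> Proteome:
        return Proteome(
            species_id=species_id,
            records=[p.record for p in self.proteins[species_id]],
        )

    def masks(self, species_id: str) -> dict[str, DisorderMask]:
        return {p.record.protein_id: p.mask for p in self.proteins[species_id]}

    def sites(self, species_id: str) -> list[SiteAnnotation]:
        return [s for p in self.proteins[species_id] for s in p.sites]

    def segments(self, species_id: str) -> list[SegmentAnnotation]:
        return [s for p in self.proteins[species_id] for s in p.segments]

    def truth(self) -> pd.DataFrame:
        rows = []
        for sp, prots in self.proteins.items():
            for p in prots:
                rows.append(
                    {
                        "species_id": sp,
                        "protein_id": p.record.protein_id,
                        "family_id": p.family_id,
                        "category": p.category,
                        "length": len(p.record),
                        "disorder_target": p.disorder_target,
                        "duplicate_of": p.duplicate_of or "",
                    }
                )
        return pd.DataFrame(rows)

    def duplicate_links(self) -> list[tuple[str, str, str]]:
        """(species_id, duplicate_id, source_id) for every planted near-duplicate."""
        return [
            (sp, p.record.protein_id, p.duplicate_of)
            for sp, prots in self.proteins.items()
            for p in prots
            if p.duplicate_of
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in self.species_ids:
            write_fasta(self.proteome(sp), outdir / f"{sp}.fasta")
            write_mask_table(self.masks(sp).values(), outdir / f"{sp}.masks.tsv")
            write_site_table(self.sites(sp), outdir / f"{sp}.sites.tsv")
            write_segment_table(self.segments(sp), outdir / f"{sp}.segments.tsv")
        self.truth().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)


def _draw_length(law: LengthLaw, rng: np.random.Generator) -> int:
    raw = rng.lognormal(mean=math.log(law.median), sigma=law.sigma)
    return int(min(max(round(raw), law.min), law.max))


def _draw_disorder_fraction(mean: float, concentration: float, rng: np.random.Generator) -> float:
    mean = min(max(mean, 0.02), 0.95)
    a = mean * concentration
    b = (1.0 - mean) * concentration
    return float(np.clip(rng.beta(a, b), 0.01, 0.98))


def _build_protein(
    cfg: SynthConfig,
    species_id: str,
    protein_id: str,
    family_id: str,
    category: str,
    rng: np.random.Generator,
    *,
    ancestor: tuple[np.ndarray, np.ndarray, float] | None = None,
) -> SyntheticProtein:
    """Generate one protein; common-family members diverge from an ancestor."""
    law = cfg.disorder_law
    fam = cfg.families
    ptm_mult = fam.specific_ptm_multiplier if category == "specific" else 1.0
    slope = cfg.site_count_disorder_slope

    planned_counts: dict[str, int] = {}
    if ancestor is not None:
        anc_seq, anc_mask, f = ancestor
        mask = anc_mask.copy()
        seq_arr = _mutate(anc_seq, mask, fam.divergence, rng)
    else:
        length = _draw_length(cfg.length_law, rng)
        mean = law.mean * (fam.specific_disorder_multiplier if category == "specific" else 1.0)
        if slope > 0.0:
            # count-first construction: the site count drives the disorder
            # target linearly, planting the bin-series correlation
            for ptm, ptm_law in cfg.enrichment.items():
                lam = ptm_law.base_per_400 * ptm_mult * length / 400.0
                planned_counts[ptm] = int(rng.poisson(lam))
            total = min(sum(planned_counts.values()), 12)
            f = float(np.clip(mean + slope * total, 0.02, 0.95))
        else:
            f = _draw_disorder_fraction(mean, law.concentration, rng)
        mask = plant_disorder_mask(length, f, law.mean_segment_len, rng)
        seq_arr = _compose_sequence(mask, rng)

    segments: list[SegmentAnnotation] = []
    sec = cfg.secretory
    # signal peptide: hydrophobic N-terminus, forced ordered
    if rng.random() < sec.signal_fraction and len(seq_arr) > 3 * sec.signal_len[1]:
        sp_len = int(rng.integers(sec.signal_len[0], sec.signal_len[1] + 1))
        seq_arr[:sp_len] = rng.choice(_HYD_LETTERS, size=sp_len, p=_HYD_P)
        mask[:sp_len] = 0
        segments.append(SegmentAnnotation(protein_id, "signal_peptide", 1, sp_len))
    # transmembrane helices: hydrophobic stretches inside ordered runs.
    # Membrane proteins are a low-disorder class, so the helix count law
    # decays steeply with the protein's disorder fraction; the factor 3
    # renormalises the mean count near the configured value for the default
    # disorder law (E[(1-f)^4] ~ 1/3 at mean disorder ~0.25).
    f_realised = float(np.asarray(mask).mean())
    n_tm = int(rng.poisson(sec.tm_mean_count * 3.0 * (1.0 - f_realised) ** 4))
    occupied = [(0, segments[0].end)] if segments else []
    for _ in range(n_tm):
        tm_len = int(rng.integers(sec.tm_len[0], sec.tm_len[1] + 1))
        slot = _find_ordered_slot(mask, tm_len, occupied, rng)
        if slot is None:
            continue
        s0 = slot
        seq_arr[s0 : s0 + tm_len] = rng.choice(_HYD_LETTERS, size=tm_len, p=_HYD_P)
        occupied.append((s0, s0 + tm_len))
        segments.append(SegmentAnnotation(protein_id, "tm_helix", s0 + 1, s0 + tm_len))
    segments.sort(key=lambda s: s.start)

    sequence = "".join(seq_arr.tolist())

    sites: list[SiteAnnotation] = []
    true_counts: dict[str, int] = {}
    for ptm, ptm_law in cfg.enrichment.items():
        if slope > 0.0 and ancestor is None:
            positions = _place_sites_fixed_count(
                sequence, mask, ptm, planned_counts.get(ptm, 0), ptm_law.rho, rng
            )
        else:
            positions = plant_sites(
                sequence, mask, ptm, ptm_law.base_per_400, ptm_law.rho, rng,
                rate_multiplier=ptm_mult,
            )
        true_counts[ptm] = len(positions)
        for pos in positions:
            sites.append(SiteAnnotation(protein_id, ptm, pos, score=_site_score(ptm, rng)))
        if ptm == "ubiquitination" and cfg.ubiquitin_decoy_fraction > 0:
            sites.extend(
                _ubiquitin_decoys(sequence, positions, protein_id, cfg, rng)
            )
    sites.sort(key=lambda s: (s.position, s.site_type))

    rec = ProteinRecord(protein_id=protein_id, species_id=species_id, sequence=sequence)
    return SyntheticProtein(
        record=rec,
        mask=DisorderMask(protein_id, mask.copy(), source="synthetic"),
        sites=sites,
        segments=segments,
        family_id=family_id,
        category=category,
        disorder_target=float(np.asarray(mask).mean()),
        true_site_count=true_counts,
    )


def _site_score(ptm: str, rng: np.random.Generator) -> float | None:
    if ptm == "ubiquitination":
        return round(float(rng.uniform(*UBI_BAND)), 3)
    if ptm.startswith("phospho"):
        return round(float(rng.uniform(0.5, 1.0)), 3)
    return None


def _ubiquitin_decoys(
    sequence: str,
    taken: Sequence[int],
    protein_id: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
) -> list[SiteAnnotation]:
    """Out-of-band ubiquitination predictions the confidence filter must drop."""
    n = int(round(cfg.ubiquitin_decoy_fraction * len(taken)))
    if n == 0:
        return []
    free = [i + 1 for i, c in enumerate(sequence) if c == "K" and (i + 1) not in set(taken)]
    if not free:
        return []
    chosen = rng.choice(np.array(free), size=min(n, len(free)), replace=False)
    out = []
    for pos in sorted(int(p) for p in chosen):
        score = float(rng.uniform(0.10, 0.60)) if rng.random() < 0.5 else float(rng.uniform(0.86, 0.99))
        out.append(SiteAnnotation(protein_id, "ubiquitination", pos, score=round(score, 3)))
    return out


def _find_ordered_slot(
    mask: np.ndarray,
    length: int,
    occupied: list[tuple[int, int]],
    rng: np.random.Generator,
) -> int | None:
    """A random start of an all-ordered, unoccupied window, or None."""
    free = np.asarray(mask, dtype=bool).copy()
    free = ~free
    for s, e in occupied:
        free[s:e] = False
    # valid starts: windows of `length` consecutive free positions
    conv = np.convolve(free.astype(int), np.ones(length, dtype=int), mode="valid")
    starts = np.flatnonzero(conv == length)
    if len(starts) == 0:
        return None
    return int(rng.choice(starts))


def generate(config: SynthConfig) -> SyntheticDataset:
    """Generate the full multi-species dataset for a configuration.

    Deterministic given ``config.seed``; see the module docstring for the
    planted structure.
    """
    n_common = int(round(config.families.common_fraction * config.n_proteins_per_species))
    species = config.species_ids()

    # common-family ancestors, generated once and diverged into every species
    ancestors: list[tuple[np.ndarray, np.ndarray, float]] = []
    for fam_idx in range(n_common):
        rng = _rng(config.seed, 0, fam_idx)
        length = _draw_length(config.length_law, rng)
        f = _draw_disorder_fraction(
            config.disorder_law.mean, config.disorder_law.concentration, rng
        )
        mask = plant_disorder_mask(length, f, config.disorder_law.mean_segment_len, rng)
        seq = _compose_sequence(mask, rng)
        ancestors.append((seq, mask, f))

    proteins: dict[str, list[SyntheticProtein]] = {}
    for sp_idx, sp in enumerate(species):
        plist: list[SyntheticProtein] = []
        for fam_idx, anc in enumerate(ancestors):
            pid = f"{sp}_c{fam_idx:05d}"
            plist.append(
                _build_protein(
                    config, sp, pid, family_id=f"F{fam_idx:05d}", category="common",
                    rng=_rng(config.seed, 1, sp_idx, fam_idx), ancestor=anc,
                )
            )
        n_specific = config.n_proteins_per_species - n_common
        for j in range(n_specific):
            pid = f"{sp}_s{j:05d}"
            plist.append(
                _build_protein(
                    config, sp, pid, family_id=f"S_{sp}_{j:05d}", category="specific",
                    rng=_rng(config.seed, 2, sp_idx, j),
                )
            )
        # near-duplicates: fraction of the final proteome that is redundant
        dfrac = config.redundancy.duplicate_fraction
        n_dup = int(round(dfrac / (1.0 - dfrac) * len(plist))) if dfrac < 1.0 else 0
        dup_rng = _rng(config.seed, 3, sp_idx)
        src_indices = dup_rng.choice(len(plist), size=min(n_dup, len(plist)), replace=False)
        for j, src_idx in enumerate(sorted(int(i) for i in src_indices)):
            src = plist[src_idx]
            rng = _rng(config.seed, 4, sp_idx, j)
            seq_arr = np.array(list(src.record.sequence), dtype="U1")
            mutated = _mutate(seq_arr, src.mask.mask, config.redundancy.mutation_rate, rng)
            pid = f"{src.record.protein_id}_d"
            rec = ProteinRecord(protein_id=pid, species_id=sp, sequence="".join(mutated.tolist()))
            sites = _replant_on_mutant(src, rec, rng)
            dup_counts: dict[str, int] = {k: 0 for k in src.true_site_count}
            for s in sites:
                if s.site_type == "ubiquitination" and not (
                    UBI_BAND[0] <= (s.score or 0.0) <= UBI_BAND[1]
                ):
                    continue  # carried decoy, not a planted site
                dup_counts[s.site_type] = dup_counts.get(s.site_type, 0) + 1
            plist.append(
                SyntheticProtein(
                    record=rec,
                    mask=DisorderMask(pid, src.mask.mask.copy(), source="synthetic"),
                    sites=sites,
                    segments=[
                        SegmentAnnotation(pid, s.segment_type, s.start, s.end)
                        for s in src.segments
                    ],
                    family_id=src.family_id,
                    category=src.category,
                    disorder_target=src.disorder_target,
                    duplicate_of=src.record.protein_id,
                    true_site_count=dup_counts,
                )
            )
        proteins[sp] = plist
    return SyntheticDataset(config=config, proteins=proteins)


def _replant_on_mutant(
    src: SyntheticProtein, rec: ProteinRecord, rng: np.random.Generator
) -> list[SiteAnnotation]:
    """Carry the source's sites onto a mutated copy where the residue survives."""
    out = []
    for s in src.sites:
        if rec.sequence[s.position - 1] == SITE_LEGAL_RESIDUE[s.site_type]:
            out.append(SiteAnnotation(rec.protein_id, s.site_type, s.position, s.score))
    return out
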
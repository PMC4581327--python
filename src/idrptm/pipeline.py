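"""End-to-end orchestration: ingest -> filter -> cluster -> scan -> annotate
-> statistics -> specific/common contrast, under one declarative config.

The run mirrors the analysis order of the study design: length filtering
first, then redundancy removal (cluster representatives), then feature
scanning and annotation joining on the non-redundant set, then the
statistics (per-400-aa densities, bin series with one-tailed Pearson
inference and within-species Benjamini-Hochberg adjustment, Rd/o with group
pooling), and finally the species-specific versus common cluster contrast.

All persisted outputs are plain TSV; identical configs produce bit-identical
outputs (no timestamps inside data files).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import (
    AnnotatedProtein,
    DisorderMask,
    SegmentAnnotation,
    SiteAnnotation,
    filter_ubiquitination,
    iter_annotated,
    load_mask_table,
    load_segment_table,
    load_site_table,
)
from .clustering import (
    ClusterCatalog,
    ContrastResult,
    IdentityParams,
    build_clusters,
    category_contrast,
    classify_clusters,
    read_cluster_table,
    redundancy_content,
    select_representatives,
    write_category_table,
    write_cluster_table,
)
from .proteome import Proteome, filter_by_length, read_fasta, summarize
from .ptm_stats import (
    PARAMETERS,
    SITE_PARAMETERS,
    NotComputable,
    bh_fdr,
    bin_by_site_count,
    density_per_400,
    group_aggregate,
    mean_density_per_400,
    pearson_one_tailed,
    pooled_density_per_400,
    rdo,
    RdoResult,
)
from .scanners import (
    SecretoryContext,
    combine_ngly,
    scan_ngly_sequons,
    scan_ogly,
    scan_pest,
    write_match_table,
)
from .synthetic import SynthConfig, SyntheticDataset, generate

logger = logging.getLogger(__name__)


@dataclass
class SpeciesInput:
    """File-based inputs for one species."""

    species_id: str
    fasta: str
    group: str = "other"
    masks: str | None = None
    sites: str | None = None
    segments: str | None = None


@dataclass
class RunConfig:
    """Declarative configuration of a full analysis run.

    Exactly one of ``species`` (file inputs) or ``synthetic`` must be set.
    Options whose reading of the study design is ambiguous (overlap policy,
    secretory gate, density mode, FDR family, bin x-variable) are explicit
    and documented in the methods note.
    """

    species: list[SpeciesInput] = field(default_factory=list)
    synthetic: SynthConfig | None = None
    min_len: int = 50
    max_len: int = 4000
    redundancy: str = "cluster"  # cluster | none
    identity: IdentityParams = field(default_factory=IdentityParams)
    ogly_allow_overlaps: bool = False
    ngly_gate: str = "signal_or_tm"  # signal_or_tm | signal_only
    ngly_source: str = "sequon_scan"  # sequon_scan | external
    pest_threshold: float = 5.0
    ubiquitin_band: tuple[float, float] = (0.69, 0.84)
    bin_cap: int = 7
    density_mode: str = "pooled"  # pooled | per_protein_mean
    fdr_family: str = "species"  # species | global
    cluster_source: str = "build"  # build | truth | file
    cluster_file: str | None = None
    grouping: dict[str, str] = field(default_factory=dict)  # species -> group
    seed: int = 0

    def __post_init__(self) -> None:
        if bool(self.species) == (self.synthetic is not None):
            raise ValueError("configure exactly one of species files or synthetic data")
        for name, value, allowed in (
            ("redundancy", self.redundancy, ("cluster", "none")),
            ("ngly_gate", self.ngly_gate, ("signal_or_tm", "signal_only")),
            ("ngly_source", self.ngly_source, ("sequon_scan", "external")),
            ("density_mode", self.density_mode, ("pooled", "per_protein_mean")),
            ("fdr_family", self.fdr_family, ("species", "global")),
            ("cluster_source", self.cluster_source, ("build", "truth", "file")),
        ):
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")
        if self.cluster_source == "file" and not self.cluster_file:
            raise ValueError("cluster_source='file' needs cluster_file")
        if self.cluster_source == "truth" and self.synthetic is None:
            raise ValueError("cluster_source='truth' needs synthetic data")

    def config_hash(self) -> str:
        blob = json.dumps(_as_plain(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from YAML (keys mirror the dataclass fields)."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if "species" in raw:
        raw["species"] = [SpeciesInput(**s) for s in raw["species"]]
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = _synth_from_dict(raw["synthetic"])
    if "identity" in raw:
        raw["identity"] = IdentityParams(**raw["identity"])
    if "ubiquitin_band" in raw:
        raw["ubiquitin_band"] = tuple(raw["ubiquitin_band"])
    return RunConfig(**raw)


def _synth_from_dict(raw: dict) -> SynthConfig:
    from . import synthetic as syn

    kwargs = dict(raw)
    for key, cls in (
        ("length_law", syn.LengthLaw),
        ("disorder_law", syn.DisorderLaw),
        ("secretory", syn.SecretoryLaw),
        ("families", syn.FamilyLaw),
        ("redundancy", syn.RedundancyLaw),
    ):
        if key in kwargs and isinstance(kwargs[key], dict):
            sub = dict(kwargs[key])
            for tup_key in ("signal_len", "tm_len"):
                if tup_key in sub:
                    sub[tup_key] = tuple(sub[tup_key])
            kwargs[key] = cls(**sub)
    if "enrichment" in kwargs:
        kwargs["enrichment"] = {
            ptm: syn.PtmLaw(**law) if isinstance(law, dict) else law
            for ptm, law in kwargs["enrichment"].items()
        }
    return SynthConfig(**kwargs)


# ---------------------------------------------------------------------------
# Per-species assembly


@dataclass
class SpeciesData:
    """One species after filtering, redundancy removal, and annotation join."""

    species_id: str
    group: str
    n_raw: int
    n_length_filtered: int
    n_nonredundant: int
    annotated: list[AnnotatedProtein]
    counts: pd.DataFrame  # per protein: one column per parameter + disorder + length

    @property
    def redundancy_fraction(self) -> float:
        return redundancy_content(self.n_length_filtered, self.n_nonredundant)


def _per_protein_counts(
    annotated: Sequence[AnnotatedProtein], config: RunConfig
) -> pd.DataFrame:
    rows = []
    for prot in annotated:
        seq = prot.record.sequence
        sequons = scan_ngly_sequons(seq, protein_id=prot.record.protein_id)
        signal = [s for s in prot.segments if s.segment_type == "signal_peptide"]
        tm = [(s.start, s.end) for s in prot.segments if s.segment_type == "tm_helix"]
        context = SecretoryContext(
            has_signal_peptide=bool(signal),
            tm_segments=tm,
            signal_end=signal[0].end if signal else 20,
        )
        if config.ngly_source == "external":
            ext = [s for s in prot.sites if s.site_type == "ngly_external"]
            ngly_count = len(
                combine_ngly(
                    [  # external N-site table in the sequon role
                        _site_as_match(s) for s in ext
                    ],
                    context,
                    gate=config.ngly_gate,
                )
            )
        else:
            ngly_count = len(combine_ngly(sequons, context, gate=config.ngly_gate))
        low, high = config.ubiquitin_band
        ubi = [
            s
            for s in filter_ubiquitination(
                [s for s in prot.sites if s.site_type == "ubiquitination"],
                low,
                high,
            )
        ]
        rows.append(
            {
                "protein_id": prot.record.protein_id,
                "length": len(prot.record),
                "disorder": prot.disorder_content,
                "phospho_S": prot.site_count("phospho_S"),
                "phospho_T": prot.site_count("phospho_T"),
                "phospho_Y": prot.site_count("phospho_Y"),
                "ogly": len(
                    scan_ogly(
                        seq,
                        protein_id=prot.record.protein_id,
                        allow_overlaps=config.ogly_allow_overlaps,
                    )
                ),
                "ngly": ngly_count,
                "ubiquitination": len(ubi),
                "pest": len(
                    scan_pest(seq, config.pest_threshold, protein_id=prot.record.protein_id)
                ),
                "tm_helix": prot.segment_count("tm_helix"),
            }
        )
    return pd.DataFrame(rows)


def _site_as_match(site: SiteAnnotation):
    from .scanners import MotifMatch

    return MotifMatch(
        protein_id=site.protein_id,
        kind="ngly_sequon",
        start=site.position,
        end=site.position,
        anchor=site.position,
    )


def _assemble_species(
    config: RunConfig,
    proteome: Proteome,
    masks: dict[str, DisorderMask],
    sites: Sequence[SiteAnnotation],
    segments: Sequence[SegmentAnnotation],
    group: str,
) -> SpeciesData:
    n_raw = len(proteome)
    filtered = filter_by_length(proteome, config.min_len, config.max_len).proteome
    if config.redundancy == "cluster":
        catalog = build_clusters(list(filtered), config.identity)
        reps = select_representatives(catalog, list(filtered))
        keep_ids = {r.protein_id for r in reps}
        nonredundant = Proteome(
            species_id=proteome.species_id,
            records=[r for r in filtered if r.protein_id in keep_ids],
            group=filtered.group,
        )
    else:
        nonredundant = filtered
    annotated = list(
        iter_annotated(
            nonredundant,
            masks,
            [s for s in sites if s.protein_id in set(nonredundant.ids)],
            [s for s in segments if s.protein_id in set(nonredundant.ids)],
        )
    )
    counts = _per_protein_counts(annotated, config)
    return SpeciesData(
        species_id=proteome.species_id,
        group=group,
        n_raw=n_raw,
        n_length_filtered=len(filtered),
        n_nonredundant=len(nonredundant),
        annotated=annotated,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# Statistics assembly


def correlation_table(
    species_data: Sequence[SpeciesData], config: RunConfig
) -> pd.DataFrame:
    """Per species x parameter: r, one-tailed p, BH FDR, number of bins.

    The FDR family is, by default, the eight parameter tests within one
    species; ``fdr_family='global'`` adjusts over all species x parameters.
    """
    rows = []
    for sd in species_data:
        for param in PARAMETERS:
            entry = {"species_id": sd.species_id, "parameter": param}
            try:
                series = bin_by_site_count(
                    sd.counts[param].to_numpy(),
                    sd.counts["disorder"].to_numpy(),
                    parameter=param,
                    cap=config.bin_cap,
                )
                res = pearson_one_tailed(series)
                entry.update(
                    r=res.r, p_one_tailed=res.p_one_tailed, n_bins=res.n,
                    direction=res.direction,
                )
            except NotComputable as exc:
                entry.update(r=np.nan, p_one_tailed=np.nan, n_bins=0, direction="")
                logger.warning("%s/%s: %s", sd.species_id, param, exc)
            rows.append(entry)
    df = pd.DataFrame(rows)
    df["fdr"] = np.nan
    if config.fdr_family == "species":
        for sp, idx in df.groupby("species_id").groups.items():
            sub = df.loc[idx]
            ok = sub["p_one_tailed"].notna()
            if ok.any():
                df.loc[sub.index[ok], "fdr"] = bh_fdr(sub.loc[ok, "p_one_tailed"].tolist())
    else:
        ok = df["p_one_tailed"].notna()
        if ok.any():
            df.loc[ok, "fdr"] = bh_fdr(df.loc[ok, "p_one_tailed"].tolist())
    return df


def density_table(species_data: Sequence[SpeciesData], config: RunConfig) -> pd.DataFrame:
    rows = []
    for sd in species_data:
        lengths = sd.counts["length"].to_numpy()
        entry = {
            "species_id": sd.species_id,
            "group": sd.group,
            "n_raw": sd.n_raw,
            "n_length_filtered": sd.n_length_filtered,
            "n_nonredundant": sd.n_nonredundant,
            "redundancy_fraction": sd.redundancy_fraction,
            "total_aa": int(lengths.sum()),
            "mean_disorder": float(sd.counts["disorder"].mean()),
        }
        for param in PARAMETERS:
            counts = sd.counts[param].to_numpy()
            if config.density_mode == "pooled":
                entry[f"{param}_per400"] = pooled_density_per_400(counts, lengths)
            else:
                entry[f"{param}_per400"] = mean_density_per_400(counts, lengths)
        rows.append(entry)
    return pd.DataFrame(rows)


def rdo_table(
    species_data: Sequence[SpeciesData],
    config: RunConfig,
    grouping: Mapping[str, str],
) -> pd.DataFrame:
    """Rd/o per group and in total, pooled over species, one row per group x PTM."""
    per_param_species: dict[str, dict[str, RdoResult]] = {p: {} for p in SITE_PARAMETERS}
    for sd in species_data:
        masks = {p.record.protein_id: p.mask.mask for p in sd.annotated}
        for param in SITE_PARAMETERS:
            anchors: dict[str, list[int]] = {}
            for prot in sd.annotated:
                pid = prot.record.protein_id
                if param == "ogly":
                    hits = scan_ogly(
                        prot.record.sequence,
                        protein_id=pid,
                        allow_overlaps=config.ogly_allow_overlaps,
                    )
                    anchors[pid] = [m.anchor for m in hits]
                elif param == "ngly":
                    seqs = scan_ngly_sequons(prot.record.sequence, protein_id=pid)
                    signal = [s for s in prot.segments if s.segment_type == "signal_peptide"]
                    tm = [(s.start, s.end) for s in prot.segments if s.segment_type == "tm_helix"]
                    ctx = SecretoryContext(
                        has_signal_peptide=bool(signal),
                        tm_segments=tm,
                        signal_end=signal[0].end if signal else 20,
                    )
                    anchors[pid] = [
                        m.anchor for m in combine_ngly(seqs, ctx, gate=config.ngly_gate)
                    ]
                elif param == "ubiquitination":
                    low, high = config.ubiquitin_band
                    anchors[pid] = [
                        s.position
                        for s in filter_ubiquitination(
                            [s for s in prot.sites if s.site_type == "ubiquitination"],
                            low,
                            high,
                        )
                    ]
                else:
                    anchors[pid] = [
                        s.position for s in prot.sites if s.site_type == param
                    ]
            per_param_species[param][sd.species_id] = rdo(anchors, masks)
    rows = []
    for param, by_species in per_param_species.items():
        pooled = group_aggregate(by_species, grouping)
        for group, result in pooled.items():
            rows.append(
                {
                    "group": group,
                    "parameter": param,
                    "Nd": result.nd,
                    "Ld": result.ld,
                    "No": result.no,
                    "Lo": result.lo,
                    "rdo": result.rdo,
                }
            )
    return pd.DataFrame(rows)


def contrast_table(
    species_data: Sequence[SpeciesData],
    categories_by_protein: Mapping[tuple[str, str], str],
) -> pd.DataFrame:
    """Specific-vs-common means, s/c ratios and one-tailed p per metric.

    Disorder is contrasted as the per-protein disorder fraction; each PTM
    parameter as the per-protein density per 400 residues. Intermediate
    proteins are excluded.
    """
    metrics = ["disorder"] + list(SITE_PARAMETERS)
    buckets: dict[str, dict[str, list[float]]] = {
        m: {"specific": [], "common": []} for m in metrics
    }
    for sd in species_data:
        for row in sd.counts.itertuples(index=False):
            cat = categories_by_protein.get((sd.species_id, row.protein_id))
            if cat not in ("specific", "common"):
                continue
            buckets["disorder"][cat].append(row.disorder)
            for param in SITE_PARAMETERS:
                buckets[param][cat].append(
                    density_per_400(getattr(row, param), row.length)
                )
    rows = []
    for metric in metrics:
        spec, comm = buckets[metric]["specific"], buckets[metric]["common"]
        try:
            res = category_contrast(spec, comm)
        except (ValueError, ZeroDivisionError):
            # a category is empty, or its mean is zero (metric absent there)
            rows.append({"metric": metric, "mean_specific": np.nan,
                         "mean_common": np.nan, "ratio_s_over_c": np.nan,
                         "p_one_tailed": np.nan, "n_specific": len(spec),
                         "n_common": len(comm)})
            continue
        rows.append(
            {
                "metric": metric,
                "mean_specific": res.mean_specific,
                "mean_common": res.mean_common,
                "ratio_s_over_c": res.ratio_s_over_c,
                "p_one_tailed": res.p_one_tailed,
                "n_specific": res.n_specific,
                "n_common": res.n_common,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The run


@dataclass
class RunReport:
    config_hash: str
    version: str
    summary: pd.DataFrame  # per-species summary + densities (figure analogues)
    correlations: pd.DataFrame  # species x parameter r/p/FDR grid
    rdo: pd.DataFrame  # group x PTM pooled Rd/o
    contrast: pd.DataFrame  # specific vs common
    bin_series: dict[tuple[str, str], pd.DataFrame]
    cluster_categories: dict[str, str]


def run(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline; optionally persist all artifacts to outdir."""
    species_data: list[SpeciesData] = []
    dataset: SyntheticDataset | None = None
    grouping: dict[str, str] = dict(config.grouping)
    if config.synthetic is not None:
        dataset = generate(config.synthetic)
        for sp in dataset.species_ids:
            species_data.append(
                _assemble_species(
                    config,
                    dataset.proteome(sp),
                    dataset.masks(sp),
                    dataset.sites(sp),
                    dataset.segments(sp),
                    grouping.get(sp, "other"),
                )
            )
            grouping.setdefault(sp, "other")
    else:
        for spin in config.species:
            proteome = read_fasta(spin.fasta, spin.species_id, spin.group)
            masks = (
                load_mask_table(spin.masks, proteome, source="other")
                if spin.masks
                else {}
            )
            sites = load_site_table(spin.sites, proteome)[0] if spin.sites else []
            segments = (
                load_segment_table(spin.segments, proteome)[0] if spin.segments else []
            )
            species_data.append(
                _assemble_species(config, proteome, masks, sites, segments, spin.group)
            )
            grouping.setdefault(spin.species_id, spin.group)

    summary = density_table(species_data, config)
    correlations = correlation_table(species_data, config)
    rdo_df = rdo_table(species_data, config, grouping)

    # cluster classification across species for the specific/common contrast
    panel = [sd.species_id for sd in species_data]
    categories_by_protein: dict[tuple[str, str], str] = {}
    cluster_categories: dict[str, str] = {}
    if config.cluster_source == "truth":
        assert dataset is not None
        truth = dataset.truth()
        for row in truth.itertuples(index=False):
            categories_by_protein[(row.species_id, row.protein_id)] = row.category
    else:
        if config.cluster_source == "file":
            catalog = read_cluster_table(config.cluster_file)
        else:
            all_records = [p.record for sd in species_data for p in sd.annotated]
            catalog = build_clusters(all_records, config.identity)
        cluster_categories = classify_clusters(catalog, panel)
        for cluster in catalog:
            cat = cluster_categories[cluster.cluster_id]
            for member in cluster.members:
                categories_by_protein[member] = cat
    contrast = contrast_table(species_data, categories_by_protein)

    bin_series: dict[tuple[str, str], pd.DataFrame] = {}
    for sd in species_data:
        for param in PARAMETERS:
            try:
                series = bin_by_site_count(
                    sd.counts[param].to_numpy(),
                    sd.counts["disorder"].to_numpy(),
                    parameter=param,
                    cap=config.bin_cap,
                )
            except ValueError:
                continue
            bin_series[(sd.species_id, param)] = pd.DataFrame(
                [
                    {
                        "bin": b.label,
                        "bin_index": b.index,
                        "n_proteins": b.n_proteins,
                        "mean_disorder": b.mean_disorder,
                    }
                    for b in series.bins
                ]
            )

    report = RunReport(
        config_hash=config.config_hash(),
        version=__version__,
        summary=summary,
        correlations=correlations,
        rdo=rdo_df,
        contrast=contrast,
        bin_series=bin_series,
        cluster_categories=cluster_categories,
    )
    if outdir is not None:
        report_tables(report, outdir)
        if dataset is not None:
            dataset.write(Path(outdir) / "synthetic_inputs")
    return report


def _sig1(p: float) -> str:
    """One-significant-figure scientific display, e.g. 1.7e-05 -> '2e-05'."""
    if not np.isfinite(p):
        return ""
    return f"{p:.0e}"


def report_tables(report: RunReport, outdir: str | Path) -> None:
    """Persist the report as TSVs with fixed column order.

    p and FDR columns keep full precision in ``*_value`` columns and carry a
    one-significant-figure display column alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    corr = report.correlations.copy()
    corr["p_display"] = corr["p_one_tailed"].map(_sig1)
    corr["fdr_display"] = corr["fdr"].map(_sig1)
    corr = corr[
        ["species_id", "parameter", "r", "p_one_tailed", "fdr",
         "p_display", "fdr_display", "n_bins", "direction"]
    ]
    corr.to_csv(outdir / "correlations.tsv", sep="\t", index=False)

    report.rdo.to_csv(outdir / "rdo.tsv", sep="\t", index=False)

    contrast = report.contrast.copy()
    contrast["p_display"] = contrast["p_one_tailed"].map(_sig1)
    contrast.to_csv(outdir / "contrast.tsv", sep="\t", index=False)

    bins_dir = outdir / "bins"
    bins_dir.mkdir(exist_ok=True)
    for (sp, param), df in report.bin_series.items():
        df.to_csv(bins_dir / f"{sp}.{param}.tsv", sep="\t", index=False)

    with open(outdir / "provenance.yaml", "w") as handle:
        yaml.safe_dump(
            {"config_hash": report.config_hash, "version": report.version},
            handle,
        )
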
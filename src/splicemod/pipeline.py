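"""End-to-end orchestration: filter -> significance -> clustering -> motif
-> RBP -> rescue -> expression, with machine-readable reports.

The pipeline consumes a bundle directory laid out the way the synthetic
generator writes it (and the way a real study would be arranged)::

    bundle/
      rmats/<cell>/<contrast>/<TYPE>.MATS.JC.txt
      genome.fa
      annotation_boundaries.tsv
      peaks/manifest.tsv + BED files
      gene_counts.tsv

Contrast directories are named ``<group1>_vs_<group2>``; the drug
response contrasts (``*_DMSO_vs_*_Drug``) feed the ΔPSI cluster matrix,
and the disease contrasts (``Ctrl_DMSO_vs_HD_*``) feed the RBP and rescue
stages.  Every stage is a pure function of (inputs, config); rerunning
with the same inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import clustering, expression, motifs, rbp, rescue
from .events import (
    ComparisonSet,
    comparison_from_rows,
    coverage_filter,
    export_significant,
    significant_events,
)
from .io_formats import (
    read_boundary_set,
    read_fasta,
    read_gene_counts,
    read_peak_manifest,
    read_peaks,
    read_rmats_table,
)

logger = logging.getLogger(__name__)

HD_CONTRAST = "Ctrl_DMSO_vs_HD_DMSO"
HD_DRUG_CONTRAST = "Ctrl_DMSO_vs_HD_Drug"
DRUG_CONTRASTS = ("Ctrl_DMSO_vs_Ctrl_Drug", "HD_DMSO_vs_HD_Drug")


class ConfigError(ValueError):
    """Invalid pipeline configuration or missing input path."""


@dataclass
class PipelineConfig:
    bundle_dir: Path
    out_dir: Path
    coverage_min: int = 10
    fdr_max: float = 0.05
    min_abs_delta: float = 0.1
    rescue_threshold: float = 0.1
    rescue_min_reads: int = 10
    peak_min_neg_log10_p: float = 3.0
    peak_min_log2fc: float = 3.0
    kmeans_k: int = 10
    kmeans_seed: int = 42
    kmeans_n_init: int = 10
    kmeans_max_iter: int = 300
    imputation_value: float = 0.0
    motif_flank: int = 5
    motif_k_sizes: tuple[int, ...] = (4, 6, 8)

    def __post_init__(self) -> None:
        self.bundle_dir = Path(self.bundle_dir)
        self.out_dir = Path(self.out_dir)
        for name in (
            "coverage_min", "fdr_max", "min_abs_delta", "rescue_threshold",
            "peak_min_neg_log10_p", "peak_min_log2fc", "kmeans_k",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not self.bundle_dir.is_dir():
            raise ConfigError(f"bundle directory not found: {self.bundle_dir}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Flat key-value config file; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "motif_k_sizes" in raw:
            raw["motif_k_sizes"] = tuple(raw["motif_k_sizes"])
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc))

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded, so reruns into
        different directories compare equal)."""
        payload = {
            k: str(v)
            for k, v in asdict(self).items()
            if k not in ("bundle_dir", "out_dir")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def discover_comparisons(bundle_dir: Path) -> dict[str, Path]:
    """Map comparison label ``cell/contrast`` to its rMATS table directory."""
    rmats_dir = Path(bundle_dir) / "rmats"
    if not rmats_dir.is_dir():
        raise ConfigError(f"no rmats/ directory under {bundle_dir}")
    out: dict[str, Path] = {}
    for cell_dir in sorted(p for p in rmats_dir.iterdir() if p.is_dir()):
        for contrast_dir in sorted(p for p in cell_dir.iterdir() if p.is_dir()):
            out[f"{cell_dir.name}/{contrast_dir.name}"] = contrast_dir
    if not out:
        raise ConfigError(f"no comparison directories under {rmats_dir}")
    return out


def load_comparison(
    table_dir: Path, label: str, boundary_set: set[tuple[str, int]]
) -> ComparisonSet:
    g1, _, g2 = label.split("/")[-1].partition("_vs_")
    rows = []
    for path in sorted(table_dir.glob("*.MATS.JC.txt")):
        event_type = path.name.split(".")[0]
        rows.extend(read_rmats_table(path, event_type))
    return comparison_from_rows(
        rows, label=label, group1_name=g1, group2_name=g2,
        boundary_set=boundary_set,
    )


@dataclass
class PipelineResult:
    summary: dict
    detected: dict[str, ComparisonSet]
    significant: dict[str, ComparisonSet]
    matrix: clustering.DeltaPsiMatrix | None = None
    assignment: clustering.ClusterAssignment | None = None
    rescue_records: dict[str, list[rescue.RescueRecord]] = field(default_factory=dict)


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write per-stage tables plus summary.json."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    try:
        result = _run_stages(config)
    except Exception as exc:
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
    return result


def _run_stages(config: PipelineConfig) -> PipelineResult:
    bundle, out = config.bundle_dir, config.out_dir
    summary: dict = {"config_digest": config.digest()}

    boundary_set = read_boundary_set(bundle / "annotation_boundaries.tsv")
    comparisons = {
        label: load_comparison(table_dir, label, boundary_set)
        for label, table_dir in discover_comparisons(bundle).items()
    }
    cells = sorted({label.split("/")[0] for label in comparisons})

    # stage: coverage + significance filtering
    detected = {
        label: coverage_filter(cs, config.coverage_min)
        for label, cs in comparisons.items()
    }
    significant = {
        label: significant_events(cs, config.fdr_max, config.min_abs_delta)
        for label, cs in detected.items()
    }
    summary["comparisons"] = {
        label: {
            "n_total": len(comparisons[label]),
            "n_detected": len(detected[label]),
            "n_significant": len(significant[label]),
        }
        for label in sorted(comparisons)
    }
    sig_dir = out / "significant"
    sig_dir.mkdir(exist_ok=True)
    for label, cs in significant.items():
        export_significant(cs, sig_dir / (label.replace("/", "__") + ".tsv"))

    # stage: ΔPSI matrix + clustering over the drug-response contrasts
    drug_labels = [
        label
        for label in comparisons
        if label.split("/")[-1] in DRUG_CONTRASTS
    ]
    matrix = assignment = None
    coherent_included: list[int] = []
    if drug_labels and any(len(significant[l]) for l in drug_labels):
        matrix = clustering.build_matrix(
            {l: significant[l] for l in drug_labels},
            {l: detected[l] for l in drug_labels},
        )
        n_rows = len(matrix.event_keys)
        k = config.kmeans_k
        if n_rows < k:
            k = max(2, n_rows // 2)
            logger.warning(
                "only %d matrix rows; k reduced from %d to %d",
                n_rows, config.kmeans_k, k,
            )
        if n_rows >= 2 and k >= 2:
            assignment = clustering.cluster_events(
                matrix, k=k, seed=config.kmeans_seed,
                n_init=config.kmeans_n_init, max_iter=config.kmeans_max_iter,
                imputation_value=config.imputation_value,
            )
            clustering.export_matrix(matrix, assignment, out / "delta_psi_matrix.tsv")
            clusters = {}
            for cid in range(k):
                if not assignment.members(cid):
                    continue
                cs_ = clustering.cluster_summary(matrix, assignment, cid)
                clusters[str(cid)] = {
                    "size": cs_.size,
                    "novel_fraction": round(cs_.novel_fraction, 4),
                    "coherent": cs_.coherent,
                    "direction": cs_.direction,
                    "mean_delta": round(cs_.mean_delta, 4),
                }
                if cs_.coherent and cs_.direction == "included":
                    coherent_included.append(cid)
            summary["clusters"] = {
                "k": k,
                "n_events": n_rows,
                "per_cluster": clusters,
                "coherent_included": coherent_included,
            }

    # stage: splice-site k-mer enrichment on drug-responsive novel exons
    motif_cfg = motifs.MotifWindowConfig(
        flank=config.motif_flank, k_sizes=tuple(config.motif_k_sizes)
    )
    foreground_keys: set[str] = set()
    if assignment is not None:
        for cid in coherent_included:
            foreground_keys.update(assignment.members(cid))
    if not foreground_keys:
        for label in drug_labels:
            foreground_keys.update(
                key
                for key, q in significant[label].events.items()
                if q.event.novel_ss
            )
    fg_events = []
    seen = set()
    for label in drug_labels:
        for key in sorted(foreground_keys):
            q = detected[label].events.get(key)
            if q is not None and key not in seen and q.event.event_type == "SE":
                fg_events.append(q.event)
                seen.add(key)
    top_kmers: dict[str, dict] = {}
    if fg_events and (bundle / "genome.fa").exists():
        genome = read_fasta(bundle / "genome.fa")
        windows = motifs.extract_windows(fg_events, genome, motif_cfg)
        enrichments = motifs.site_enrichments(windows, motif_cfg)
        motifs.export_enrichments(enrichments, out / "kmer_enrichment.tsv")
        for (site, k_), records in enrichments.items():
            if records:
                best = records[0]
                top_kmers[f"{site}_{k_}mer"] = {
                    "kmer": best.kmer,
                    "pvalue": best.pvalue,
                    "fg_freq": round(best.relative_frequency_fg, 4),
                }
    summary["top_kmers"] = top_kmers
    summary["n_motif_foreground_events"] = len(fg_events)

    # stage: RBP binding enrichment at disease events
    manifest_path = bundle / "peaks" / "manifest.tsv"
    bound_by_rbp: dict[str, dict[str, set[str]]] = {}
    if manifest_path.exists():
        manifest = read_peak_manifest(manifest_path)
        pooled: dict[str, list] = {}
        for _, row in manifest.iterrows():
            peaks = read_peaks(
                bundle / "peaks" / row["file"],
                rbp_name=row["rbp_name"], cell_line=row["cell_line"],
            )
            pooled.setdefault(row["rbp_name"], []).extend(peaks)
        significant_peaks = {
            name: rbp.filter_peaks(
                peaks, config.peak_min_neg_log10_p, config.peak_min_log2fc
            )
            for name, peaks in pooled.items()
        }
        summary["rbp_enrichment"] = {}
        for cell in cells:
            label = f"{cell}/{HD_CONTRAST}"
            if label not in comparisons:
                continue
            background = detected[label]
            foreground = significant[label]
            regions = [
                rbp.event_region(q.event) for q in background.events.values()
            ]
            bound = {
                name: rbp.events_bound(regions, peaks)
                for name, peaks in significant_peaks.items()
            }
            bound_by_rbp[cell] = bound
            records = rbp.rbp_enrichment(
                foreground.keys(), background.keys(), bound
            )
            rbp.export_enrichments(
                records, out / f"rbp_enrichment_{cell}.tsv"
            )
            summary["rbp_enrichment"][cell] = [
                {
                    "rbp": r.rbp_name, "fold": round(r.fold_enrichment, 4),
                    "pvalue": r.pvalue, "k": r.k_bound, "n": r.n,
                }
                for r in records[:5]
            ]

    # stage: rescue quantification
    summary["rescue"] = {}
    summary["drug_vs_disease_overlap"] = {}
    rescue_records_by_cell: dict[str, list[rescue.RescueRecord]] = {}
    for cell in cells:
        hd_label = f"{cell}/{HD_CONTRAST}"
        drug_label = f"{cell}/{HD_DRUG_CONTRAST}"
        if hd_label not in comparisons or drug_label not in comparisons:
            continue
        records, n_excluded = rescue.rescue_records(
            significant[hd_label],
            comparisons[hd_label],
            comparisons[drug_label],
            rescue_threshold=config.rescue_threshold,
            min_reads=config.rescue_min_reads,
        )
        rescue_records_by_cell[cell] = records
        rescue.export_records(records, out / f"rescue_{cell}.tsv")
        if records:
            rs = rescue.rescue_summary(records)
            summary["rescue"][cell] = {
                "n_events": rs.n_events,
                "n_excluded": n_excluded,
                "mean_abs_diff_dmso": round(rs.mean_abs_diff_dmso, 4),
                "mean_abs_diff_drug": round(rs.mean_abs_diff_drug, 4),
                "percent_reduction": round(rs.percent_reduction, 2),
                "rescued_fraction": round(rs.rescued_fraction, 4),
                "n_rescued": rs.n_rescued,
                "n_still_included": rs.n_still_included,
                "n_still_excluded": rs.n_still_excluded,
                "ranksum_p": rs.ranksum_p,
            }
            # RBP binding in rescued vs unrescued disease events
            if cell in bound_by_rbp:
                rescued_set = {r.key for r in records if r.rescued}
                unrescued_set = {r.key for r in records if not r.rescued}
                contrasts = {}
                for name, bound in sorted(bound_by_rbp[cell].items()):
                    bc = rbp.rescued_vs_unrescued_binding(
                        rescued_set, unrescued_set, bound
                    )
                    contrasts[name] = {
                        "odds_ratio": bc.odds_ratio, "pvalue": bc.pvalue,
                        "table": [list(r) for r in bc.table],
                    }
                summary["rescue"][cell]["rbp_binding_contrast"] = contrasts
        # does the drug directly target the disease events?
        drug_keys: set[str] = set()
        for contrast in DRUG_CONTRASTS:
            label = f"{cell}/{contrast}"
            if label in significant:
                drug_keys |= significant[label].keys()
        report = rescue.drug_targets_disease_events(
            significant[hd_label].keys(), drug_keys
        )
        summary["drug_vs_disease_overlap"][cell] = {
            "n_hd": report.n_a, "n_drug": report.n_b,
            "n_overlap": len(report.intersection),
            "jaccard": round(report.jaccard, 4),
        }

    # stage: expression
    counts_path = bundle / "gene_counts.tsv"
    if counts_path.exists():
        counts = read_gene_counts(counts_path)
        rpkm_df = expression.rpkm_table(counts)
        rpkm_df.to_csv(out / "rpkm.tsv", sep="\t", index_label="gene_id")
        samples = list(rpkm_df.columns)
        comp_groups: dict[str, tuple[list[str], list[str]]] = {}
        for cell in cells:
            for genotype in ("Ctrl", "HD"):
                treated = [
                    s for s in samples if s.startswith(f"{cell}_{genotype}_Drug_")
                ]
                vehicle = [
                    s for s in samples if s.startswith(f"{cell}_{genotype}_DMSO_")
                ]
                if treated and vehicle:
                    comp_groups[f"{cell}/{genotype}"] = (treated, vehicle)
        if comp_groups:
            ratios = expression.log2_ratio_table(rpkm_df, comp_groups)
            ratios.to_csv(out / "expression_log2_ratio.tsv", sep="\t",
                          index_label="gene_id")
            up, down = expression.consistent_direction_genes(ratios)
            summary["expression"] = {
                "comparisons": sorted(comp_groups),
                "consistent_up": sorted(up),
                "consistent_down": sorted(down),
            }

    return PipelineResult(
        summary=summary,
        detected=detected,
        significant=significant,
        matrix=matrix,
        assignment=assignment,
        rescue_records=rescue_records_by_cell,
    )
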
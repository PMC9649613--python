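"""Truth-annotated synthetic four-condition splicing dataset.

The generator emulates the data structure of a splice-modulator study in
two cell types (fibroblasts, 4 replicates per group; cortical neurons, 3)
with four condition groups each (Ctrl/HD x DMSO/drug).  Per event the
per-sample PSI is a truncated normal around the group mean, junction
counts are a binomial split of a Poisson read total with the inclusion
probability weighted by the effective form lengths — so the standard
length-normalized PSI formula inverts the simulation exactly in
expectation.  Planted structure:

* disease (HD) events with a Ctrl-vs-HD ΔPSI drawn from ±[0.15, 0.6],
  a configurable fraction of which the drug reverts to the Ctrl level;
* drug-induced novel exons (near-zero PSI under DMSO, high under drug)
  whose target splice sites are absent from the annotation boundary set
  and carry chosen splice-site motifs in the genome;
* scattered drug-responsive events with an independent response per
  cohort (cluster-analysis background);
* per-RBP eCLIP-style peak files with planted bound-event sets and a
  binding bias toward rescued events for the first RBP;
* gene counts with planted consistent drug expression effects.

Emitted files are rMATS-dialect junction-count tables (one per AS type
per comparison), a genome FASTA, an annotation exon-boundary list, BED6+2
peak files with a manifest, a gene-count table and a truth JSON.  The
same seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import ttest_ind, truncnorm
from statsmodels.stats.multitest import multipletests

from .io_formats import (
    RmatsRow,
    write_boundary_set,
    write_fasta,
    write_gene_counts,
    write_peaks,
    write_rmats_table,
    PeakRecord,
)
from .motifs import reverse_complement

GROUPS = ("Ctrl_DMSO", "Ctrl_Drug", "HD_DMSO", "HD_Drug")

#: (contrast name, group 1 = reference, group 2 = target)
CONTRASTS = (
    ("Ctrl_DMSO_vs_Ctrl_Drug", "Ctrl_DMSO", "Ctrl_Drug"),
    ("HD_DMSO_vs_HD_Drug", "HD_DMSO", "HD_Drug"),
    ("Ctrl_DMSO_vs_HD_DMSO", "Ctrl_DMSO", "HD_DMSO"),
    ("Ctrl_DMSO_vs_HD_Drug", "Ctrl_DMSO", "HD_Drug"),
)

DRUG_CONTRASTS = ("Ctrl_DMSO_vs_Ctrl_Drug", "HD_DMSO_vs_HD_Drug")

ALT_TYPES = ("A3SS", "A5SS", "MXE", "RI")


@dataclass
class SimConfig:
    """Study-structure parameters; defaults mirror the emulated design."""

    seed: int = 0
    n_se: int = 60
    n_alt: int = 5                 # events per non-SE AS type
    n_hd: int = 30                 # disease-affected events
    n_drug: int = 20               # drug-induced novel exons (SE only)
    n_scattered: int = 12          # cohort-independent drug responders
    n_low_coverage: int = 4        # scattered events undersampled in the last cell type
    cell_types: dict[str, int] = field(
        default_factory=lambda: {"fibroblast": 4, "neuron": 3}
    )
    mean_depth: float = 100.0
    low_depth: float = 4.0
    psi_sigma: float = 0.05
    hd_delta_range: tuple[float, float] = (0.15, 0.6)
    drug_dmso_psi: tuple[float, float] = (0.01, 0.08)
    drug_treated_psi: tuple[float, float] = (0.5, 0.9)
    drug_cluster_deltas: tuple[float, ...] = ()
    rescue_fraction: float = 0.5
    hd_drug_effect: str = "rescue"   # "rescue" or "none" (null: drug inert on HD events)
    five_prime_motif: str = "AGAGTAAG"
    three_prime_motif: str = "TTCAGTTT"
    motif_frequency: float = 1.0
    flank: int = 5
    motif_offset: int = 1
    inc_form_len: int = 2
    skip_form_len: int = 1
    rbp_names: tuple[str, ...] = ("QKI", "RBFOX2", "CELF1", "TARDBP")
    rbp_bound_fraction: float = 0.3
    rescued_bias: tuple[float, float] = (0.7, 0.15)  # first RBP: P(bound | rescued/unrescued)
    n_decoy_peaks: int = 20
    n_expr_up: int = 3
    n_expr_down: int = 3
    expr_baseline: tuple[float, float] = (50.0, 500.0)
    expr_lfc_range: tuple[float, float] = (0.5, 1.5)
    n_contigs: int = 2
    boundary_overrides: bool = False  # plant exact-threshold rows (unit fixtures)

    def __post_init__(self) -> None:
        if not 0.0 <= self.rescue_fraction <= 1.0:
            raise ValueError("rescue fraction must lie in [0, 1]")
        if len(self.five_prime_motif) > 2 * self.flank or len(
            self.three_prime_motif
        ) > 2 * self.flank:
            raise ValueError("motif longer than the splice-site window")
        if self.motif_offset + max(
            len(self.five_prime_motif), len(self.three_prime_motif)
        ) > 2 * self.flank:
            raise ValueError("motif does not fit the window at this offset")
        if self.n_drug + (4 if self.boundary_overrides else 0) > self.n_se:
            raise ValueError("not enough SE events for the planted categories")
        if self.n_expr_up + self.n_expr_down > self.n_drug:
            raise ValueError("not enough drug events to carry expression effects")
        n_total = self.n_se + 4 * self.n_alt
        if self.n_drug + self.n_hd + self.n_scattered > n_total:
            raise ValueError("planted categories exceed the event count")
        if self.hd_drug_effect not in ("rescue", "none"):
            raise ValueError("hd_drug_effect must be 'rescue' or 'none'")


@dataclass
class _Event:
    idx: int
    event_type: str
    chrom: str
    strand: str
    coords: tuple[int, ...]
    gene_id: str
    gene_symbol: str
    category: str = "background"
    rescued: bool = False
    drug_cluster: int | None = None
    low_coverage: bool = False
    has_motif: bool = False
    psi: dict = field(default_factory=dict)     # (cell, group) -> true mean PSI

    @property
    def key(self) -> str:
        coords = "-".join(str(c) for c in self.coords)
        return f"{self.event_type}|{self.chrom}|{self.strand}|{coords}"

    @property
    def region(self) -> tuple[int, int]:
        return (min(self.coords), max(self.coords))

    def exon_pairs(self) -> list[tuple[int, int]]:
        return list(zip(self.coords[::2], self.coords[1::2]))


@dataclass
class TruthBundle:
    """Ground truth and file paths for one generated dataset."""

    config: SimConfig
    out_dir: Path
    genome_path: Path
    boundary_path: Path
    counts_path: Path
    manifest_path: Path
    truth_path: Path
    table_paths: dict[str, dict[str, Path]]      # comparison label -> type -> path
    comparison_groups: dict[str, tuple[str, str]]
    samples: dict[str, list[str]]                # "cell:group" -> sample names
    event_category: dict[str, str]
    hd_keys: set[str]
    drug_keys: set[str]
    rescued_keys: set[str]
    motif_keys: set[str]
    novel_keys: set[str]
    drug_cluster_labels: dict[str, int]
    true_psi: dict[str, dict[str, float]]        # key -> "cell:group" -> mean PSI
    coverage_pass: dict[str, set[str]]           # comparison label -> keys
    significant: dict[str, set[str]]
    rbp_bound: dict[str, set[str]]
    peak_counts: dict[str, tuple[int, int]]      # rbp -> (n significant, n total)
    expr_up: set[str]
    expr_down: set[str]
    expr_up_realized: set[str]
    expr_down_realized: set[str]
    event_gene: dict[str, str]
    true_rescued_fraction: float
    true_percent_reduction: dict[str, float]     # per cell, from latent group means
    expected_percent_reduction: dict[str, float]  # per cell, from realized sample PSIs

    @property
    def drug_comparisons(self) -> list[str]:
        return [
            f"{cell}/{contrast}"
            for cell in self.config.cell_types
            for contrast in DRUG_CONTRASTS
        ]


def _layout_event(
    rng: np.random.Generator, event_type: str, cursor: int
) -> tuple[tuple[int, ...], int]:
    """Place one event's exons after ``cursor``; returns (coords, new cursor)."""

    def exon(lo: int = 80, hi: int = 160) -> int:
        return int(rng.integers(lo, hi))

    def intron(lo: int = 150, hi: int = 400) -> int:
        return int(rng.integers(lo, hi))

    a = cursor + int(rng.integers(60, 120))
    if event_type == "SE":
        us, ue = a, a + exon()
        ts = ue + intron()
        te = ts + exon(60, 140)
        ds = te + intron()
        de = ds + exon()
        return (ts, te, us, ue, ds, de), de
    if event_type in ("A3SS", "A5SS"):
        fs, fe = a, a + exon()
        ls = fe + intron()
        le = ls + exon(90, 160)
        if event_type == "A3SS":
            ss, se_ = ls + 30, le            # shorter exon: later acceptor
        else:
            ss, se_ = ls, le - 30            # shorter exon: earlier donor
        return (ls, le, ss, se_, fs, fe), le
    if event_type == "MXE":
        us, ue = a, a + exon()
        s1 = ue + intron()
        e1 = s1 + exon(60, 120)
        s2 = e1 + intron()
        e2 = s2 + exon(60, 120)
        ds = e2 + intron()
        de = ds + exon()
        return (s1, e1, s2, e2, us, ue, ds, de), de
    if event_type == "RI":
        us, ue = a, a + exon()
        ds = ue + intron()
        de = ds + exon()
        return (us, de, us, ue, ds, de), de
    raise ValueError(event_type)


def _sample_psi(
    rng: np.random.Generator, means: np.ndarray, sigma: float, n_reps: int
) -> np.ndarray:
    """Per-sample PSI ~ truncated normal(mean, sigma) on [0, 1]."""
    loc = np.repeat(means[:, None], n_reps, axis=1)
    a = (0.0 - loc) / sigma
    b = (1.0 - loc) / sigma
    return truncnorm.rvs(a, b, loc=loc, scale=sigma, random_state=rng)


def generate(cfg: SimConfig, out_dir: str | Path) -> TruthBundle:
    """Write the full synthetic bundle under ``out_dir`` and return truth."""
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- event geometry -------------------------------------------------
    events: list[_Event] = []
    cursors = {f"chr{i + 1}": 100 for i in range(cfg.n_contigs)}
    contigs = list(cursors)
    type_plan = ["SE"] * cfg.n_se + [t for t in ALT_TYPES for _ in range(cfg.n_alt)]
    for idx, event_type in enumerate(type_plan):
        chrom = contigs[idx % len(contigs)]
        coords, end = _layout_event(rng, event_type, cursors[chrom])
        cursors[chrom] = end
        strand = "+" if event_type != "SE" else ("+", "-")[int(rng.integers(0, 2))]
        events.append(
            _Event(
                idx=idx, event_type=event_type, chrom=chrom, strand=strand,
                coords=coords, gene_id=f"G{idx:04d}", gene_symbol=f"SYM{idx}",
            )
        )

    # --- category assignment -------------------------------------------
    se_events = [e for e in events if e.event_type == "SE"]
    for i, e in enumerate(se_events[: cfg.n_drug]):
        e.category = "drug"
        e.has_motif = bool(rng.random() < cfg.motif_frequency)
        if cfg.drug_cluster_deltas:
            e.drug_cluster = i % len(cfg.drug_cluster_deltas)
    remaining = [e for e in events if e.category == "background"]
    if cfg.boundary_overrides:
        for e, cat in zip(remaining[-4:], ("cov10", "cov9", "fdr_edge", "delta_edge")):
            e.category = cat
        remaining = [e for e in remaining if e.category == "background"]
    for e in remaining[: cfg.n_hd]:
        e.category = "hd"
        e.rescued = bool(rng.random() < cfg.rescue_fraction)
    for e in remaining[cfg.n_hd : cfg.n_hd + cfg.n_scattered]:
        e.category = "scattered"
    scattered = [e for e in events if e.category == "scattered"]
    for e in scattered[: cfg.n_low_coverage]:
        e.low_coverage = True

    # --- true group-mean PSI --------------------------------------------
    cells = list(cfg.cell_types)
    for e in events:
        base = float(rng.uniform(0.2, 0.8))
        if e.category == "drug":
            dmso = float(rng.uniform(*cfg.drug_dmso_psi))
            if e.drug_cluster is not None:
                treated = float(
                    np.clip(dmso + cfg.drug_cluster_deltas[e.drug_cluster], 0.02, 0.98)
                )
            else:
                treated = float(rng.uniform(*cfg.drug_treated_psi))
            for cell in cells:
                e.psi[(cell, "Ctrl_DMSO")] = dmso
                e.psi[(cell, "HD_DMSO")] = dmso
                e.psi[(cell, "Ctrl_Drug")] = treated
                e.psi[(cell, "HD_Drug")] = treated
        elif e.category == "hd":
            sign = 1.0 if rng.random() < 0.5 else -1.0
            delta = sign * float(rng.uniform(*cfg.hd_delta_range))
            hd_level = float(np.clip(base + delta, 0.02, 0.98))
            if cfg.hd_drug_effect == "none":
                hd_drug = hd_level
            else:
                hd_drug = base if e.rescued else hd_level
            for cell in cells:
                e.psi[(cell, "Ctrl_DMSO")] = base
                e.psi[(cell, "Ctrl_Drug")] = base
                e.psi[(cell, "HD_DMSO")] = hd_level
                e.psi[(cell, "HD_Drug")] = hd_drug
        elif e.category == "scattered":
            for cell in cells:
                e.psi[(cell, "Ctrl_DMSO")] = base
                e.psi[(cell, "HD_DMSO")] = base
                for genotype in ("Ctrl", "HD"):
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    delta = sign * float(rng.uniform(0.15, 0.6))
                    e.psi[(cell, f"{genotype}_Drug")] = float(
                        np.clip(base + delta, 0.02, 0.98)
                    )
        elif e.category in ("fdr_edge", "delta_edge"):
            shifted = float(np.clip(base + 0.3, 0.02, 0.98))
            for cell in cells:
                e.psi[(cell, "Ctrl_DMSO")] = base
                for group in ("Ctrl_Drug", "HD_DMSO", "HD_Drug"):
                    e.psi[(cell, group)] = shifted
        else:  # background, cov10, cov9: flat
            for cell in cells:
                for group in GROUPS:
                    e.psi[(cell, group)] = base

    # --- genome with planted splice-site motifs --------------------------
    genome_arrays = {
        chrom: rng.integers(0, 4, size=end + 200).astype(np.uint8)
        for chrom, end in cursors.items()
    }
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    lookup = {ord(b): i for i, b in enumerate("ACGT")}

    def plant(e: _Event, boundary: int, motif: str) -> None:
        arr = genome_arrays[e.chrom]
        lo, hi = boundary - cfg.flank, boundary + cfg.flank
        window = "".join("ACGT"[c] for c in arr[lo:hi])
        sense = reverse_complement(window) if e.strand == "-" else window
        sense = (
            sense[: cfg.motif_offset]
            + motif
            + sense[cfg.motif_offset + len(motif):]
        )
        genomic = reverse_complement(sense) if e.strand == "-" else sense
        arr[lo:hi] = [lookup[ord(c)] for c in genomic]

    for e in events:
        if e.category == "drug" and e.has_motif:
            ts, te = e.coords[0], e.coords[1]
            if e.strand == "-":
                plant(e, ts, cfg.five_prime_motif)
                plant(e, te, cfg.three_prime_motif)
            else:
                plant(e, ts, cfg.three_prime_motif)
                plant(e, te, cfg.five_prime_motif)

    genome = {
        chrom: bases[arr].tobytes().decode() for chrom, arr in genome_arrays.items()
    }
    genome_path = out_dir / "genome.fa"
    write_fasta(genome, genome_path)

    # --- annotation boundary set (novel exons' target sites omitted) -----
    boundaries: set[tuple[str, int, str, str]] = set()
    for e in events:
        pairs = e.exon_pairs()
        if e.category == "drug":
            pairs = pairs[1:]  # target exon unannotated -> novelSS
        for s, ee in pairs:
            boundaries.add((e.chrom, s, "start", e.strand))
            boundaries.add((e.chrom, ee, "end", e.strand))
    boundary_path = out_dir / "annotation_boundaries.tsv"
    write_boundary_set(boundaries, boundary_path)

    # --- per-sample PSI and junction counts ------------------------------
    n = len(events)
    means = {
        (cell, group): np.array([e.psi[(cell, group)] for e in events])
        for cell in cells
        for group in GROUPS
    }
    psi_s: dict[tuple[str, str], np.ndarray] = {}
    ijc: dict[tuple[str, str], np.ndarray] = {}
    sjc: dict[tuple[str, str], np.ndarray] = {}
    last_cell = cells[-1]
    depth_base = {
        cell: np.where(
            np.array([e.low_coverage for e in events]) & (cell == last_cell),
            cfg.low_depth,
            cfg.mean_depth,
        )
        for cell in cells
    }
    ifl, sfl = cfg.inc_form_len, cfg.skip_form_len
    for cell in cells:
        n_reps = cfg.cell_types[cell]
        for group in GROUPS:
            psi = _sample_psi(rng, means[(cell, group)], cfg.psi_sigma, n_reps)
            totals = rng.poisson(
                np.repeat(depth_base[cell][:, None], n_reps, axis=1)
            )
            for e in events:  # exact-threshold coverage rows
                if e.category == "cov10":
                    totals[e.idx, :] = 10
                elif e.category == "cov9":
                    totals[e.idx, :] = 50
                    totals[e.idx, 0] = 9
            p_inc = psi * ifl / (psi * ifl + (1.0 - psi) * sfl)
            inc = rng.binomial(totals, p_inc)
            psi_s[(cell, group)] = psi
            ijc[(cell, group)] = inc
            sjc[(cell, group)] = totals - inc

    samples = {
        f"{cell}:{group}": [
            f"{cell}_{group}_{r + 1}" for r in range(cfg.cell_types[cell])
        ]
        for cell in cells
        for group in GROUPS
    }

    # truth-implied rescue statistic, re-derived brute-force from the
    # realized per-sample PSIs over all disease events: it carries the same
    # replicate noise the pipeline's group-mean estimates see
    hd_idx = np.array([e.idx for e in events if e.category == "hd"], dtype=int)
    expected_percent_reduction: dict[str, float] = {}
    for cell in cells:
        if hd_idx.size == 0:
            expected_percent_reduction[cell] = 0.0
            continue
        ctrl = psi_s[(cell, "Ctrl_DMSO")][hd_idx].mean(axis=1)
        hd_dmso = psi_s[(cell, "HD_DMSO")][hd_idx].mean(axis=1)
        hd_drug = psi_s[(cell, "HD_Drug")][hd_idx].mean(axis=1)
        d_dmso = np.abs(ctrl - hd_dmso).mean()
        d_drug = np.abs(ctrl - hd_drug).mean()
        expected_percent_reduction[cell] = float(100.0 * (1.0 - d_drug / d_dmso))

    # --- comparison statistics and rMATS tables ---------------------------
    def observed_psi(counts_i: np.ndarray, counts_s: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            inc = counts_i / ifl
            skip = counts_s / sfl
            psi = inc / (inc + skip)
        psi[(counts_i + counts_s) == 0] = np.nan
        return psi

    table_paths: dict[str, dict[str, Path]] = {}
    comparison_groups: dict[str, tuple[str, str]] = {}
    coverage_pass: dict[str, set[str]] = {}
    significant: dict[str, set[str]] = {}
    rmats_dir = out_dir / "rmats"
    for cell in cells:
        for contrast, g1, g2 in CONTRASTS:
            label = f"{cell}/{contrast}"
            comparison_groups[label] = (f"{cell}:{g1}", f"{cell}:{g2}")
            i1, s1 = ijc[(cell, g1)], sjc[(cell, g1)]
            i2, s2 = ijc[(cell, g2)], sjc[(cell, g2)]
            obs1, obs2 = observed_psi(i1, s1), observed_psi(i2, s2)
            with np.errstate(invalid="ignore"), warnings.catch_warnings():
                # flat events give near-identical groups; the t-test warns
                # about precision it does not need (those P values are ~1)
                warnings.simplefilter("ignore", RuntimeWarning)
                pvals = ttest_ind(
                    obs1, obs2, axis=1, equal_var=False, nan_policy="omit"
                ).pvalue
            pvals = np.where(np.isfinite(pvals), pvals, 1.0)
            fdrs = multipletests(pvals, method="fdr_bh")[1]
            delta = np.nanmean(obs1, axis=1) - np.nanmean(obs2, axis=1)

            rows_by_type: dict[str, list[RmatsRow]] = {t: [] for t in set(type_plan)}
            cov: set[str] = set()
            sig: set[str] = set()
            for e in events:
                i = e.idx
                lv1 = [None if np.isnan(v) else round(float(v), 3) for v in obs1[i]]
                lv2 = [None if np.isnan(v) else round(float(v), 3) for v in obs2[i]]
                d = None if np.isnan(delta[i]) else round(float(delta[i]), 3)
                fdr = float(fdrs[i])
                if cfg.boundary_overrides and e.category == "fdr_edge":
                    fdr = 0.05
                if cfg.boundary_overrides and e.category == "delta_edge":
                    fdr, d = 0.01, 0.1
                row = RmatsRow(
                    event_type=e.event_type,
                    event_id=str(i),
                    gene_id=e.gene_id,
                    gene_symbol=e.gene_symbol,
                    chrom=e.chrom,
                    strand=e.strand,
                    coords=e.coords,
                    ijc_s1=[int(v) for v in i1[i]],
                    sjc_s1=[int(v) for v in s1[i]],
                    ijc_s2=[int(v) for v in i2[i]],
                    sjc_s2=[int(v) for v in s2[i]],
                    inc_form_len=ifl,
                    skip_form_len=sfl,
                    pvalue=float(pvals[i]),
                    fdr=fdr,
                    inc_level_1=lv1,
                    inc_level_2=lv2,
                    inc_level_difference=d,
                )
                rows_by_type[e.event_type].append(row)
                # truth by direct scan of the emitted values
                totals = [a + b for a, b in zip(row.ijc_s1, row.sjc_s1)] + [
                    a + b for a, b in zip(row.ijc_s2, row.sjc_s2)
                ]
                if all(t >= 10 for t in totals):
                    cov.add(e.key)
                    if row.fdr < 0.05 and d is not None and abs(d) > 0.1:
                        sig.add(e.key)
            comp_dir = rmats_dir / cell / contrast
            comp_dir.mkdir(parents=True, exist_ok=True)
            table_paths[label] = {}
            for event_type, rows in sorted(rows_by_type.items()):
                path = comp_dir / f"{event_type}.MATS.JC.txt"
                write_rmats_table(rows, path, event_type)
                table_paths[label][event_type] = path
            coverage_pass[label] = cov
            significant[label] = sig

    # --- eCLIP-style peaks ------------------------------------------------
    peaks_dir = out_dir / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    rbp_bound: dict[str, set[str]] = {}
    peak_counts: dict[str, tuple[int, int]] = {}
    manifest_rows = []
    for r_i, rbp in enumerate(cfg.rbp_names):
        bound: set[str] = set()
        peaks: list[PeakRecord] = []
        for e in events:
            if r_i == 0 and e.category == "hd" and cfg.hd_drug_effect == "rescue":
                p_bound = cfg.rescued_bias[0] if e.rescued else cfg.rescued_bias[1]
            else:
                p_bound = cfg.rbp_bound_fraction
            if rng.random() >= p_bound:
                continue
            bound.add(e.key)
            lo, hi = e.region
            width = int(rng.integers(30, 80))
            start = int(rng.integers(lo, max(lo + 1, hi - width)))
            peaks.append(
                PeakRecord(
                    chrom=e.chrom, start=start, end=start + width,
                    rbp_name=rbp, cell_line="K562", strand=e.strand,
                    log2_fold_change=round(float(rng.uniform(3.0, 6.0)), 3),
                    neg_log10_p=round(float(rng.uniform(3.0, 8.0)), 3),
                )
            )
        for _ in range(cfg.n_decoy_peaks):
            e = events[int(rng.integers(0, n))]
            lo, hi = e.region
            start = int(rng.integers(lo, hi - 20))
            fail_p = rng.random() < 0.5
            peaks.append(
                PeakRecord(
                    chrom=e.chrom, start=start, end=start + 20,
                    rbp_name=rbp, cell_line="K562", strand=e.strand,
                    log2_fold_change=round(
                        float(rng.uniform(0.0, 2.9)) if not fail_p else
                        float(rng.uniform(3.0, 6.0)), 3),
                    neg_log10_p=round(
                        float(rng.uniform(0.0, 2.9)) if fail_p else
                        float(rng.uniform(3.0, 8.0)), 3),
                )
            )
        if cfg.boundary_overrides and r_i == 0:
            lo, hi = events[0].region
            peaks.append(
                PeakRecord(
                    chrom=events[0].chrom, start=lo, end=lo + 25,
                    rbp_name=rbp, cell_line="K562", strand=events[0].strand,
                    log2_fold_change=3.0, neg_log10_p=3.0,
                )
            )
            peaks.append(
                PeakRecord(
                    chrom=events[0].chrom, start=lo, end=lo + 25,
                    rbp_name=rbp, cell_line="K562", strand=events[0].strand,
                    log2_fold_change=10.0, neg_log10_p=2.99,
                )
            )
        peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
        path = peaks_dir / f"{rbp}_K562.bed"
        write_peaks(peaks, path)
        rbp_bound[rbp] = bound
        n_pass = sum(
            1 for p in peaks if p.neg_log10_p >= 3.0 and p.log2_fold_change >= 3.0
        )
        peak_counts[rbp] = (n_pass, len(peaks))
        manifest_rows.append((path.name, rbp, "K562"))
    manifest_path = peaks_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("file\trbp_name\tcell_line\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")

    # --- gene counts with planted expression effects ----------------------
    import pandas as pd

    drug_events = [e for e in events if e.category == "drug"]
    expr_up = {e.gene_id for e in drug_events[: cfg.n_expr_up]}
    expr_down = {
        e.gene_id
        for e in drug_events[cfg.n_expr_up : cfg.n_expr_up + cfg.n_expr_down]
    }
    gene_lengths = rng.integers(500, 5000, size=n)
    baseline = rng.uniform(*cfg.expr_baseline, size=n)
    lfc = np.zeros(n)
    for e in events:
        if e.gene_id in expr_up:
            lfc[e.idx] = float(rng.uniform(*cfg.expr_lfc_range))
        elif e.gene_id in expr_down:
            lfc[e.idx] = -float(rng.uniform(*cfg.expr_lfc_range))
    all_samples: list[str] = []
    for cell in cells:
        for group in GROUPS:
            all_samples.extend(samples[f"{cell}:{group}"])
    counts = {}
    for cell in cells:
        for group in GROUPS:
            lam = baseline * (2.0 ** lfc if group.endswith("_Drug") else 1.0)
            for name in samples[f"{cell}:{group}"]:
                counts[name] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts, index=[e.gene_id for e in events])
    counts_df.insert(0, "length", gene_lengths)
    counts_path = out_dir / "gene_counts.tsv"
    write_gene_counts(counts_df, counts_path)

    # realized expression truth: brute-force RPKM log2 ratios per cohort
    rpkm_brute = {
        name: counts[name] * 1e9 / (gene_lengths * counts[name].sum())
        for name in all_samples
    }
    signs = []
    for cell in cells:
        for genotype in ("Ctrl", "HD"):
            treated = np.mean(
                [rpkm_brute[s] for s in samples[f"{cell}:{genotype}_Drug"]], axis=0
            )
            vehicle = np.mean(
                [rpkm_brute[s] for s in samples[f"{cell}:{genotype}_DMSO"]], axis=0
            )
            with np.errstate(divide="ignore"):
                signs.append(np.sign(np.log2(treated / vehicle)))
    signs_arr = np.array(signs)
    gene_ids = np.array([e.gene_id for e in events])
    expr_up_realized = {str(g) for g in gene_ids[(signs_arr > 0).all(axis=0)]}
    expr_down_realized = {str(g) for g in gene_ids[(signs_arr < 0).all(axis=0)]}

    # --- truth ------------------------------------------------------------
    hd_keys = {e.key for e in events if e.category == "hd"}
    rescued_keys = (
        {e.key for e in events if e.category == "hd" and e.rescued}
        if cfg.hd_drug_effect == "rescue"
        else set()
    )
    true_percent_reduction = {}
    for cell in cells:
        dmso = np.array(
            [
                abs(e.psi[(cell, "Ctrl_DMSO")] - e.psi[(cell, "HD_DMSO")])
                for e in events
                if e.category == "hd"
            ]
        )
        drug = np.array(
            [
                abs(e.psi[(cell, "Ctrl_DMSO")] - e.psi[(cell, "HD_Drug")])
                for e in events
                if e.category == "hd"
            ]
        )
        true_percent_reduction[cell] = (
            float(100.0 * (1.0 - drug.mean() / dmso.mean())) if dmso.size else 0.0
        )
    n_hd_planted = len(hd_keys)
    bundle = TruthBundle(
        config=cfg,
        out_dir=out_dir,
        genome_path=genome_path,
        boundary_path=boundary_path,
        counts_path=counts_path,
        manifest_path=manifest_path,
        truth_path=out_dir / "truth.json",
        table_paths=table_paths,
        comparison_groups=comparison_groups,
        samples=samples,
        event_category={e.key: e.category for e in events},
        hd_keys=hd_keys,
        drug_keys={e.key for e in events if e.category == "drug"},
        rescued_keys=rescued_keys,
        motif_keys={e.key for e in events if e.has_motif},
        novel_keys={e.key for e in events if e.category == "drug"},
        drug_cluster_labels={
            e.key: e.drug_cluster for e in events if e.drug_cluster is not None
        },
        true_psi={
            e.key: {f"{cell}:{g}": e.psi[(cell, g)] for cell in cells for g in GROUPS}
            for e in events
        },
        coverage_pass=coverage_pass,
        significant=significant,
        rbp_bound=rbp_bound,
        peak_counts=peak_counts,
        expr_up=expr_up,
        expr_down=expr_down,
        expr_up_realized=expr_up_realized,
        expr_down_realized=expr_down_realized,
        event_gene={e.key: e.gene_id for e in events},
        true_rescued_fraction=(
            len(rescued_keys) / n_hd_planted if n_hd_planted else 0.0
        ),
        true_percent_reduction=true_percent_reduction,
        expected_percent_reduction=expected_percent_reduction,
    )
    _write_truth_json(bundle)
    return bundle


def _write_truth_json(bundle: TruthBundle) -> None:
    def js(value):
        if isinstance(value, set):
            return sorted(value)
        if isinstance(value, Path):
            return str(value)
        if isinstance(value, dict):
            return {str(k): js(v) for k, v in value.items()}
        if isinstance(value, (list, tuple)):
            return [js(v) for v in value]
        return value

    payload = {
        "config": js(asdict(bundle.config)),
        "samples": js(bundle.samples),
        "event_category": js(bundle.event_category),
        "hd_keys": js(bundle.hd_keys),
        "drug_keys": js(bundle.drug_keys),
        "rescued_keys": js(bundle.rescued_keys),
        "motif_keys": js(bundle.motif_keys),
        "novel_keys": js(bundle.novel_keys),
        "drug_cluster_labels": js(bundle.drug_cluster_labels),
        "coverage_pass": js(bundle.coverage_pass),
        "significant": js(bundle.significant),
        "rbp_bound": js(bundle.rbp_bound),
        "peak_counts": js(bundle.peak_counts),
        "expr_up": js(bundle.expr_up),
        "expr_down": js(bundle.expr_down),
        "expr_up_realized": js(bundle.expr_up_realized),
        "expr_down_realized": js(bundle.expr_down_realized),
        "true_rescued_fraction": bundle.true_rescued_fraction,
        "true_percent_reduction": js(bundle.true_percent_reduction),
        "expected_percent_reduction": js(bundle.expected_percent_reduction),
    }
    with open(bundle.truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def small_fixture(out_dir: str | Path, seed: int = 7) -> TruthBundle:
    """A <=50-event, 2-contig bundle for unit tests: at least one event per
    AS type, planted exact-threshold rows, and undersampled events that
    produce masked ΔPSI cells."""
    cfg = SimConfig(
        seed=seed,
        n_se=18,
        n_alt=2,
        n_hd=8,
        n_drug=6,
        n_scattered=4,
        n_low_coverage=2,
        cell_types={"fibroblast": 3, "neuron": 3},
        boundary_overrides=True,
        n_decoy_peaks=5,
        n_expr_up=2,
        n_expr_down=2,
    )
    return generate(cfg, out_dir)
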
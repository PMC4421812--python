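"""Run configuration and end-to-end orchestration of the demo pipeline.

Stages communicate only through files in the run directory, so each stage
is independently inspectable and the whole run is reproducible from the
serialized config: identical config + seed gives byte-identical outputs.
All randomness derives from the single top-level seed by a fixed rule
(stage index offsets).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    Gene,
    GeneAnnotation,
    read_newick,
    write_bed,
    write_matrix_tsv,
    write_newick,
    write_vcf,
)
from .mol_evolution import te_age_distribution
from .phylo_dollo import bootstrap_support, dollo_reconstruct
from .popgen_scan import (
    candidate_regions,
    empirical_thresholds,
    genes_in_regions,
    regions_to_frame,
    sliding_scan,
)
from .seq_qc import filter_contigs
from .synthetic_data import (
    simulate_contigs,
    simulate_family_evolution,
    simulate_te_decay,
    simulate_two_pop,
)

logger = logging.getLogger("kelpscan")

# fixed seed-derivation offsets per stage
_STAGE_SEEDS = {"simulate": 1, "families": 2, "te": 3, "contigs": 4, "bootstrap": 5}

DEMO_SPECIES_TREE = (
    "(((Sjaponica:0.15,Esiliculosus:0.15):0.2,(Ngaditana:0.12,Noceanica:0.12):0.23)"
    ":0.1,((Ptricornutum:0.18,Tpseudonana:0.18):0.12,Aanophagefferens:0.3):0.05);"
)


@dataclass
class RunConfig:
    """All tunables of the demo pipeline; serialized into every run directory."""

    seed: int = 1
    out_dir: str = "runs/demo"
    # scan
    window_size: int = 10_000
    step: int = 5_000
    tail_fraction: float = 0.05
    # simulation
    n_wild: int = 5
    n_cultivated: int = 5
    theta: float = 10.0
    bottleneck_severity: float = 0.05
    split_time: float = 0.1
    n_windows: int = 100
    # trees / families
    n_bootstrap: int = 100
    n_families: int = 300
    loss_rate: float = 0.02
    # repeats / qc
    te_consensus_length: int = 5_000
    identity_threshold: float = 0.85
    provenance: dict = field(default_factory=dict)  # key -> "default" | "user"


def validate_config(config: RunConfig) -> list[str]:
    """Range checks; returns the full list of problems (empty when valid)."""
    errors = []
    if not (0 < config.tail_fraction < 0.5):
        errors.append("tail_fraction out of range (0, 0.5)")
    if config.window_size < config.step:
        errors.append("window_size must be >= step")
    if config.step < 1:
        errors.append("step must be >= 1")
    if not (0 < config.bottleneck_severity <= 1):
        errors.append("bottleneck_severity out of range (0, 1]")
    if config.split_time <= 0:
        errors.append("split_time must be > 0")
    if config.theta <= 0:
        errors.append("theta must be > 0")
    if config.n_windows < 1:
        errors.append("n_windows must be >= 1")
    if config.n_bootstrap < 1:
        errors.append("n_bootstrap must be >= 1")
    if not (0 < config.identity_threshold <= 1):
        errors.append("identity_threshold out of range (0, 1]")
    if config.seed < 0 or config.seed >= 2**31:
        errors.append("seed must be in [0, 2^31)")
    return errors


def demo_annotation(chrom: str, length: int) -> GeneAnnotation:
    """Synthetic gene models tiled along the simulated chromosome."""
    genes = []
    start = 500
    i = 0
    while start + 2000 <= length:
        genes.append(
            Gene(gene_id=f"gene{i:04d}", chrom=chrom, start=start, end=start + 2000, order=i)
        )
        start += 3000
        i += 1
    return GeneAnnotation(genes=genes)


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate -> scan -> regions -> tree -> dollo -> teage -> qc.

    Writes scan.tsv, regions.tsv, tree.nwk, gainloss.tsv, te_age.tsv,
    qc_report.tsv and manifest.json into the run directory and returns its
    path.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    cfg_text = json.dumps(asdict(config), indent=2, sort_keys=True)
    (out / "config.json").write_text(cfg_text)
    # hash the statistical parameters only, so identical runs in different
    # directories produce identical manifests
    cfg_stat = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_stat, sort_keys=True).encode()
    ).hexdigest()

    # --- simulate ---------------------------------------------------------
    two_pop = simulate_two_pop(
        n_wild=config.n_wild,
        n_cultivated=config.n_cultivated,
        theta=config.theta,
        bottleneck_severity=config.bottleneck_severity,
        split_time=config.split_time,
        n_windows=config.n_windows,
        window_length=config.window_size,
        seed=seed + _STAGE_SEEDS["simulate"],
    )
    write_vcf(two_pop.table, out / "variants.vcf")
    two_pop.truth.to_json(out / "sim_truth.json")
    (out / "wild_samples.txt").write_text("\n".join(two_pop.wild_samples) + "\n")
    (out / "cultivated_samples.txt").write_text(
        "\n".join(two_pop.cultivated_samples) + "\n"
    )
    chrom_len = config.n_windows * config.window_size
    annotation = demo_annotation("chr1", chrom_len)
    write_bed(annotation, out / "genes.bed")

    # --- scan + regions ---------------------------------------------------
    chrom_lengths = {"chr1": chrom_len}
    scans = {}
    all_regions = []
    summaries = {}
    for pop_label, samples in (
        ("W", two_pop.wild_samples),
        ("C", two_pop.cultivated_samples),
    ):
        scan = sliding_scan(
            two_pop.table,
            window_size=config.window_size,
            step=config.step,
            population_samples=samples,
            chrom_lengths=chrom_lengths,
        )
        scans[pop_label] = scan
        low, high = empirical_thresholds(scan["D"].to_numpy(), config.tail_fraction)
        regions = candidate_regions(scan, low, high, pop_label)
        regions, n_genes = genes_in_regions(regions, annotation)
        all_regions.extend(regions)
        summaries[pop_label] = dict(
            mean_pi=float(np.nanmean(scan["pi"])),
            mean_theta_w=float(np.nanmean(scan["theta_w"])),
            mean_D=float(np.nanmean(scan["D"])),
            threshold_low=low,
            threshold_high=high,
            n_regions=len(regions),
            n_region_genes=n_genes,
        )
    scan_df = pd.concat(
        [df.assign(population=lbl) for lbl, df in scans.items()], ignore_index=True
    )
    scan_df.to_csv(out / "scan.tsv", sep="\t", index=False)
    regions_to_frame(all_regions).to_csv(out / "regions.tsv", sep="\t", index=False)

    # --- NJ tree with bootstrap ------------------------------------------
    tree = bootstrap_support(
        two_pop.table,
        n_replicates=config.n_bootstrap,
        seed=seed + _STAGE_SEEDS["bootstrap"],
    )
    (out / "tree.nwk").write_text(write_newick(tree))

    # --- Dollo gain/loss --------------------------------------------------
    species_tree = read_newick(DEMO_SPECIES_TREE)
    presence, truth_map, fam_truth = simulate_family_evolution(
        species_tree,
        n_families=config.n_families,
        loss_rate=config.loss_rate,
        seed=seed + _STAGE_SEEDS["families"],
    )
    write_matrix_tsv(presence, out / "families.tsv")
    fam_truth.to_json(out / "families_truth.json")
    recon = dollo_reconstruct(presence, species_tree)
    rows = []
    for sig in sorted(
        set(recon.gains) | set(recon.losses), key=lambda s: (len(s), sorted(s))
    ):
        rows.append(
            dict(
                branch="|".join(sorted(sig)),
                gained=len(recon.gains.get(sig, ())),
                lost=len(recon.losses.get(sig, ())),
            )
        )
    pd.DataFrame(rows, columns=["branch", "gained", "lost"]).to_csv(
        out / "gainloss.tsv", sep="\t", index=False
    )
    gain_match = sum(
        1
        for fam, sig in recon.family_gain.items()
        if truth_map.family_gain.get(fam) == sig
    )
    summaries["dollo"] = dict(
        n_families=len(recon.family_gain),
        gain_branch_recovery=gain_match / max(1, len(recon.family_gain)),
    )

    # --- TE ages ----------------------------------------------------------
    copies, te_truth = simulate_te_decay(
        consensus_length=config.te_consensus_length,
        copy_ages=[0.02] * 150 + [0.20] * 150,
        seed=seed + _STAGE_SEEDS["te"],
    )
    te_truth.to_json(out / "te_truth.json")
    hist = te_age_distribution(copies, bin_width=0.01)
    hist.to_csv(out / "te_age.tsv", sep="\t", index=False)

    # --- contamination filter --------------------------------------------
    contigs, labels, _ = simulate_contigs(
        n_host=50, n_bacterial=50, seed=seed + _STAGE_SEEDS["contigs"]
    )
    kept, removed = filter_contigs(contigs)
    qc = pd.DataFrame(
        [
            dict(
                contig_id=c.contig_id,
                hint=c.taxonomy_hint,
                gc=round(c.gc, 6),
                orf_density=round(c.orf_dens, 6),
                removed=c.filtered,
            )
            for c in contigs
        ]
    )
    qc = qc.merge(labels[["contig_id", "origin"]], on="contig_id")
    qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    removed_ids = {c.contig_id for c in removed}
    by_origin = labels.groupby("origin")["contig_id"].apply(list)
    summaries["qc"] = {
        f"removed_frac_{origin}": (
            sum(cid in removed_ids for cid in cids) / len(cids)
        )
        for origin, cids in by_origin.items()
    }

    manifest = dict(
        tool="kelpscan",
        version=__version__,
        config_sha256=cfg_hash,
        seed=seed,
        summary=summaries,
        artifacts=sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return out
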
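"""End-to-end orchestration of the analysis stages.

Stages run in dependency order: ORF selection -> redundancy collapse ->
tissue specificity -> toxin screens / family clustering / GO enrichment /
proteome integration -> summary reports. A JSON manifest records the
configuration, seed, input checksums and per-stage outputs so identical
config + seed reproduces identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    family_clustering,
    go_enrichment,
    io,
    orf_tools,
    proteome_integration,
    redundancy,
    synthetic_data,
    tissue_specificity,
    toxin_screens,
)


@dataclass
class RunConfig:
    """All stage parameters, with their documented defaults."""

    min_orf_nt: int = 90
    mstart_ratio: float = 0.75
    quantile: float = 0.025
    min_ecpm: float = 1.0
    screen_max_len: int = 200
    screen_min_cys: int = 6
    identity_grid: tuple = tuple(range(30, 100, 5))
    coverage_grid: tuple = tuple(range(30, 100, 5))
    n_resamples: int = 10_000
    fdr_alpha: float = 0.05
    min_prob: float = 0.95
    min_unique: int = 2
    max_cluster_proteins: int = 400
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_bundle(bundle: synthetic_data.SyntheticBundle, outdir) -> dict:
    """Serialize a synthetic bundle (plus its peptide table) to disk."""
    outdir = io.ensure_dir(outdir)
    io.write_fasta(bundle.transcripts, outdir / "transcripts.fasta")
    io.write_tsv(bundle.counts, outdir / "counts.tsv")
    io.write_tsv(bundle.annotations, outdir / "annotations.tsv")
    io.write_tsv(bundle.go_terms, outdir / "go_terms.tsv")
    io.write_tsv(bundle.signal, outdir / "signal.tsv")
    io.write_tsv(bundle.truth, outdir / "truth.tsv")
    peptides = synthetic_data.generate_peptide_ids(bundle.truth, bundle.config)
    io.write_tsv(peptides, outdir / "peptides.tsv")
    return {
        name: _sha256(outdir / name)
        for name in (
            "transcripts.fasta", "counts.tsv", "annotations.tsv",
            "go_terms.tsv", "signal.tsv", "truth.tsv", "peptides.tsv",
        )
    }


def run_pipeline(
    indir,
    outdir,
    config: RunConfig | None = None,
) -> dict:
    """Run every stage on a serialized input bundle; returns the manifest.

    ``indir`` must contain transcripts.fasta, counts.tsv,
    annotations.tsv, go_terms.tsv, signal.tsv and peptides.tsv (the
    layout written by ``write_bundle``).
    """
    config = config or RunConfig()
    indir = Path(indir)
    outdir = io.ensure_dir(outdir)
    required = [
        "transcripts.fasta", "counts.tsv", "annotations.tsv",
        "go_terms.tsv", "signal.tsv", "peptides.tsv",
    ]
    for name in required:
        if not (indir / name).exists():
            raise FileNotFoundError(
                f"stage input {name!r} missing from {indir}"
            )
    manifest: dict = {
        "config": config.to_dict(),
        "inputs": {n: _sha256(indir / n) for n in required},
        "stages": [],
    }

    transcripts = io.read_fasta(indir / "transcripts.fasta")
    counts = io.read_tsv(indir / "counts.tsv").set_index("transcript_id")
    annotations = io.read_tsv(indir / "annotations.tsv")
    go_table = io.read_tsv(indir / "go_terms.tsv")
    signal = io.read_tsv(indir / "signal.tsv")
    peptides = io.read_tsv(indir / "peptides.tsv")

    # --- ORF selection -----------------------------------------------------
    frames = {}
    if "hit_frame" in annotations.columns:
        frames = dict(
            zip(annotations["transcript_id"], annotations["hit_frame"])
        )
    predictions = orf_tools.predict_proteins(
        transcripts,
        best_hit_frames=frames,
        min_len=config.min_orf_nt,
        mstart_ratio=config.mstart_ratio,
    )
    proteins = {tid: p.aa_seq for tid, p in predictions.items()}
    orf_table = pd.DataFrame(
        [
            {
                "transcript_id": tid,
                "frame": p.frame,
                "rule": p.rule,
                "is_mstart": p.is_mstart,
                "aa_length": len(p.aa_seq),
            }
            for tid, p in predictions.items()
        ]
    )
    io.write_tsv(orf_table, outdir / "proteins.tsv")
    io.write_fasta(proteins, outdir / "proteins.fasta")
    manifest["stages"].append({"name": "orfs", "n_proteins": len(proteins)})

    # --- redundancy collapse ----------------------------------------------
    kept, clusters = redundancy.collapse(proteins)
    cluster_rows = [
        {
            "cluster_id": ci,
            "member_id": m,
            "is_representative": m == cl.representative,
        }
        for ci, cl in enumerate(clusters)
        for m in cl.members
    ]
    io.write_tsv(pd.DataFrame(cluster_rows), outdir / "redundancy.tsv")
    manifest["stages"].append(
        {"name": "collapse", "n_kept": len(kept), "n_clusters": len(clusters)}
    )

    # --- tissue specificity ------------------------------------------------
    ecpm = tissue_specificity.compute_ecpm(counts)
    fpkm = tissue_specificity.compute_fpkm(
        counts, counts["effective_length_nt"]
    )
    spec = tissue_specificity.classify_vst(
        ecpm, quantile=config.quantile, min_ecpm=config.min_ecpm
    )
    spec_out = spec.table.reset_index(names="transcript_id")
    io.write_tsv(spec_out, outdir / "specificity.tsv")
    (outdir / "specificity.json").write_text(
        json.dumps(
            {
                "fold_cutoff_silk": spec.fold_cutoff_silk,
                "fold_cutoff_ceph": spec.fold_cutoff_ceph,
                "quantile": spec.quantile,
                "min_ecpm": spec.min_ecpm,
                "class_counts": spec.counts(),
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    vst_ids = set(spec.vst_ids)
    manifest["stages"].append({"name": "specificity", "n_vst": len(vst_ids)})

    # --- toxin screens -----------------------------------------------------
    categories = toxin_screens.tag_categories(
        annotations[["transcript_id", "hit_description", "evalue"]],
        transcript_ids=list(counts.index),
    )
    vst_proteins = {t: s for t, s in kept.items() if t in vst_ids}
    screen_hits = toxin_screens.screen_cysteine_rich(
        vst_proteins,
        max_len=config.screen_max_len,
        min_cys=config.screen_min_cys,
    )
    cleavage = {
        str(r.protein_id): int(r.cleavage_pos)
        for r in signal.itertuples(index=False)
        if bool(r.has_signal)
    }
    frameworks = [
        toxin_screens.extract_framework(
            pid, vst_proteins[pid], cleavage.get(pid)
        )
        for pid in screen_hits
    ]
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": fw.protein_id,
                    "n_cys": fw.cys_count,
                    "spacings": ",".join(map(str, fw.spacings)),
                    "ick_candidate": fw.ick_candidate,
                }
                for fw in frameworks
            ],
            columns=["protein_id", "n_cys", "spacings", "ick_candidate"],
        ),
        outdir / "cysteine_screen.tsv",
    )
    io.write_tsv(
        pd.DataFrame(
            sorted(categories.items()), columns=["transcript_id", "category"]
        ),
        outdir / "categories.tsv",
    )
    vst_fpkm = fpkm.loc[sorted(vst_ids), "venom"]
    summary = toxin_screens.summarize_category_expression(vst_fpkm, categories)
    io.write_tsv(summary.reset_index(), outdir / "category_summary.tsv")
    manifest["stages"].append(
        {
            "name": "screen",
            "n_cysteine_rich": len(screen_hits),
            "n_ick_candidates": sum(fw.ick_candidate for fw in frameworks),
        }
    )

    # --- family clustering sweep ------------------------------------------
    if len(vst_proteins) >= 2:
        cluster_input = vst_proteins
        if len(cluster_input) > config.max_cluster_proteins:
            keep = sorted(cluster_input)[: config.max_cluster_proteins]
            cluster_input = {t: cluster_input[t] for t in keep}
        cells = family_clustering.sweep(
            cluster_input,
            identity_grid=config.identity_grid,
            coverage_grid=config.coverage_grid,
        )
        io.write_tsv(
            pd.DataFrame(
                [
                    {
                        "identity": c.identity_threshold,
                        "coverage": c.coverage_threshold,
                        "n_clusters_ge2": c.n_clusters_ge2,
                        "n_seqs_clustered": c.n_seqs_clustered,
                        "max_size": c.max_cluster_size,
                    }
                    for c in cells
                ]
            ),
            outdir / "cluster_sweep.tsv",
        )
        manifest["stages"].append(
            {"name": "cluster", "n_cells": len(cells),
             "n_proteins": len(cluster_input)}
        )

    # --- GO enrichment -----------------------------------------------------
    background = ecpm.index[ecpm["venom"] > 1.0]
    bg_ids = [t for t in background]
    lengths = counts.loc[bg_ids, "effective_length_nt"].to_numpy(float)
    result = go_enrichment.enrich(
        go_table[go_table["transcript_id"].isin(bg_ids)],
        vst_ids & set(bg_ids),
        bg_ids,
        lengths,
        n_resamples=config.n_resamples,
        alpha=config.fdr_alpha,
        seed=config.seed,
    )
    io.write_tsv(result.table, outdir / "go_enrichment.tsv")
    manifest["stages"].append(
        {
            "name": "enrich",
            "n_terms": len(result.table),
            "n_flagged": int(result.table["flagged"].sum()),
        }
    )

    # --- proteome integration ---------------------------------------------
    high_conf = peptides[peptides["peptide_prob"] > config.min_prob]
    placements = proteome_integration.map_peptides(
        high_conf["peptide_seq"].astype(str), kept
    )
    evidence = proteome_integration.filter_evidence(
        placements, peptides, kept,
        min_prob=config.min_prob, min_unique=config.min_unique,
    )
    signal_ids = {
        str(r.protein_id)
        for r in signal.itertuples(index=False)
        if bool(r.has_signal)
    }
    secretome = proteome_integration.classify_secretome(
        evidence, signal_ids, vst_ids, classified_ids=set(counts.index)
    )
    io.write_tsv(
        pd.DataFrame(
            [
                {
                    "protein_id": e.protein_id,
                    "n_unique_peptides": e.n_unique_peptides,
                    "pct_coverage": round(e.percent_coverage, 4),
                    "max_protein_prob": e.max_protein_prob,
                    "venom_confirmed": e.venom_confirmed,
                    "category": categories.get(e.protein_id, "no_hit"),
                }
                for e in evidence
            ],
            columns=[
                "protein_id", "n_unique_peptides", "pct_coverage",
                "max_protein_prob", "venom_confirmed", "category",
            ],
        ),
        outdir / "proteome_evidence.tsv",
    )
    io.write_tsv(secretome, outdir / "secretome.tsv")
    manifest["stages"].append(
        {
            "name": "proteome",
            "n_confirmed": sum(e.venom_confirmed for e in evidence),
        }
    )

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
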
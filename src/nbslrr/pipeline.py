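"""End-to-end orchestration: annotate -> structure -> phylogeny bundles."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import classify_protein, summarize_categories
from .gffio import read_fasta, read_gff3
from .motifs import load_paper_motifs, synthetic_rpw8_profile
from .phylogeny import build_msa, bootstrap_support, nj_tree, partition_families, pdistance_matrix
from .structure import (
    chromosome_summary,
    classify_duplications,
    detect_clusters,
    intron_stats,
    protein_identity_matrix,
)
from .synthetic import SyntheticConfig, generate_genome


@dataclass
class RunConfig:
    """Thresholds and toggles for a pipeline run (all values land in the
    run manifest)."""

    outdir: str = "nbslrr_out"
    seed: int = 0
    motif_threshold: float = 0.6
    cc_threshold: float = 0.8
    cluster_max_gap: int = 200_000
    cluster_max_intervening: int = 7
    identity_threshold: float = 0.7
    bootstrap_replicates: int = 200
    size_window: tuple = (300, 800)
    run_phylogeny: bool = True
    run_structure: bool = True
    # inputs: either a synthetic config or real files
    synthetic: SyntheticConfig | None = None
    genome_fasta: str | None = None
    gff3: str | None = None
    proteins_fasta: str | None = None

    def validate(self):
        if not 0 < self.motif_threshold <= 1:
            raise ValueError("motif_threshold must be in (0, 1]")
        if not 0 <= self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in [0, 1]")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")


def run_annotate(proteins: dict, config: RunConfig | None = None):
    """Classify every protein; returns (architectures, summary, report)."""
    config = config or RunConfig()
    config.validate()
    library = load_paper_motifs()
    rpw8 = synthetic_rpw8_profile()
    archs = [
        classify_protein(
            gid, seq, motif_library=library, threshold=config.motif_threshold,
            rpw8_profile=rpw8, cc_threshold=config.cc_threshold,
        )
        for gid, seq in proteins.items()
    ]
    summary = summarize_categories(archs) if archs else {"total": 0}
    report = pd.DataFrame(
        {
            "gene_id": [a.gene_id for a in archs],
            "letter_code": [a.letter_code for a in archs],
            "domains": [
                ";".join(f"{n}:{s}-{e}" for n, s, e in a.domains) for a in archs
            ],
            "kinase2_residue": [a.kinase2_last_residue or "." for a in archs],
            "kinase2_family": [a.kinase2_family_call for a in archs],
            "has_nbs_core": [a.nbs_core is not None for a in archs],
        }
    )
    return archs, summary, report


def run_full(config: RunConfig) -> dict:
    """Run every stage in dependency order and write the report bundle.

    Returns a dict of in-memory results; artifacts (TSV/newick/JSON) are
    written under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        genome = generate_genome(config.synthetic)
        genome.write(outdir / "synthetic")
        genes = genome.genes
        proteins = {g.gene_id: g.protein for g in genes}
    elif config.proteins_fasta is not None:
        proteins = read_fasta(config.proteins_fasta)
        genes = []
        if config.gff3 is not None:
            genome_seq = (
                read_fasta(config.genome_fasta) if config.genome_fasta else None
            )
            genes = read_gff3(config.gff3, genome=genome_seq)
            if not proteins:
                proteins = {g.gene_id: g.protein for g in genes}
    else:
        raise ValueError("run_full needs a synthetic config or input paths")

    results: dict = {}
    archs, summary, report = run_annotate(proteins, config)
    results["architectures"] = archs
    results["summary"] = summary
    report.to_csv(outdir / "architectures.tsv", sep="\t", index=False)
    pd.Series(summary).to_csv(outdir / "summary.tsv", sep="\t", header=False)

    arch_by_id = {a.gene_id: a for a in archs}
    if config.run_structure and genes:
        for g in genes:
            a = arch_by_id.get(g.gene_id)
            g.is_nbs = a is not None and a.letter_code != "unclassified"
        nbs = [g for g in genes if g.is_nbs]
        clusters = detect_clusters(
            nbs, genes, max_gap=config.cluster_max_gap,
            max_intervening=config.cluster_max_intervening,
        )
        identity = protein_identity_matrix({g.gene_id: g.protein for g in nbs})
        dups = classify_duplications(
            nbs, identity, clusters, identity_threshold=config.identity_threshold
        )
        introns = {g.gene_id: intron_stats(g) for g in genes}
        results["clusters"] = clusters
        results["duplications"] = dups
        results["introns"] = introns
        results["chromosomes"] = chromosome_summary(nbs)
        pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "chromosome": c.chromosome,
                    "n_members": len(c.members),
                    "span_bases": c.span_bases,
                    "members": ",".join(c.members),
                }
                for c in clusters
            ]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
        pd.DataFrame([asdict(d) for d in dups]).to_csv(
            outdir / "duplications.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"gene_id": gid, "intron_count": n, "phases": ",".join(map(str, ph))}
                for gid, (n, ph) in introns.items()
            ]
        ).to_csv(outdir / "introns.tsv", sep="\t", index=False)

    if config.run_phylogeny:
        cores = {a.gene_id: a.nbs_core for a in archs if a.nbs_core}
        if len(cores) >= 4:
            aln = build_msa(cores)
            tree = bootstrap_support(
                aln, n_replicates=config.bootstrap_replicates, seed=config.seed
            )
            anchors = {
                a.gene_id: a.kinase2_family_call
                for a in archs
                if a.gene_id in cores and a.kinase2_family_call in ("TIR", "CC")
            }
            partition = (
                partition_families(tree, anchors) if anchors else None
            )
            results["tree"] = tree
            results["partition"] = partition
            (outdir / "tree.nwk").write_text(tree.to_newick(hide_leq=50) + "\n")
            if partition is not None and partition.resolved:
                pd.DataFrame(
                    {
                        "leaf": sorted(partition.family),
                        "family": [
                            partition.family[k] for k in sorted(partition.family)
                        ],
                        "subfamily": [
                            partition.subfamily.get(k, ".")
                            for k in sorted(partition.family)
                        ],
                    }
                ).to_csv(outdir / "partition.tsv", sep="\t", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "motif_threshold": config.motif_threshold,
        "cc_threshold": config.cc_threshold,
        "cluster_max_gap": config.cluster_max_gap,
        "cluster_max_intervening": config.cluster_max_intervening,
        "identity_threshold": config.identity_threshold,
        "bootstrap_replicates": config.bootstrap_replicates,
        "size_window": list(config.size_window),
        "stages": {
            "structure": bool(config.run_structure),
            "phylogeny": bool(config.run_phylogeny),
        },
        "synthetic_seed": config.synthetic.seed if config.synthetic else None,
        "n_proteins": len(proteins),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results
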
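#!/usr/bin/env python
"""Generate the synthetic study inputs: two species' genomes and gene
tables with planted binding-site structure, a differential-expression table,
an ortholog map and a pathway gene set.

Large sequence files go to scratch/synthetic/ (regenerable from the seed);
a small summary of what was planted goes to results/.
"""

import argparse
import json
from pathlib import Path

from ppmscreen.synthetic import (
    SynthConfig,
    gen_de_table,
    gen_species_pair,
    write_de_table,
    write_gene_table,
    write_genome_fasta,
    write_ortholog_tsv,
    write_pathway_tsv,
    write_truth_json,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-genes", type=int, default=600)
    args = parser.parse_args()

    out = ROOT / "scratch" / "synthetic"
    out.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(seed=args.seed, n_genes=args.n_genes)
    pair = gen_species_pair(cfg)

    write_genome_fasta(pair.study_a.genome, out / "genome_a.fa")
    write_gene_table(pair.study_a.transcripts, out / "genes_a.tsv")
    write_genome_fasta(pair.study_b.genome, out / "genome_b.fa")
    write_gene_table(pair.study_b.transcripts, out / "genes_b.tsv")
    write_ortholog_tsv(pair.ortho, out / "orthologs.tsv")
    write_pathway_tsv(pair.pathway, out / "pathway.tsv")
    write_truth_json(pair.study_a.truth, out / "truth_a.json")
    write_truth_json(pair.study_b.truth, out / "truth_b.json")
    de = gen_de_table(cfg, pair.study_a.truth)
    write_de_table(de, out / "de_a.tsv")

    summary = {
        "seed": args.seed,
        "n_genes_per_species": args.n_genes,
        "planted_pairs_species_a": sum(
            t.planted and t.n_sites == 2 for t in pair.study_a.truth.values()
        ),
        "planted_clusters_species_a": sum(
            t.n_sites > 2 for t in pair.study_a.truth.values()
        ),
        "planted_pairs_species_b": sum(
            t.planted and t.n_sites == 2 for t in pair.study_b.truth.values()
        ),
        "planted_clusters_species_b": sum(
            t.n_sites > 2 for t in pair.study_b.truth.values()
        ),
        "conserved_genes": len(pair.conserved_pairs),
        "ortholog_pairs": len(pair.ortho),
        "pathway_size": len(pair.pathway.members),
        "inputs_dir": str(out),
    }
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "01_simulation_summary.json").write_text(
        json.dumps(summary, indent=1) + "\n"
    )
    print("Synthetic inputs written to", out)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
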
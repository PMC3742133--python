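#!/usr/bin/env python
"""Validate the promoter model on synthetic training sets.

Builds a single-species genome in which 3 promoters carry a planted
canonical site pair, stratifies a differential-expression table so those
genes sit in the FDR<0.01 stratum (30 genes), samples a 2,000-promoter
negative set from the remaining universe, and computes the tiered
validation table: per-tier rates, fold enrichment, Fisher p, and
sensitivity/specificity with exact binomial CIs.
"""

import argparse
import json
from pathlib import Path

from ppmscreen.screen import build_training_sets, validate_ppm
from ppmscreen.synthetic import SynthConfig, gen_de_table, gen_genome_and_genes

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-genes", type=int, default=2500)
    parser.add_argument("--n-neg", type=int, default=2000)
    args = parser.parse_args()

    cfg = SynthConfig(seed=args.seed, n_genes=args.n_genes, n_planted=3)
    study = gen_genome_and_genes(cfg)
    de = gen_de_table(cfg, study.truth)
    universe = [t.gene_symbol for t in study.transcripts]
    sets = build_training_sets(de, universe, fdr_cut=0.01, n_neg=args.n_neg,
                               seed=args.seed)
    report = validate_ppm(study.windows_for(sets.positive),
                          study.windows_for(sets.negative))

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "02_validation.tsv").write_text(report.to_tsv())
    (results / "02_validation.json").write_text(
        json.dumps(report.to_dict(), indent=1) + "\n"
    )

    d = report.to_dict()
    print(f"(+) set: {len(sets.positive)} genes (3 with a planted pair); "
          f"(-) set: {len(sets.negative)} random promoters")
    print(report.to_tsv())
    ppm = d["PPM"]
    print(
        f"Strict-tier fold enrichment {ppm['fold_enrichment']} "
        f"(Fisher p={ppm['fisher_p']:.2g}): the planted 10% positive rate "
        f"against a ~{ppm['neg_rate_pct']}% background rate. Relaxed tiers "
        "gain sensitivity and lose specificity, as expected for the "
        "weakly-specific core motif."
    )


if __name__ == "__main__":
    main()
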
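"""Simulate the stated world: two cohorts, protein panel, LD reference, truth.

Writes the ground-truth and gene tables (and a small genotype VCF excerpt)
under results/, and the full simulation state under scratch/ for the later
steps.  Every artifact records the seed.
"""

import argparse
import pickle
from pathlib import Path

from protmr.io import write_dosage_vcf
from protmr.pipeline import PipelineConfig, default_world
from protmr.simulate import simulate_cohort_pair, simulate_ld_panel

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-proteins", type=int, default=30)
    args = ap.parse_args()

    cfg = PipelineConfig(n_proteins=args.n_proteins)
    specs, truths, gene_table = default_world(cfg, args.seed)
    discovery, replication, truth = simulate_cohort_pair(
        specs, truths,
        n_discovery=cfg.n_discovery, n_replication=cfg.n_replication,
        heritability_polygenic=cfg.h2_polygenic, seed=args.seed,
    )
    panel = simulate_ld_panel(specs, n_samples=2, seed=args.seed)

    results = ROOT / "results"
    scratch = ROOT / "scratch"
    results.mkdir(exist_ok=True)
    scratch.mkdir(exist_ok=True)

    import dataclasses
    import json

    with open(results / "world_config.json", "w") as fh:
        json.dump({"seed": args.seed} | dataclasses.asdict(cfg), fh, indent=2)
    truth.to_csv(results / "truth_table.tsv", sep="\t", index=False)
    gene_table.to_csv(results / "gene_table.tsv", sep="\t", index=False)
    # a small excerpt of the discovery genotypes as VCF (first 20 samples, first block)
    k = cfg.snps_per_block
    write_dosage_vcf(
        discovery.dosages[:20, :k], discovery.variants.iloc[:k],
        results / "discovery_genotypes_excerpt.vcf", seed=args.seed,
    )
    with open(scratch / "world.pkl", "wb") as fh:
        pickle.dump(
            {"cfg": cfg, "seed": args.seed, "discovery": discovery,
             "replication": replication, "panel": panel, "truth": truth,
             "gene_table": gene_table},
            fh,
        )
    print(
        f"simulated {cfg.n_proteins} proteins over {panel.n_variants} variants; "
        f"cohorts n={cfg.n_discovery}/{cfg.n_replication}; "
        f"scenarios: {truth['scenario'].value_counts().to_dict()}"
    )
    print(f"state -> {scratch / 'world.pkl'}; tables -> {results}")


if __name__ == "__main__":
    main()
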
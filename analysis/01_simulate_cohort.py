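#!/usr/bin/env python
"""Generate the discovery-design synthetic cohort.

37 cases vs 208 controls, 500 genes, one planted risk gene carried by
~4/37 cases and ~1/208 controls over a 0.007 background; writes the
variant/genotype/label tables, a VCF, and the ground-truth sidecar under
results/cohort/.
"""

from pathlib import Path

from carrierscan.io import (
    write_genotypes_tsv,
    write_labels_tsv,
    write_variants_tsv,
    write_vcf,
)
from carrierscan.simulate import CohortSimParams, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20220708


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = CohortSimParams(seed=SEED)
    sim = simulate_cohort(params)
    write_variants_tsv(sim.variants, OUT / "variants.tsv")
    write_genotypes_tsv(sim.genotypes, OUT / "genotypes.tsv")
    write_labels_tsv(sim.labels, OUT / "labels.tsv")
    write_vcf(sim.variants, sim.genotypes, sim.labels.index, OUT / "cohort.vcf")
    sim.truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    planted = sim.truth[sim.truth["planted"]]
    print(f"cohort: {params.n_cases} cases / {params.n_controls} controls, "
          f"{params.n_genes} genes, {len(sim.variants)} variants, "
          f"{len(sim.genotypes)} genotype calls")
    for row in planted.itertuples(index=False):
        print(f"planted gene {row.gene}: {row.case_carriers} case carriers, "
              f"{row.control_carriers} control carriers (post-QC)")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
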
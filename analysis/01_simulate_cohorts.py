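#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emulates the data sources of a drug-target MR study: a blood cis-eQTL
exposure GWAS (n ~ 30k), a binary-outcome biobank GWAS (effective
n ~ 15k on the log-odds scale), an exposure->mediator->outcome chain,
and a 48-SNP cis region with LD blocks plus a downstream biomarker for
the inhibition-proxy arm. Tables are written under results/data/ as
plain TSV so every later step runs off files, exactly as a real
analysis would.
"""

import argparse
from pathlib import Path

import robustmr as mr

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/data"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

# main exposure/outcome pair: one causal pathway, beta = 0.3, mild
# balanced pleiotropy, instruments preselected in-sample at p < 1e-3
cfg = mr.SimConfig(
    p=150, beta=0.3, seed=args.seed,
    pleiotropy=mr.PleiotropySpec(mode="balanced", tau=0.01),
    selection=mr.SelectionSpec(mode="same_sample", p_threshold=1e-3),
)
exposure, outcome, truth = mr.simulate_two_sample(cfg)
mr.write_sumstats(exposure, args.out / "exposure.tsv")
mr.write_sumstats(outcome, args.out / "outcome.tsv")

# a second outcome with a confounded pathway (40% of SNPs), for mode detection
cfg2 = mr.SimConfig(
    p=150, beta=0.4, seed=args.seed + 1,
    pleiotropy=mr.PleiotropySpec(mode="correlated", tau=0.01, fraction=0.4,
                                 confounder_shift=-0.6),
)
exposure2, outcome2, _ = mr.simulate_two_sample(cfg2)
mr.write_sumstats(exposure2, args.out / "exposure_confounded.tsv")
mr.write_sumstats(outcome2, args.out / "outcome_confounded.tsv")

# mediation chain (total 0.3 = direct 0.2 + indirect 0.1)
med_cfg = mr.SimConfig(p=100, beta=0.0, seed=args.seed + 2,
                       mediation=mr.MediationSpec())
ds_xy, ds_xm, ds_my, ds_xmy, med_truth = mr.simulate_mediation(med_cfg)
for name, ds in (("xy", ds_xy), ("xm", ds_xm), ("my", ds_my), ("xmy", ds_xmy)):
    ds.write(args.out / f"mediation_{name}.tsv")

# drug-target cis fixture
eqtl, biomarker, drug_outcome, ld, dt_truth = mr.simulate_drug_target(
    mr.DrugTargetSimConfig(seed=args.seed + 3))
mr.write_sumstats(eqtl, args.out / "eqtl.tsv")
mr.write_sumstats(biomarker, args.out / "biomarker.tsv")
mr.write_sumstats(drug_outcome, args.out / "drug_outcome.tsv")
mr.write_ld_matrix(ld, args.out / "ld.tsv")

print(f"wrote study inputs to {args.out}")
print(f"  main pair: {len(exposure.table)} instruments survive in-sample selection")
print(f"  truth: beta={cfg.beta}, mediation total={med_truth.total:.2f} "
      f"(direct {med_truth.direct:.2f} + indirect {med_truth.indirect:.2f}), "
      f"drug effect {mr.DrugTargetSimConfig().beta_drug}")
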
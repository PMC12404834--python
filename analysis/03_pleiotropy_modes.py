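#!/usr/bin/env python
"""Profile-likelihood mode detection and marker-SNP attribution.

Profiles the robust (Tukey) objective over candidate effects for two
simulated outcomes: one with a single causal pathway and one where 40%
of instruments act through a shared confounder. The first yields a
single mode at the causal effect; the second a secondary mode at the
confounded pathway's apparent effect, with marker SNPs attributing
instruments to pathways. Also runs the reversed-role direction
diagnostic. Writes results/modes.tsv and profile-curve plots.
"""

import argparse
from pathlib import Path

import pandas as pd

import robustmr as mr
from robustmr.plotting import profile_plot

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/data"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

rows = []
for label, exp_name, out_name in (
    ("one_pathway", "exposure.tsv", "outcome.tsv"),
    ("two_pathway", "exposure_confounded.tsv", "outcome_confounded.tsv"),
):
    exposure = mr.read_sumstats(args.data / exp_name, trait_label="exposure")
    outcome = mr.read_sumstats(args.data / out_name, trait_label="outcome")
    ds = mr.select_instruments(mr.harmonize([exposure], outcome), 1e-4)
    curve = mr.robust_profile(ds)
    ms = mr.detect_modes(curve)
    profile_plot(curve, args.out / f"profile_{label}.png")
    print(f"{label}: {len(ms)} mode(s), near-zero flag {ms.near_zero_flag}")
    for rank, m in enumerate(ms.modes, 1):
        markers = mr.marker_snps(ds, m.beta)
        rows.append({"fixture": label, "rank": rank, "beta": round(m.beta, 4),
                     "objective": m.objective, "n_markers": len(markers),
                     "near_zero_flag": ms.near_zero_flag})
        print(f"  mode {rank}: beta={m.beta:+.3f}, {len(markers)} marker SNPs")

# direction diagnostic on a realistic mixed panel: a spike-slab exposure
# architecture plus outcome-specific genetics. With the roles reversed and
# instruments re-selected on the new "exposure", the profile turns bimodal
# with one peak near zero — the signature of a misspecified direction.
cfg = mr.SimConfig(p=400, beta=0.4, seed=3,
                   gamma_dist=mr.GammaSpec(kind="spike_slab", sd=0.4,
                                           slab_fraction=0.15, spike_sd=0.005),
                   pleiotropy=mr.PleiotropySpec(mode="balanced", tau=0.05))
e, o, _ = mr.simulate_two_sample(cfg)
for label, ds_dir, grid in (
    ("correct_direction", mr.select_instruments(mr.as_harmonized(e, o), 1e-4), (-2, 2, 0.001)),
    ("reversed_direction", mr.select_instruments(mr.as_harmonized(o, e), 1e-4), (-4, 4, 0.002)),
):
    ms_dir = mr.detect_modes(mr.robust_profile(ds_dir, grid_spec=grid))
    for rank, m in enumerate(ms_dir.modes, 1):
        rows.append({"fixture": label, "rank": rank, "beta": round(m.beta, 4),
                     "objective": m.objective, "n_markers": 0,
                     "near_zero_flag": ms_dir.near_zero_flag})
    print(f"{label}: {len(ms_dir)} mode(s), near-zero flag {ms_dir.near_zero_flag}")

pd.DataFrame(rows).to_csv(args.out / "modes.tsv", sep="\t", index=False)
print("wrote results/modes.tsv")
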
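"""Genetically proxied drug-target inhibition from cis-eQTLs and a biomarker.

Pharmacological inhibition of a gene product is proxied by cis-eQTL
lead SNPs re-oriented to their expression-LOWERING allele, retained
only when that orientation also lowers a downstream biomarker of the
drug's on-target action (here modeled on HbA1c for a glucose-lowering
target): the instrument then mimics the drug's direction of effect.
No p-value filter is applied — with a handful of cis instruments the
downstream estimator (debiased IVW) is expected to absorb weak
instruments — but the joined set is LD-pruned (default r2 < 0.001,
with a relaxed 0.8 sensitivity preset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError
from .sumstats import (
    HarmonizedDataset,
    LDMatrix,
    SummaryStats,
    clump,
    harmonize,
)

DEFAULT_R2 = 0.001
RELAXED_R2 = 0.8


@dataclass
class InhibitionInstrumentSet:
    """Instruments for the inhibition exposure, expression-lowering oriented.

    ``oriented_betas`` are effects on the inhibition exposure (positive
    = more inhibition = less expression); ``biomarker_effects`` are the
    matching oriented biomarker estimates, negative for every retained
    SNP. ``provenance`` logs tissue, LD threshold, and counts at each
    filter stage (non-increasing).
    """

    snp_ids: list
    oriented_betas: np.ndarray
    oriented_ses: np.ndarray
    effect_allele: np.ndarray
    other_allele: np.ndarray
    biomarker_effects: np.ndarray
    biomarker_ses: np.ndarray
    eqtl_pvalues: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.snp_ids) == 0:
            raise EmptyDatasetError("inhibition instrument set is empty")
        if (np.asarray(self.biomarker_effects) >= 0).any():
            raise ValueError("every retained SNP must have a negative oriented biomarker effect")
        counts = self.provenance.get("stage_counts")
        if counts and any(b > a for a, b in zip(counts.values(), list(counts.values())[1:])):
            raise ValueError("stage counts must be non-increasing")

    def __len__(self):
        return len(self.snp_ids)

    def exposure_table(self, trait_label: str = "inhibition") -> SummaryStats:
        """The instrument set as a SummaryStats table for downstream harmonization."""
        return SummaryStats(
            pd.DataFrame(
                {
                    "SNP": self.snp_ids,
                    "EA": self.effect_allele,
                    "OA": self.other_allele,
                    "EAF": np.nan,
                    "BETA": self.oriented_betas,
                    "SE": self.oriented_ses,
                    "P": self.eqtl_pvalues,
                    "N": np.nan,
                }
            ),
            trait_label=trait_label,
        )


def orient_to_lowering(eqtl: SummaryStats) -> SummaryStats:
    """Flip each row so the effect allele LOWERS expression (BETA <= 0).

    The table stays on the expression scale; rows already oriented are
    untouched, so applying the orientation twice is a no-op.
    """
    t = eqtl.table.copy()
    flip = t["BETA"].to_numpy() > 0
    ea = t["EA"].to_numpy(dtype=object)
    oa = t["OA"].to_numpy(dtype=object)
    ea[flip], oa[flip] = t.loc[flip, "OA"].to_numpy(), t.loc[flip, "EA"].to_numpy()
    t["EA"], t["OA"] = ea, oa
    t["BETA"] = -np.abs(t["BETA"])
    t.loc[flip, "EAF"] = 1.0 - t.loc[flip, "EAF"]
    return SummaryStats(t, trait_label=eqtl.trait_label or "inhibition")


def pool_tissues(tables: list, dedupe: bool = True) -> SummaryStats:
    """Pool per-tissue lead-SNP tables, keeping the smallest eQTL p per SNP."""
    df = pd.concat([t.table for t in tables], ignore_index=True)
    if dedupe:
        df = df.sort_values(["P", "SNP"], kind="mergesort").drop_duplicates("SNP")
    return SummaryStats(df.reset_index(drop=True), trait_label=tables[0].trait_label)


def build_inhibition_exposure(
    eqtl: SummaryStats,
    biomarker: SummaryStats,
    ld: LDMatrix,
    r2_threshold: float = DEFAULT_R2,
    tissue_label: str = "pooled",
) -> InhibitionInstrumentSet:
    """Construct the inhibition instrument set.

    Stages: (1) orient each lead cis-eQTL to its expression-lowering
    allele; (2) harmonize with the biomarker table; (3) retain SNPs
    whose oriented biomarker effect is strictly negative; (4) LD-prune
    the joined set at ``r2_threshold`` (ordered by eQTL p-value); no
    p-value filter anywhere. Stage counts are logged in provenance.
    """
    stage_counts = {"input": len(eqtl)}
    oriented = orient_to_lowering(eqtl)
    stage_counts["oriented"] = len(oriented)

    ds = harmonize([oriented], biomarker, palindrome_policy="keep")
    stage_counts["joined"] = ds.n_snps

    neg = ds.outcome_beta < 0
    if not neg.any():
        raise EmptyDatasetError(
            "no SNP has a negative oriented biomarker effect; the inhibition "
            "exposure cannot be instrumented"
        )
    ds_neg = ds.subset(neg)
    stage_counts["negative_biomarker"] = ds_neg.n_snps

    exposures, _ = ds_neg.harmonized_tables()
    kept = clump(exposures[0].subset(ds_neg.snp_ids), ld, r2_threshold=r2_threshold)
    stage_counts["ld_pruned"] = len(kept)
    order = [list(ds_neg.snp_ids).index(s) for s in kept]

    # expression-scale lowering effects become positive inhibition effects
    return InhibitionInstrumentSet(
        snp_ids=[str(ds_neg.snp_ids[i]) for i in order],
        oriented_betas=-ds_neg.exposure_beta[order, 0],
        oriented_ses=ds_neg.exposure_se[order, 0],
        effect_allele=ds_neg.effect_allele[order],
        other_allele=ds_neg.other_allele[order],
        biomarker_effects=ds_neg.outcome_beta[order],
        biomarker_ses=ds_neg.outcome_se[order],
        eqtl_pvalues=ds_neg.exposure_pvalue[order, 0],
        provenance={
            "tissue": tissue_label,
            "r2_threshold": r2_threshold,
            "p_filter": "none",
            "stage_counts": stage_counts,
        },
    )


def inhibition_outcome_dataset(
    instruments: InhibitionInstrumentSet, outcome: SummaryStats
) -> HarmonizedDataset:
    """Harmonize the inhibition instruments with an outcome table for estimation."""
    ds = harmonize([instruments.exposure_table()], outcome, palindrome_policy="keep")
    ds.meta["drug_target_provenance"] = instruments.provenance
    return ds
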
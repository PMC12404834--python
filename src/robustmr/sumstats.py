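"""GWAS summary-statistics data layer.

Reads, validates, harmonizes, LD-prunes, and p-value-selects per-SNP
association tables. Every estimator in the package consumes the
:class:`HarmonizedDataset` produced here: an allele-aligned inner join
of one or more exposure tables (per-SNP effects ``gamma_hat`` with
standard errors ``sigma_x``) with one outcome table (``Gamma_hat``,
``sigma_y``).

Conventions
-----------
* Effects are per copy of the effect allele; binary-trait effects are
  on the log-odds scale.
* Harmonization aligns every source to the *first* exposure table's
  effect allele. A swapped allele pair flips the beta sign and replaces
  eaf by 1 - eaf; strand-complement pairs are reconciled the same way.
* Palindromic SNPs (A/T or G/C) cannot be strand-checked from alleles
  alone: the default policy drops them when the effect-allele frequency
  is missing or uninformative (within [0.42, 0.58] on either side) and
  otherwise uses frequency concordance to orient them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, EmptyDatasetError, ValidationError

CANONICAL_COLUMNS = ["SNP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
MANDATORY_COLUMNS = ["SNP", "EA", "OA", "BETA", "SE", "P"]
_VALID_ALLELES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROME_EAF_WINDOW = (0.42, 0.58)


# ---------------------------------------------------------------------------
# SummaryStats
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """One source's per-SNP association table.

    Wraps a DataFrame with canonical columns SNP, EA, OA, EAF, BETA,
    SE, P, N (EAF and N may be NaN). Invariants: SE > 0, P in (0, 1],
    unique SNP ids, EA != OA, alleles in {A,C,G,T}.
    """

    table: pd.DataFrame
    trait_label: str = ""

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True).copy()
        for col in ("EAF", "N"):
            if col not in self.table.columns:
                self.table[col] = np.nan
        missing = [c for c in MANDATORY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ConfigError(f"summary statistics missing mandatory columns: {missing}")
        self.table = self.table[CANONICAL_COLUMNS]
        self.table["SNP"] = self.table["SNP"].astype(str)
        for c in ("EA", "OA"):
            self.table[c] = self.table[c].astype(str).str.upper()
        for c in ("EAF", "BETA", "SE", "P", "N"):
            self.table[c] = pd.to_numeric(self.table[c], errors="coerce")
        self.validate()

    def validate(self) -> None:
        t = self.table
        bad_se = t.loc[~(t["SE"] > 0), "SNP"]
        if len(bad_se):
            raise ValidationError(
                f"non-positive or missing SE for SNPs: {list(bad_se)}", snp_ids=bad_se
            )
        bad_p = t.loc[~((t["P"] > 0) & (t["P"] <= 1)), "SNP"]
        if len(bad_p):
            raise ValidationError(
                f"p-values outside (0, 1] for SNPs: {list(bad_p)}", snp_ids=bad_p
            )
        dup = t.loc[t["SNP"].duplicated(), "SNP"]
        if len(dup):
            raise ValidationError(f"duplicate SNP ids: {sorted(set(dup))}", snp_ids=dup)
        same = t.loc[t["EA"] == t["OA"], "SNP"]
        if len(same):
            raise ValidationError(
                f"effect allele equals other allele for SNPs: {list(same)}", snp_ids=same
            )
        bad_allele = t.loc[
            ~(t["EA"].isin(_VALID_ALLELES) & t["OA"].isin(_VALID_ALLELES)), "SNP"
        ]
        if len(bad_allele):
            raise ValidationError(
                f"alleles outside A/C/G/T for SNPs: {list(bad_allele)}",
                snp_ids=bad_allele,
            )
        eaf = t["EAF"].dropna()
        if ((eaf < 0) | (eaf > 1)).any():
            raise ValidationError("EAF outside [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.table["SNP"].to_numpy()

    def subset(self, snp_ids) -> "SummaryStats":
        keep = self.table[self.table["SNP"].isin(set(snp_ids))]
        return SummaryStats(keep, trait_label=self.trait_label)


def read_sumstats(path, dialect: dict | None = None, trait_label: str = "",
                  sep: str | None = None) -> SummaryStats:
    """Read a delimited summary-statistics table.

    ``dialect`` maps file column names onto the canonical fields, e.g.
    ``{"rsid": "SNP", "effect_allele": "EA", ...}``. Columns already
    canonically named need no entry. The delimiter is sniffed from the
    header (tab preferred) unless ``sep`` is given.
    """
    df = pd.read_csv(path, sep=sep if sep is not None else None, engine="python")
    if dialect:
        unknown = [v for v in dialect.values() if v not in CANONICAL_COLUMNS]
        if unknown:
            raise ConfigError(f"dialect maps onto unknown canonical columns: {unknown}")
        df = df.rename(columns=dialect)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(
            f"missing mandatory columns {missing}; provide a dialect mapping "
            f"(canonical header: {CANONICAL_COLUMNS})"
        )
    return SummaryStats(df, trait_label=trait_label)


def write_sumstats(ss: SummaryStats, path, sep: str = "\t") -> None:
    ss.table.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# LD matrix
# ---------------------------------------------------------------------------


@dataclass
class LDMatrix:
    """Symmetric p x p matrix of squared LD correlations with unit diagonal."""

    snp_ids: list
    r2: np.ndarray

    def __post_init__(self):
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r2 = np.asarray(self.r2, dtype=float)
        p = len(self.snp_ids)
        if self.r2.shape != (p, p):
            raise ValidationError("LD matrix shape does not match SNP id list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12):
            raise ValidationError("LD matrix diagonal is not 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValidationError("LD r2 values outside [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def submatrix(self, snp_ids) -> "LDMatrix":
        missing = [s for s in snp_ids if str(s) not in self._index]
        if missing:
            raise ValidationError(f"SNPs absent from LD matrix: {missing}", snp_ids=missing)
        idx = [self._index[str(s)] for s in snp_ids]
        return LDMatrix([str(s) for s in snp_ids], self.r2[np.ix_(idx, idx)])


def read_ld_matrix(path, sep: str = "\t") -> LDMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return LDMatrix(list(df.columns), df.to_numpy())


def write_ld_matrix(ld: LDMatrix, path, sep: str = "\t") -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# HarmonizedDataset
# ---------------------------------------------------------------------------


@dataclass
class HarmonizedDataset:
    """Allele-aligned exposure(s)/outcome join; the unit of all estimation.

    exposure_beta/exposure_se/exposure_pvalue are (p, K) arrays, one
    column per exposure; outcome_beta/outcome_se are length-p vectors.
    ``orientation`` records, per SNP and source, the flip applied so the
    original signs are exactly reconstructible. ``meta`` carries trait
    labels and selection provenance (p threshold, clumping r2, drop log).
    """

    snp_ids: np.ndarray
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    exposure_pvalue: np.ndarray | None = None
    exposure_eaf: np.ndarray | None = None
    outcome_eaf: np.ndarray | None = None
    effect_allele: np.ndarray | None = None
    other_allele: np.ndarray | None = None
    orientation: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.exposure_beta = np.atleast_2d(np.asarray(self.exposure_beta, dtype=float))
        self.exposure_se = np.atleast_2d(np.asarray(self.exposure_se, dtype=float))
        if self.exposure_beta.shape[0] == 1 and len(self.snp_ids) != 1:
            self.exposure_beta = self.exposure_beta.T
            self.exposure_se = self.exposure_se.T
        self.outcome_beta = np.asarray(self.outcome_beta, dtype=float).ravel()
        self.outcome_se = np.asarray(self.outcome_se, dtype=float).ravel()
        if self.exposure_pvalue is not None:
            self.exposure_pvalue = np.atleast_2d(np.asarray(self.exposure_pvalue, dtype=float))
            if self.exposure_pvalue.shape[0] == 1 and len(self.snp_ids) != 1:
                self.exposure_pvalue = self.exposure_pvalue.T
        p = len(self.snp_ids)
        shapes_ok = (
            self.exposure_beta.shape[0] == p
            and self.exposure_se.shape == self.exposure_beta.shape
            and self.outcome_beta.shape == (p,)
            and self.outcome_se.shape == (p,)
        )
        if not shapes_ok:
            raise ValidationError("harmonized arrays do not share length p")
        if p == 0:
            raise EmptyDatasetError("harmonized dataset has no SNPs")
        if (self.exposure_se <= 0).any() or (self.outcome_se <= 0).any():
            raise ValidationError("all standard errors must be > 0")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposures(self) -> int:
        return self.exposure_beta.shape[1]

    def subset(self, mask_or_ids) -> "HarmonizedDataset":
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            mask = mask_or_ids
        else:
            wanted = set(str(s) for s in mask_or_ids)
            mask = np.array([str(s) in wanted for s in self.snp_ids])
        if not mask.any():
            raise EmptyDatasetError("subset would remove every SNP")
        return HarmonizedDataset(
            snp_ids=self.snp_ids[mask],
            exposure_beta=self.exposure_beta[mask],
            exposure_se=self.exposure_se[mask],
            outcome_beta=self.outcome_beta[mask],
            outcome_se=self.outcome_se[mask],
            exposure_pvalue=None if self.exposure_pvalue is None else self.exposure_pvalue[mask],
            exposure_eaf=None if self.exposure_eaf is None else self.exposure_eaf[mask],
            outcome_eaf=None if self.outcome_eaf is None else self.outcome_eaf[mask],
            effect_allele=None if self.effect_allele is None else self.effect_allele[mask],
            other_allele=None if self.other_allele is None else self.other_allele[mask],
            orientation=None if self.orientation is None else
            self.orientation[self.orientation["SNP"].isin(set(map(str, self.snp_ids[mask])))].reset_index(drop=True),
            meta=dict(self.meta),
        )

    def single_exposure(self):
        """(gamma_hat, sigma_x) for the first (or only) exposure."""
        return self.exposure_beta[:, 0], self.exposure_se[:, 0]

    def to_frame(self) -> pd.DataFrame:
        cols = {"SNP": self.snp_ids}
        if self.effect_allele is not None:
            cols["EA"] = self.effect_allele
            cols["OA"] = self.other_allele
        labels = self.meta.get("exposure_labels") or [
            f"exposure{k+1}" for k in range(self.n_exposures)
        ]
        for k, lab in enumerate(labels):
            cols[f"beta_{lab}"] = self.exposure_beta[:, k]
            cols[f"se_{lab}"] = self.exposure_se[:, k]
            if self.exposure_pvalue is not None:
                cols[f"p_{lab}"] = self.exposure_pvalue[:, k]
        cols["beta_outcome"] = self.outcome_beta
        cols["se_outcome"] = self.outcome_se
        return pd.DataFrame(cols)

    def write(self, path, provenance_path=None, sep: str = "\t") -> None:
        """Serialize the join as a delimited table plus a key-value side-car."""
        self.to_frame().to_csv(path, sep=sep, index=False)
        if provenance_path is not None:
            with open(provenance_path, "w") as fh:
                for key, val in sorted(self.meta.items()):
                    if key == "drop_log":
                        for entry in val:
                            fh.write(f"dropped\t{entry['SNP']}\t{entry['source']}\t{entry['reason']}\n")
                    else:
                        fh.write(f"{key}\t{val}\n")

    def harmonized_tables(self) -> tuple[list[SummaryStats], SummaryStats]:
        """Reconstruct aligned SummaryStats per source (all on the joint orientation)."""
        if self.effect_allele is None:
            raise ValidationError("allele columns not retained; cannot rebuild tables")
        labels = self.meta.get("exposure_labels") or [
            f"exposure{k+1}" for k in range(self.n_exposures)
        ]
        exposures = []
        for k, lab in enumerate(labels):
            df = pd.DataFrame(
                {
                    "SNP": self.snp_ids,
                    "EA": self.effect_allele,
                    "OA": self.other_allele,
                    "EAF": self.exposure_eaf if self.exposure_eaf is not None else np.nan,
                    "BETA": self.exposure_beta[:, k],
                    "SE": self.exposure_se[:, k],
                    "P": self.exposure_pvalue[:, k]
                    if self.exposure_pvalue is not None
                    else 0.5,
                    "N": np.nan,
                }
            )
            exposures.append(SummaryStats(df, trait_label=lab))
        out = pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "EA": self.effect_allele,
                "OA": self.other_allele,
                "EAF": self.outcome_eaf if self.outcome_eaf is not None else np.nan,
                "BETA": self.outcome_beta,
                "SE": self.outcome_se,
                "P": 0.5,
                "N": np.nan,
            }
        )
        return exposures, SummaryStats(out, trait_label=self.meta.get("outcome_label", ""))


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def _match_alleles(ref_ea, ref_oa, ea, oa):
    """How does (ea, oa) relate to the reference pair?

    Returns one of 'same', 'swap', 'same_flipstrand', 'swap_flipstrand',
    or None when the pairs are irreconcilable.
    """
    if (ea, oa) == (ref_ea, ref_oa):
        return "same"
    if (ea, oa) == (ref_oa, ref_ea):
        return "swap"
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (cea, coa) == (ref_ea, ref_oa):
        return "same_flipstrand"
    if (cea, coa) == (ref_oa, ref_ea):
        return "swap_flipstrand"
    return None


def harmonize(
    exposure_tables,
    outcome_table: SummaryStats,
    palindrome_policy: str = "default",
    eaf_window: tuple = PALINDROME_EAF_WINDOW,
) -> HarmonizedDataset:
    """Inner-join exposure table(s) with the outcome on SNP id and align alleles.

    The first exposure defines the reference orientation. Swapped allele
    pairs flip the beta sign and replace eaf by 1 - eaf. Palindromic
    SNPs are handled per ``palindrome_policy``:

    * ``"default"`` — drop when eaf is missing on either side or when
      either eaf lies within ``eaf_window``; otherwise orient by
      frequency concordance.
    * ``"strict"`` — drop every palindromic SNP.
    * ``"keep"`` — trust the allele labels as-is (no strand inference).

    Missing eaf anywhere forces strict handling for the affected SNP.
    """
    if isinstance(exposure_tables, SummaryStats):
        exposure_tables = [exposure_tables]
    if len(exposure_tables) < 1:
        raise ConfigError("at least one exposure table is required")
    if palindrome_policy not in ("default", "strict", "keep"):
        raise ConfigError(f"unknown palindrome policy {palindrome_policy!r}")

    sources = [("exposure1", exposure_tables[0])]
    sources += [(f"exposure{k+2}", t) for k, t in enumerate(exposure_tables[1:])]
    sources += [("outcome", outcome_table)]

    common = set(sources[0][1].table["SNP"])
    for _, tab in sources[1:]:
        common &= set(tab.table["SNP"])
    if not common:
        raise EmptyDatasetError("no SNPs shared by all exposure and outcome tables")

    ref = sources[0][1].table.set_index("SNP")
    frames = {name: tab.table.set_index("SNP") for name, tab in sources}
    snp_order = [s for s in sources[0][1].table["SNP"] if s in common]

    drop_log = []
    orient_rows = []
    kept = []
    lo, hi = eaf_window

    for snp in snp_order:
        ref_row = ref.loc[snp]
        ref_ea, ref_oa = ref_row["EA"], ref_row["OA"]
        actions = {}
        ok = True
        for name, _tab in sources:
            row = frames[name].loc[snp]
            rel = _match_alleles(ref_ea, ref_oa, row["EA"], row["OA"])
            if rel is None:
                drop_log.append({"SNP": snp, "source": name, "reason": "incompatible_alleles"})
                ok = False
                break
            palindromic = _is_palindromic(row["EA"], row["OA"])
            if palindromic and name != sources[0][0]:
                # strand cannot be read off the alleles; fall back to policy
                if palindrome_policy == "strict":
                    drop_log.append({"SNP": snp, "source": name, "reason": "palindromic_strict"})
                    ok = False
                    break
                if palindrome_policy == "default":
                    eaf_ref, eaf_row = ref_row["EAF"], row["EAF"]
                    ambiguous = (
                        pd.isna(eaf_ref)
                        or pd.isna(eaf_row)
                        or (lo <= eaf_ref <= hi)
                        or (lo <= eaf_row <= hi)
                    )
                    if ambiguous:
                        drop_log.append(
                            {"SNP": snp, "source": name, "reason": "palindromic_ambiguous_eaf"}
                        )
                        ok = False
                        break
                    # same-strand reading: eaf of the aligned allele should agree in side
                    aligned_eaf = row["EAF"] if rel in ("same", "same_flipstrand") else 1 - row["EAF"]
                    rel = ("same" if rel in ("same", "same_flipstrand") else "swap")
                    if (aligned_eaf > 0.5) != (eaf_ref > 0.5):
                        # frequencies disagree: the reported strand must be flipped,
                        # which for a palindrome swaps effect/other allele
                        rel = "swap" if rel == "same" else "same"
                # policy "keep": trust labels, rel already set
            actions[name] = rel
        if ok:
            kept.append(snp)
            for name, rel in actions.items():
                orient_rows.append({"SNP": snp, "source": name, "action": rel})

    if not kept:
        raise EmptyDatasetError("harmonization dropped every shared SNP")

    def _aligned(name):
        tab = frames[name].loc[kept]
        acts = pd.DataFrame([r for r in orient_rows if r["source"] == name]).set_index("SNP")
        flip = acts.loc[kept, "action"].isin(["swap", "swap_flipstrand"]).to_numpy()
        beta = tab["BETA"].to_numpy(dtype=float).copy()
        eaf = tab["EAF"].to_numpy(dtype=float).copy()
        beta[flip] = -beta[flip]
        eaf[flip] = 1.0 - eaf[flip]
        return beta, tab["SE"].to_numpy(dtype=float), tab["P"].to_numpy(dtype=float), eaf

    exp_names = [name for name, _ in sources[:-1]]
    betas, ses, pvals, eafs = [], [], [], []
    for name in exp_names:
        b, s, p_, e = _aligned(name)
        betas.append(b)
        ses.append(s)
        pvals.append(p_)
        eafs.append(e)
    ob, os_, _op, oeaf = _aligned("outcome")

    orientation = pd.DataFrame(orient_rows)
    meta = {
        "exposure_labels": [t.trait_label or n for (n, t) in sources[:-1]],
        "outcome_label": outcome_table.trait_label or "outcome",
        "palindrome_policy": palindrome_policy,
        "drop_log": drop_log,
        "n_dropped": len({d["SNP"] for d in drop_log}),
    }
    return HarmonizedDataset(
        snp_ids=np.array(kept, dtype=object),
        exposure_beta=np.column_stack(betas),
        exposure_se=np.column_stack(ses),
        outcome_beta=ob,
        outcome_se=os_,
        exposure_pvalue=np.column_stack(pvals),
        exposure_eaf=eafs[0],
        outcome_eaf=oeaf,
        effect_allele=ref.loc[kept, "EA"].to_numpy(dtype=object),
        other_allele=ref.loc[kept, "OA"].to_numpy(dtype=object),
        orientation=orientation,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Clumping and instrument selection
# ---------------------------------------------------------------------------


def clump(
    table: SummaryStats,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    tie_break: str = "snp_id",
) -> list:
    """Greedy LD pruning: keep the best remaining SNP by p-value, drop its LD partners.

    Returns kept SNP ids in the order they were selected. Ties in
    p-value break lexicographically on SNP id (deterministic).
    """
    if tie_break != "snp_id":
        raise ConfigError("only tie_break='snp_id' is supported")
    sub = ld.submatrix(list(table.snp_ids))  # raises naming missing SNPs
    order = table.table.sort_values(["P", "SNP"], kind="mergesort")
    idx = {s: i for i, s in enumerate(sub.snp_ids)}
    alive = {s: True for s in sub.snp_ids}
    kept = []
    for snp in order["SNP"]:
        if not alive[snp]:
            continue
        kept.append(snp)
        row = sub.r2[idx[snp]]
        for other, j in idx.items():
            if alive[other] and other != snp and row[j] > r2_threshold:
                alive[other] = False
    return kept


GENOME_WIDE_P = 5e-8


def select_instruments(ds: HarmonizedDataset, p_threshold: float = 1e-4) -> HarmonizedDataset:
    """Keep SNPs with first-exposure p-value < ``p_threshold``.

    Records the threshold and the count of genome-wide-significant
    survivors (p < 5e-8) in ``meta``.
    """
    if ds.exposure_pvalue is None:
        raise ConfigError("exposure p-values unavailable; cannot select instruments")
    pvals = ds.exposure_pvalue[:, 0]
    mask = pvals < p_threshold
    if not mask.any():
        raise EmptyDatasetError(
            f"no SNPs pass p < {p_threshold:g}; consider relaxing the threshold"
        )
    out = ds.subset(mask)
    out.meta = dict(out.meta)
    out.meta["p_threshold"] = p_threshold
    out.meta["n_selected"] = int(mask.sum())
    out.meta["n_genome_wide"] = int((pvals[mask] < GENOME_WIDE_P).sum())
    return out
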
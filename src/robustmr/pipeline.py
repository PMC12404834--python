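"""Config-driven study orchestration and report generation.

``run_study`` reproduces the analysis shape of a drug-target MR study
end-to-end: instrument selection -> univariable estimators (full
method roster) -> robust profile + mode detection -> multivariable
adjustment for user-supplied confounders when the profile is
multimodal -> mediation (when a mediator source is given) -> the
drug-target arm (inhibition proxy + debiased IVW). Every stochastic
stage is seeded from the study seed; a stage failure is recorded in
the report and halts only that stage.

Inputs come either from delimited summary-statistics files or from the
synthetic generator (``simulate:`` block in the config). The report is
a set of machine-readable tables plus a markdown summary; odds-ratio
columns are always computed from the beta columns, never stored
independently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bma import run_beside, summarize
from .drug_target import build_inhibition_exposure, inhibition_outcome_dataset
from .estimators import divw, ivw, or_from_beta, raps
from .exceptions import ConfigError, RobustMRError
from .mediation import run_mediation
from .profile import conditional_q, detect_modes, marker_snps, mvmr_fit, residual_qq, robust_profile
from .sumstats import (
    harmonize,
    read_ld_matrix,
    read_sumstats,
    select_instruments,
)
from .synthetic import (
    DrugTargetSimConfig,
    GammaSpec,
    MediationSpec,
    PleiotropySpec,
    SelectionSpec,
    SimConfig,
    as_harmonized,
    simulate_drug_target,
    simulate_mediation,
    simulate_two_sample,
)

DEFAULT_METHODS = ("IVW", "dIVW", "RAPS-l2", "RAPS-huber", "RAPS-tukey")


@dataclass
class StudyConfig:
    """Parsed study configuration; see ``from_yaml`` for the file format."""

    seed: int
    out_dir: str
    simulate: dict | None = None
    exposure: dict | None = None  # {path, dialect?, label?}
    outcomes: list = field(default_factory=list)  # [{path, dialect?, label?}]
    mediator: dict | None = None
    confounders: list = field(default_factory=list)
    drug_target: dict | None = None  # {eqtl, biomarker, ld, r2_threshold?}
    ld: str | None = None
    p_threshold: float = 1e-4
    clump_r2: float = 0.001
    methods: tuple = DEFAULT_METHODS
    grid: tuple = (-2.0, 2.0, 0.001)
    beside: dict = field(default_factory=lambda: {
        "components": 1, "lambda": 0.0, "iterations": 20_000, "burn_in": 5_000,
    })
    mediation_method: str = "raps-tukey"
    plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir=None) -> "StudyConfig":
        if "seed" not in raw:
            raise ConfigError("study config requires a 'seed' key")
        if "out_dir" not in raw:
            raise ConfigError("study config requires an 'out_dir' key")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown study config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if base_dir is not None:
            cfg._resolve_paths(Path(base_dir))
        cfg._validate_paths()
        return cfg

    def _iter_path_slots(self):
        for block in [self.exposure, self.mediator, self.drug_target, *self.outcomes,
                      *self.confounders]:
            if isinstance(block, dict):
                for key in ("path", "eqtl", "biomarker", "ld"):
                    if key in block:
                        yield block, key

    def _resolve_paths(self, base: Path):
        for block, key in self._iter_path_slots():
            block[key] = str((base / block[key]).resolve()) if not Path(block[key]).is_absolute() else block[key]
        if self.ld and not Path(self.ld).is_absolute():
            self.ld = str((base / self.ld).resolve())

    def _validate_paths(self):
        if self.simulate is not None:
            return
        missing = [block[key] for block, key in self._iter_path_slots()
                   if not Path(block[key]).exists()]
        if self.ld and not Path(self.ld).exists():
            missing.append(self.ld)
        if missing:
            raise ConfigError(f"study config references missing paths: {missing}")
        if self.exposure is None or not self.outcomes:
            raise ConfigError("non-simulated study needs 'exposure' and 'outcomes'")


@dataclass
class StudyReport:
    estimates: pd.DataFrame
    drug_target: pd.DataFrame | None
    modes: pd.DataFrame
    mediation: pd.DataFrame | None
    diagnostics: pd.DataFrame
    provenance: dict
    errors: list = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)
        self.modes.to_csv(out / "modes.tsv", sep="\t", index=False)
        self.diagnostics.to_csv(out / "diagnostics.tsv", sep="\t", index=False)
        if self.drug_target is not None:
            self.drug_target.to_csv(out / "drug_target.tsv", sep="\t", index=False)
        if self.mediation is not None:
            self.mediation.to_csv(out / "mediation.tsv", sep="\t", index=False)
        with open(out / "provenance.yaml", "w") as fh:
            yaml.safe_dump(self.provenance, fh, sort_keys=True)
        with open(out / "summary.md", "w") as fh:
            fh.write(self.render_markdown())

    def render_markdown(self) -> str:
        buf = io.StringIO()
        buf.write("# Study report\n\n## Causal-effect estimates\n\n")
        buf.write(self.estimates.to_markdown(index=False))
        buf.write("\n\n## Profile-likelihood modes\n\n")
        buf.write(self.modes.to_markdown(index=False))
        if self.mediation is not None:
            buf.write("\n\n## Mediation (difference in coefficients)\n\n")
            buf.write(self.mediation.to_markdown(index=False))
        if self.drug_target is not None:
            buf.write("\n\n## Drug-target inhibition arm (debiased IVW)\n\n")
            buf.write(self.drug_target.to_markdown(index=False))
        buf.write("\n\n## Diagnostics\n\n")
        buf.write(self.diagnostics.to_markdown(index=False))
        if self.errors:
            buf.write("\n\n## Stage failures\n\n")
            for e in self.errors:
                buf.write(f"- **{e['stage']}**: {e['error']}\n")
        buf.write("\n")
        return buf.getvalue()


def _est_row(outcome_label, est):
    orr, orl, orh = or_from_beta(est)
    return {
        "outcome": outcome_label, "method": est.method, "n_snps": est.n_snps,
        "beta": est.beta, "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
        "pvalue": est.pvalue, "OR": orr, "OR_ci_low": orl, "OR_ci_high": orh,
        "condition": est.condition if est.condition is not None else np.nan,
        "tau2": est.tau2 if est.tau2 is not None else np.nan,
        "converged": est.converged,
    }


def _fit_method(ds, method):
    m = method.lower()
    if m == "ivw":
        return ivw(ds)
    if m == "divw":
        return divw(ds)
    if m.startswith("raps-"):
        return raps(ds, loss=m.split("-", 1)[1], overdispersion=False)
    if m.startswith("beside"):
        raise ConfigError("BESIDE summaries are produced by the beside stage, not the roster")
    raise ConfigError(f"unknown method {method!r}")


def _load_table(block: dict, default_label: str):
    return read_sumstats(block["path"], dialect=block.get("dialect"),
                         trait_label=block.get("label", default_label))


def _simulated_inputs(cfg: StudyConfig):
    """Build study datasets from the synthetic generator, seeded from cfg.seed."""
    sim = dict(cfg.simulate or {})
    base = SimConfig(
        p=sim.get("p", 150),
        beta=sim.get("beta", 0.3),
        gamma_dist=GammaSpec(sd=sim.get("gamma_sd", 0.4)),
        n_x=sim.get("n_x", 30_000),
        n_y=sim.get("n_y", 15_000),
        pleiotropy=PleiotropySpec(mode=sim.get("pleiotropy", "balanced"),
                                  tau=sim.get("tau", 0.01)),
        selection=SelectionSpec(mode="same_sample", p_threshold=1e-3),
        seed=cfg.seed,
    )
    exposure, outcome, _truth = simulate_two_sample(base)
    datasets = {"outcome": as_harmonized(exposure, outcome)}
    med_cfg = SimConfig(
        p=sim.get("p", 150), beta=0.0, gamma_dist=GammaSpec(sd=sim.get("gamma_sd", 0.4)),
        n_x=sim.get("n_x", 30_000), n_y=sim.get("n_y", 15_000),
        mediation=MediationSpec(), seed=cfg.seed + 1,
    )
    ds_xy, _xm, _my, ds_xmy, med_truth = simulate_mediation(med_cfg)
    drug = simulate_drug_target(DrugTargetSimConfig(seed=cfg.seed + 2))
    return datasets, (ds_xy, ds_xmy, med_truth), drug


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full study and return its report (also written to cfg.out_dir)."""
    errors = []
    est_rows, mode_rows, diag_rows = [], [], []
    mediation_df = None
    drug_df = None
    provenance = {
        "package_version": __version__,
        "seed": cfg.seed,
        "p_threshold": cfg.p_threshold,
        "clump_r2": cfg.clump_r2,
        "methods": list(cfg.methods),
        "grid": list(cfg.grid),
        "beside": dict(cfg.beside),
        "simulated": cfg.simulate is not None,
    }

    # ----- assemble inputs -----
    med_bundle = None
    drug_bundle = None
    if cfg.simulate is not None:
        datasets, med_bundle, drug_bundle = _simulated_inputs(cfg)
    else:
        exposure = _load_table(cfg.exposure, "exposure")
        datasets = {}
        for block in cfg.outcomes:
            label = block.get("label", Path(block["path"]).stem)
            outcome = _load_table(block, label)
            datasets[label] = harmonize([exposure], outcome)

    # ----- per-outcome univariable + profile stages -----
    for label, ds_full in datasets.items():
        try:
            ds = select_instruments(ds_full, cfg.p_threshold) \
                if ds_full.exposure_pvalue is not None else ds_full
        except RobustMRError as e:
            errors.append({"stage": f"selection[{label}]", "error": str(e)})
            continue
        provenance[f"n_instruments[{label}]"] = ds.n_snps
        provenance[f"n_genome_wide[{label}]"] = ds.meta.get("n_genome_wide")

        primary = None
        for method in cfg.methods:
            try:
                est = _fit_method(ds, method)
                est_rows.append(_est_row(label, est))
                if method.lower() == "raps-tukey":
                    primary = est
            except RobustMRError as e:
                errors.append({"stage": f"{method}[{label}]", "error": str(e)})

        try:
            bs = cfg.beside
            ps = run_beside(ds, n_components=bs.get("components", 1),
                            lam=bs.get("lambda", 0.0),
                            iterations=bs.get("iterations", 20_000),
                            burn_in=bs.get("burn_in", 5_000), seed=cfg.seed)
            summ = summarize(ps)
            est_rows.append({
                "outcome": label, "method": "BESIDE-MR", "n_snps": ds.n_snps,
                "beta": float(summ.beta_mean[0]), "se": float(summ.beta_sd[0]),
                "ci_low": float(summ.credible_low[0]), "ci_high": float(summ.credible_high[0]),
                "pvalue": np.nan,
                "OR": float(np.exp(summ.beta_mean[0])),
                "OR_ci_low": float(np.exp(summ.credible_low[0])),
                "OR_ci_high": float(np.exp(summ.credible_high[0])),
                "condition": np.nan,
                "tau2": float(np.median(ps.kept()[1])), "converged": True,
            })
            diag_rows.append({"outcome": label, "metric": "beside_mean_model_size",
                              "value": summ.mean_model_size})
        except RobustMRError as e:
            errors.append({"stage": f"beside[{label}]", "error": str(e)})

        curve = None
        try:
            curve = robust_profile(ds, grid_spec=cfg.grid)
            ms = detect_modes(curve)
            for rank, m in enumerate(ms.modes, 1):
                mode_rows.append({
                    "outcome": label, "rank": rank, "beta": m.beta,
                    "objective": m.objective, "curvature": m.curvature,
                    "n_marker_snps": len(marker_snps(ds, m.beta)),
                    "marker_snps": ";".join(marker_snps(ds, m.beta)[:10]),
                    "near_zero_flag": ms.near_zero_flag,
                })
            if len(ms.modes) >= 2 and cfg.confounders and cfg.simulate is None:
                conf_tables = [_load_table(b, f"confounder{i+1}")
                               for i, b in enumerate(cfg.confounders)]
                exp_tab, out_tab = ds.harmonized_tables()
                mv_ds = harmonize([exp_tab[0], *conf_tables], out_tab)
                mv = mvmr_fit(mv_ds)
                for k, lab in enumerate(mv.exposure_labels):
                    lo, hi = mv.ci(k)
                    est_rows.append({
                        "outcome": label, "method": f"MVMR[{lab}]", "n_snps": mv.n_snps,
                        "beta": float(mv.betas[k]), "se": float(mv.ses[k]),
                        "ci_low": lo, "ci_high": hi, "pvalue": float(mv.pvalues[k]),
                        "OR": float(np.exp(mv.betas[k])), "OR_ci_low": float(np.exp(lo)),
                        "OR_ci_high": float(np.exp(hi)), "condition": np.nan,
                        "tau2": np.nan, "converged": mv.converged,
                    })
        except RobustMRError as e:
            errors.append({"stage": f"profile[{label}]", "error": str(e)})

        if primary is not None:
            q, df, qp = conditional_q(ds, [primary.beta])
            diag_rows.append({"outcome": label, "metric": "cochran_q", "value": q})
            diag_rows.append({"outcome": label, "metric": "cochran_q_df", "value": df})
            diag_rows.append({"outcome": label, "metric": "cochran_q_pvalue", "value": qp})
            qq = residual_qq(ds, primary)
            diag_rows.append({"outcome": label, "metric": "shapiro_stat", "value": qq.shapiro_stat})
            diag_rows.append({"outcome": label, "metric": "shapiro_pvalue", "value": qq.shapiro_pvalue})
            if cfg.plots and curve is not None:
                from .plotting import profile_plot, qq_plot
                out = Path(cfg.out_dir)
                out.mkdir(parents=True, exist_ok=True)
                try:
                    profile_plot(curve, out / f"profile_{label}.png")
                    qq_plot(qq, out / f"qq_{label}.png")
                except Exception as e:  # plotting must never kill the study
                    errors.append({"stage": f"plots[{label}]", "error": str(e)})

    # ----- mediation -----
    try:
        if med_bundle is not None:
            ds_xy, ds_xmy, med_truth = med_bundle
            res = run_mediation(ds_xy, ds_xmy, method=cfg.mediation_method,
                                mediator_label="mediator")
            mediation_df = _mediation_frame(res, source="simulated")
        elif cfg.mediator is not None:
            exposure = _load_table(cfg.exposure, "exposure")
            mediator = _load_table(cfg.mediator, "mediator")
            rows = []
            for block in cfg.outcomes:
                label = block.get("label", Path(block["path"]).stem)
                outcome = _load_table(block, label)
                ds_xy = select_instruments(harmonize([exposure], outcome), cfg.p_threshold)
                ds_xmy = select_instruments(harmonize([exposure, mediator], outcome), cfg.p_threshold)
                res = run_mediation(ds_xy, ds_xmy, method=cfg.mediation_method,
                                    mediator_label=mediator.trait_label)
                rows.append(_mediation_frame(res, source=label))
            mediation_df = pd.concat(rows, ignore_index=True) if rows else None
    except RobustMRError as e:
        errors.append({"stage": "mediation", "error": str(e)})

    # ----- drug-target arm -----
    try:
        if drug_bundle is not None:
            eqtl, biomarker, outcome_tab, ld, _truth = drug_bundle
            r2 = (cfg.drug_target or {}).get("r2_threshold", cfg.clump_r2)
            drug_df = _drug_target_frame(eqtl, biomarker, outcome_tab, ld, r2)
        elif cfg.drug_target is not None:
            eqtl = read_sumstats(cfg.drug_target["eqtl"], trait_label="gene_expression")
            biomarker = read_sumstats(cfg.drug_target["biomarker"], trait_label="biomarker")
            ld = read_ld_matrix(cfg.drug_target["ld"])
            r2 = cfg.drug_target.get("r2_threshold", cfg.clump_r2)
            frames = []
            for block in cfg.outcomes:
                label = block.get("label", Path(block["path"]).stem)
                outcome_tab = _load_table(block, label)
                frames.append(_drug_target_frame(eqtl, biomarker, outcome_tab, ld, r2))
            drug_df = pd.concat(frames, ignore_index=True) if frames else None
    except RobustMRError as e:
        errors.append({"stage": "drug_target", "error": str(e)})

    estimates = pd.DataFrame(est_rows)
    modes = pd.DataFrame(mode_rows, columns=[
        "outcome", "rank", "beta", "objective", "curvature",
        "n_marker_snps", "marker_snps", "near_zero_flag",
    ])
    diagnostics = pd.DataFrame(diag_rows, columns=["outcome", "metric", "value"])
    report = StudyReport(estimates=estimates, drug_target=drug_df, modes=modes,
                         mediation=mediation_df, diagnostics=diagnostics,
                         provenance=provenance, errors=errors)
    report.write(cfg.out_dir)
    return report


def _mediation_frame(res, source) -> pd.DataFrame:
    return pd.DataFrame([{
        "source": source,
        "mediator": res.mediator_label,
        "total_beta": res.total.beta, "total_se": res.total.se,
        "total_ci_low": res.total.ci_low, "total_ci_high": res.total.ci_high,
        "direct_beta": res.direct_beta, "direct_se": res.direct_se,
        "direct_ci_low": res.direct_ci[0], "direct_ci_high": res.direct_ci[1],
        "indirect_beta": res.indirect_beta, "indirect_se": res.indirect_se,
        "indirect_ci_low": res.indirect_ci[0], "indirect_ci_high": res.indirect_ci[1],
        "proportion_mediated": res.proportion_mediated if res.proportion_defined else np.nan,
    }])


def _drug_target_frame(eqtl, biomarker, outcome_tab, ld, r2_threshold) -> pd.DataFrame:
    import warnings as _warnings

    instruments = build_inhibition_exposure(eqtl, biomarker, ld, r2_threshold=r2_threshold)
    ds = inhibition_outcome_dataset(instruments, outcome_tab)
    with _warnings.catch_warnings():
        _warnings.simplefilter("always")
        est = divw(ds)
    orr, orl, orh = or_from_beta(est)
    return pd.DataFrame([{
        "outcome": outcome_tab.trait_label or "outcome",
        "n_instruments": len(instruments),
        "divw_estimate": est.beta, "se": est.se,
        "ci_low": est.ci_low, "ci_high": est.ci_high, "pvalue": est.pvalue,
        "OR": orr, "OR_ci_low": orl, "OR_ci_high": orh,
        "condition": est.condition,
        "stage_counts": str(instruments.provenance["stage_counts"]),
    }])
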
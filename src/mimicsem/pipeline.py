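"""End-to-end pipeline orchestration and publication-style reporting.

``run_pipeline`` chains simulate -> prepare -> fit -> compare -> scan ->
sensitivity -> evalue -> report, writing each stage's artifact as tidy CSV
plus a YAML log (seed, bootstrap size, convergence diagnostics, exclusion
reconciliation). Rendering (``render_estimates_table``) only formats numbers already
stored in artifacts; nothing is recomputed at render time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import names as N
from .analysis import (
    DIRECT_SCAN_ALPHA,
    ComparatorReport,
    PrimaryReport,
    direct_effect_scan,
    indirect_effects,
    ordinary_regression,
    run_primary,
    sensitivity,
    SENSITIVITY_MODES,
)
from .cohort import prepare_cohort, read_cohort_csv, write_cohort_csv
from .evalue import evalue_ols
from .simulate import GeneratorConfig, GeneratingParameters, assemble_raw_population


@dataclass
class PipelineConfig:
    """Schema-validated configuration for a full pipeline run."""

    output_dir: str
    seed: int = 0
    bootstrap_b: int = 0
    compute_indices: bool = True
    run_scan: bool = False
    sensitivity_modes: tuple[str, ...] = ()
    cohort_path: str | None = None  # read a raw cohort instead of simulating
    bapwv_unit: str = "m/s"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if self.bootstrap_b < 0:
            raise ValueError("bootstrap_b must be non-negative")
        if self.bapwv_unit not in ("m/s", "cm/s"):
            raise ValueError(f"unknown baPWV unit {self.bapwv_unit!r}")
        unknown = set(self.sensitivity_modes) - set(SENSITIVITY_MODES)
        if unknown:
            raise ValueError(f"unknown sensitivity modes {sorted(unknown)}")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(f"cohort file not found: {self.cohort_path}")
        self.generator.validate()


def load_pipeline_config(path) -> PipelineConfig:
    """Read a pipeline configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    gen_kwargs = raw.pop("generator", {})
    if "indicator_means_sds" in gen_kwargs:
        gen_kwargs["indicator_means_sds"] = {
            k: tuple(v) for k, v in gen_kwargs["indicator_means_sds"].items()
        }
    for key in ("stratum_counts", "stratum_mean_doses", "expansion_per_stratum",
                "female_prop", "nagasaki_prop", "distal_prop",
                "smoking_current_prop", "smoking_past_prop", "thoracic_cum_probs",
                "abdominal_region_cuts", "n_abi_high", "n_abi_low", "age_range",
                "exposure_offset_range"):
        if key in gen_kwargs:
            gen_kwargs[key] = tuple(gen_kwargs[key])
    if "stratum_bounds" in gen_kwargs:
        gen_kwargs["stratum_bounds"] = tuple(tuple(b) for b in gen_kwargs["stratum_bounds"])
    if "sensitivity_modes" in raw:
        raw["sensitivity_modes"] = tuple(raw["sensitivity_modes"])
    cfg = PipelineConfig(generator=GeneratorConfig(**gen_kwargs), **raw)
    return cfg


def primary_table_csv(report: PrimaryReport) -> pd.DataFrame:
    """Tidy parameter table (parameter, estimate, standardized, CI)."""
    return report.table.copy()


def evalue_table(report: PrimaryReport) -> pd.DataFrame:
    """E-values for the standardized dose coefficient of each factor."""
    rows = []
    for fac in N.FACTORS:
        name = f"structural:{N.DOSE}->{fac}"
        est = float(report.table.set_index("parameter").loc[name, "standardized"])
        ci = None
        if "ci_lower" in report.table.columns:
            r = report.table.set_index("parameter").loc[name]
            if np.isfinite(r["ci_lower"]) and np.isfinite(r["ci_upper"]):
                ci = (float(r["ci_lower"]), float(r["ci_upper"]))
        res = evalue_ols(est, ci=ci, r2=float(report.r2[fac]))
        rows.append({
            "factor": fac,
            "estimate": res.estimate,
            "r2": float(report.r2[fac]),
            "rr": res.rr,
            "evalue": res.evalue,
            "evalue_ci_limit": res.evalue_ci if res.evalue_ci is not None else np.nan,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every pipeline stage; returns artifact paths by stage name."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    log: dict = {"seed": config.seed, "bootstrap_b": config.bootstrap_b}

    # simulate (or load)
    if config.cohort_path is None:
        raw = assemble_raw_population(config.generator, seed=config.seed)
        raw_path = out / "raw_cohort.csv"
        write_cohort_csv(raw, raw_path, seed=config.seed)
        artifacts["simulate"] = raw_path
    else:
        raw = read_cohort_csv(config.cohort_path)
        artifacts["simulate"] = Path(config.cohort_path)

    # prepare
    prepared, excl_log, validity_log = prepare_cohort(raw, bapwv_unit=config.bapwv_unit)
    prep_path = out / "prepared_cohort.csv"
    write_cohort_csv(prepared, prep_path, seed=config.seed)
    excl_log.to_frame().to_csv(out / "exclusion_log.csv", index=False)
    validity_log.to_csv(out / "validity_log.csv", index=False)
    artifacts["prepare"] = prep_path
    log["exclusions"] = {k: int(v) for k, v in excl_log.counts.items()}
    log["n_analyzed"] = int(excl_log.n_analyzed)

    # fit
    report = run_primary(prepared, B=config.bootstrap_b, seed=config.seed,
                         compute_indices=config.compute_indices)
    primary_table_csv(report).to_csv(out / "primary_table.csv", index=False)
    report.r2.rename("r2").to_csv(out / "r2.csv")
    artifacts["fit"] = out / "primary_table.csv"
    log["fit"] = {"converged": bool(report.model.converged_),
                  "n_iter": int(report.model.n_iter_),
                  "loglik": float(report.model.loglik_),
                  "n_used": int(report.n_used)}
    if report.indices is not None:
        pd.DataFrame([dataclasses.asdict(report.indices)]).to_csv(
            out / "fit_indices.csv", index=False)
    if report.bootstrap is not None:
        log["fit"]["bootstrap_failure_rate"] = float(report.bootstrap.failure_rate)

    indirect_effects(report.model).to_csv(out / "indirect_effects.csv", index=False)

    # compare
    comp = ordinary_regression(prepared, compute_indices=config.compute_indices)
    comp.dose_effects.to_csv(out / "comparator_dose_effects.csv", index=False)
    artifacts["compare"] = out / "comparator_dose_effects.csv"
    log["compare"] = {"aic_comparator": float(comp.aic),
                      "aic_mimic": float(report.model.aic())}
    if comp.indices is not None:
        pd.DataFrame([dataclasses.asdict(comp.indices)]).to_csv(
            out / "comparator_fit_indices.csv", index=False)

    # scan
    if config.run_scan:
        scan = direct_effect_scan(prepared, base_model=report.model)
        scan.to_csv(out / "direct_effect_scan.csv", index=False)
        artifacts["scan"] = out / "direct_effect_scan.csv"
        log["scan"] = {"alpha": DIRECT_SCAN_ALPHA,
                       "n_significant": int(scan["significant"].sum())}

    # sensitivity
    for mode in config.sensitivity_modes:
        sens = sensitivity(prepared, mode, B=0, compute_indices=False)
        primary_table_csv(sens).to_csv(out / f"sensitivity_{mode}.csv", index=False)
        artifacts[f"sensitivity_{mode}"] = out / f"sensitivity_{mode}.csv"

    # evalue
    ev = evalue_table(report)
    ev.to_csv(out / "evalues.csv", index=False)
    artifacts["evalue"] = out / "evalues.csv"

    # report
    rendered = render_estimates_table(primary_table_csv(report), report.r2, report.indices)
    (out / "report.md").write_text(rendered)
    artifacts["report"] = out / "report.md"

    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    artifacts["log"] = out / "run_log.yaml"
    return artifacts


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------
def _row_order() -> list[tuple[str, str]]:
    rows = []
    for fac in N.FACTORS:
        for ind in N.FACTOR_INDICATORS[fac]:
            rows.append(("Measurement model", f"loading:{ind}~{fac}"))
    for a, b in ((N.STIFFNESS, N.CALCIFICATION), (N.STIFFNESS, N.PLAQUE),
                 (N.CALCIFICATION, N.PLAQUE)):
        rows.append(("Factor correlations", f"factor_corr:{a}~{b}"))
    for c, i in N.DIRECT_PATHS:
        rows.append(("Other components", f"direct:{c}->{i}"))
    for a, b in N.RESIDUAL_CORR_PAIRS:
        rows.append(("Other components", f"resid_corr:{a}~{b}"))
    for fac in N.FACTORS:
        for cov in N.FACTOR_COVARIATES[fac]:
            rows.append(("Structural model", f"structural:{cov}->{fac}"))
    return rows


def render_estimates_table(table: pd.DataFrame, r2: pd.Series, indices=None) -> str:
    """Markdown table of standardized estimates in publication row order."""
    t = table.set_index("parameter")
    has_ci = "ci_lower" in t.columns
    lines = ["| Sub-model | Parameter | Standardized estimate | 95% CI |",
             "|---|---|---|---|"]
    for group, name in _row_order():
        if name not in t.index:
            continue
        est = t.loc[name, "standardized"]
        if has_ci and np.isfinite(t.loc[name, "ci_lower"]):
            ci = f"{t.loc[name, 'ci_lower']:.3f}, {t.loc[name, 'ci_upper']:.3f}"
        else:
            ci = ""
        lines.append(f"| {group} | {name} | {est:.3f} | {ci} |")
    lines.append("")
    lines.append("Factor R²: " + ", ".join(f"{f} = {r2[f]:.2f}" for f in r2.index))
    if indices is not None:
        lines.append(
            f"Model fit: chi2 = {indices.chi2:.1f} (df {indices.df}), "
            f"CFI = {indices.cfi:.3f}, RMSEA = {indices.rmsea:.3f}, "
            f"AIC = {indices.aic:.1f}"
        )
    return "\n".join(lines) + "\n"


def parse_rendered_table(text: str) -> pd.DataFrame:
    """Parse a rendered markdown table back to (parameter, standardized)."""
    rows = []
    for line in text.splitlines():
        if not line.startswith("|") or line.startswith("|---") or "Parameter" in line:
            continue
        parts = [p.strip() for p in line.strip("|").split("|")]
        if len(parts) >= 3:
            rows.append({"parameter": parts[1], "standardized": float(parts[2])})
    return pd.DataFrame(rows)
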
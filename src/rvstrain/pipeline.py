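"""End-to-end orchestration: meshes -> strains -> cohort -> survival + CART report.

All randomness flows from the single ``RunConfig.seed``; rerunning with the
same config yields byte-identical JSON artifacts. Every stage logs to stderr
and to ``run.log`` in the output directory, and every artifact records the
seed and package version.
"""
from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, mannwhitneyu

from . import __version__
from .errors import ConfigError, RVStrainError, SchemaError
from .obj_io import read_obj_dir, write_obj_series
from .stats import ADJUSTMENT_SETS, auc, cox_fit, dichotomize, endpoint_table, km_estimate, nnt_binary, nnt_continuous
from .strain import compute_strains
from .synthetic import CohortConfig, MeshCycleParams, generate_cohort, generate_mesh_cycle, read_cohort_csv, write_cohort_csv
from .tree import LogRankSurvivalTree

__all__ = ["RunConfig", "run_pipeline", "make_report", "VARIABLE_PRESETS"]

log = logging.getLogger("rvstrain")

#: candidate-variable presets for the CART stage
VARIABLE_PRESETS: dict[str, list[str]] = {
    "all22": [
        "age", "male", "bsa", "ckd", "heart_rate", "sbp", "dbp",
        "lvedvi_3d", "lvesvi_3d", "lvef_3d", "lvgls_3d",
        "lavi_max", "lavi_min", "e_over_e_prime", "tapse", "rv_s_prime",
        "rvedvi_3d", "rvesvi_3d", "rvef_3d", "rvgcs_3d", "rvgls_3d", "rvgas_3d",
    ],
    "echo15": [
        "lvedvi_3d", "lvesvi_3d", "lvef_3d", "lvgls_3d",
        "lavi_max", "lavi_min", "e_over_e_prime", "tapse", "rv_s_prime",
        "rvedvi_3d", "rvesvi_3d", "rvef_3d", "rvgcs_3d", "rvgls_3d", "rvgas_3d",
    ],
}

#: cohort variables summarized in the report, with their kinds
_REPORT_CONTINUOUS = [
    "age", "bsa", "heart_rate", "sbp", "dbp", "lvedvi_3d", "lvesvi_3d",
    "lvef_3d", "lvgls_3d", "lavi_max", "lavi_min", "e_over_e_prime", "tapse",
    "rv_s_prime", "rvedvi_3d", "rvesvi_3d", "rvef_3d", "rvgcs_3d",
    "rvgls_3d", "rvgas_3d",
]
_REPORT_BINARY = ["male", "ht", "dm", "hl", "cad", "ckd"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path = "rvstrain_run"
    seed: int = 0
    # mesh stage: analyze these OBJ directories, or simulate this many cycles
    mesh_dirs: tuple[str, ...] = ()
    simulate_mesh_subjects: int = 2
    # cohort stage: load this CSV, or simulate with this size
    cohort_csv: str | None = None
    cohort_n: int = 341
    endpoint: str = "composite"
    cart_vars: str = "all22"
    n_lat: int = 15
    n_long: int = 45
    run_strain: bool = True
    run_survival: bool = True
    run_cart: bool = True
    run_report: bool = True

    def __post_init__(self) -> None:
        for d in self.mesh_dirs:
            if not Path(d).is_dir():
                raise ConfigError(f"mesh directory does not exist: {d}")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise ConfigError(f"cohort CSV does not exist: {self.cohort_csv}")
        if self.cart_vars not in VARIABLE_PRESETS:
            raise ConfigError(
                f"unknown CART preset {self.cart_vars!r}; choose from {list(VARIABLE_PRESETS)}"
            )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [logging.StreamHandler(sys.stderr), logging.FileHandler(out_dir / "run.log")]
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in log.handlers:
        h.setFormatter(fmt)


def run_pipeline(config: RunConfig) -> dict:
    """Run all enabled stages; returns a manifest of emitted artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest: dict = {"version": __version__, "seed": config.seed, "artifacts": {}}
    log.info("rvstrain %s pipeline start (seed=%d)", __version__, config.seed)

    try:
        if config.run_strain:
            _stage_strain(config, out, manifest)
        cohort = _stage_cohort(config, out, manifest)
        endpoints = endpoint_table(cohort, config.endpoint)
        if config.run_survival:
            _stage_survival(config, cohort, endpoints, out, manifest)
        if config.run_cart:
            _stage_cart(config, cohort, endpoints, out, manifest)
        else:
            log.info("CART stage disabled")
        if config.run_report:
            report = make_report(cohort, endpoints)
            if not config.run_cart:
                report += "\n\n*CART stage was disabled for this run; no tree.json emitted.*\n"
            (out / "report.md").write_text(report)
            manifest["artifacts"]["report"] = "report.md"
            log.info("report written")
    except RVStrainError as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    _json_dump(manifest, out / "manifest.json")
    log.info("pipeline complete: %s", out)
    return manifest


def _stage_strain(config: RunConfig, out: Path, manifest: dict) -> None:
    rows = []
    if config.mesh_dirs:
        series_list = [(Path(d).name, read_obj_dir(d)) for d in config.mesh_dirs]
    else:
        series_list = []
        rng = np.random.default_rng(config.seed)
        for i in range(config.simulate_mesh_subjects):
            params = MeshCycleParams(
                longitudinal_scale_es=float(rng.uniform(0.82, 0.95)),
                circumferential_scale_es=float(rng.uniform(0.85, 0.96)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            series, _ = generate_mesh_cycle(params)
            sid = f"sim{i:03d}"
            mesh_out = out / "meshes" / sid
            write_obj_series(series, mesh_out)
            series_list.append((sid, series))
    for sid, series in series_list:
        res = compute_strains(series, config.n_lat, config.n_long)
        rows.append({"subject_id": sid, **res.to_dict()})
        log.info("strain %s: EF=%.1f%% GCS=%.1f%% GLS=%.1f%% GAS=%.1f%%",
                 sid, res.rvef_pct, res.gcs_pct, res.gls_pct, res.gas_pct)
    pd.DataFrame(rows).to_csv(out / "strain_results.csv", index=False)
    manifest["artifacts"]["strain_results"] = "strain_results.csv"


def _stage_cohort(config: RunConfig, out: Path, manifest: dict) -> pd.DataFrame:
    if config.cohort_csv is not None:
        cohort = read_cohort_csv(config.cohort_csv)
        log.info("loaded cohort: %d subjects from %s", len(cohort), config.cohort_csv)
    else:
        cohort = generate_cohort(CohortConfig(n_subjects=config.cohort_n, seed=config.seed))
        log.info("simulated cohort: %d subjects", len(cohort))
    write_cohort_csv(cohort, out / "cohort.csv")
    manifest["artifacts"]["cohort"] = "cohort.csv"
    return cohort


def _stage_survival(config, cohort, endpoints, out: Path, manifest: dict) -> None:
    records = pd.concat([endpoints[["time_months", "status"]], cohort.drop(columns=["id", "followup_months", "event"], errors="ignore")], axis=1)
    fits: dict = {"seed": config.seed, "version": __version__, "endpoint": config.endpoint}
    for var in ("rvef_3d", "rvgcs_3d", "rvgls_3d", "rvgas_3d"):
        fits[f"univariate:{var}"] = cox_fit(records, [var]).to_dict()
    for preset, adjust in ADJUSTMENT_SETS.items():
        for var in ("rvef_3d", "rvgcs_3d", "rvgls_3d", "rvgas_3d"):
            fits[f"multi:{preset}+{var}"] = cox_fit(records, adjust + [var]).to_dict()
    # dichotomized analysis: RVEF at the guideline cutoff 45%, strains at medians
    cuts = {"rvef_3d": 45.0}
    for var in ("rvgcs_3d", "rvgls_3d", "rvgas_3d"):
        cuts[var] = float(cohort[var].median())
    for var, cut in cuts.items():
        low = dichotomize(cohort[var], cut, "<")
        rec = records[["time_months", "status"]].copy()
        rec["low_group"] = low.astype(float)
        fits[f"dichotomized:{var}<{cut:g}"] = cox_fit(rec, ["low_group"]).to_dict()
        km_lo = km_estimate(endpoints.loc[low, "time_months"], endpoints.loc[low, "status"])
        km_hi = km_estimate(endpoints.loc[~low, "time_months"], endpoints.loc[~low, "status"])
        km_lo.to_frame().to_csv(out / f"km_{var}_below.csv", index=False)
        km_hi.to_frame().to_csv(out / f"km_{var}_atabove.csv", index=False)
    _json_dump(fits, out / "fits.json")
    manifest["artifacts"]["fits"] = "fits.json"
    log.info("survival fits written (%d models)", len(fits) - 3)


def _stage_cart(config, cohort, endpoints, out: Path, manifest: dict) -> None:
    variables = [v for v in VARIABLE_PRESETS[config.cart_vars] if v in cohort.columns]
    model = LogRankSurvivalTree()
    model.fit(cohort[variables], (endpoints["time_months"], endpoints["status"]))
    tree_doc = {"seed": config.seed, "version": __version__, "variables": variables,
                "tree": model.to_dict()}
    _json_dump(tree_doc, out / "tree.json")
    manifest["artifacts"]["tree"] = "tree.json"
    log.info("CART grown: %d leaves", len(model.leaves_))


def _fmt_median_iqr(x: pd.Series) -> str:
    return f"{x.median():.1f} [{x.quantile(0.25):.1f}, {x.quantile(0.75):.1f}]"


def make_report(cohort: pd.DataFrame, endpoints: pd.DataFrame) -> str:
    """Markdown group-comparison table: overall / event(+) / event(-) / p / NNT.

    Continuous variables are compared with Mann-Whitney U tests and their NNT
    uses the AUC formulation; binary variables use Fisher's exact test and the
    inverse absolute risk difference.
    """
    for col in _REPORT_CONTINUOUS + _REPORT_BINARY:
        if col not in cohort.columns:
            raise SchemaError(f"cohort table missing report column {col!r}")
    ce = endpoints["status"].to_numpy(bool)
    lines = [
        "# Cohort report",
        "",
        f"Subjects: {len(cohort)}; events: {int(ce.sum())} "
        f"({100 * ce.mean():.1f}%).",
        "",
        "| Variable | Overall | CE (+) | CE (-) | P-value | NNT |",
        "|---|---|---|---|---|---|",
    ]
    for var in _REPORT_CONTINUOUS:
        x = cohort[var].astype(float)
        if x[ce].nunique() > 1 and x[~ce].nunique() > 1:
            p = float(mannwhitneyu(x[ce], x[~ce], alternative="two-sided").pvalue)
        else:
            p = 1.0
        nnt = nnt_continuous(auc(x, ce.astype(int)))
        lines.append(
            f"| {var} | {_fmt_median_iqr(x)} | {_fmt_median_iqr(x[ce])} | "
            f"{_fmt_median_iqr(x[~ce])} | {p:.3g} | {nnt:.1f} |"
        )
    for var in _REPORT_BINARY:
        x = cohort[var].astype(int)
        table = [
            [int((x[ce] == 1).sum()), int((x[ce] == 0).sum())],
            [int((x[~ce] == 1).sum()), int((x[~ce] == 0).sum())],
        ]
        p = float(fisher_exact(table).pvalue)
        nnt = nnt_binary(float(x[ce].mean()), float(x[~ce].mean()))
        lines.append(
            f"| {var} | {x.mean() * 100:.0f}% | {x[ce].mean() * 100:.0f}% | "
            f"{x[~ce].mean() * 100:.0f}% | {p:.3g} | {nnt:.1f} |"
        )
    return "\n".join(lines) + "\n"
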
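"""End-to-end orchestration: cells → thresholds → densities → cut-offs →
association → survival, with every intermediate artifact written out.

The pipeline either ingests the three input CSVs (cells, areas, clinical)
or simulates them from the built-in cohort preset.  All tabular artifacts
are CSV with a header row; fits and test results are JSON.  Given the same
inputs and seed the whole report bundle is byte-identical between runs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import cutoff as co
from . import density as dens
from . import mixture as mix
from . import survival as surv
from . import synthetic

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Run configuration (YAML-serializable).

    Either ``simulate_preset`` ("paperlike") with a ``seed``, or explicit
    ``cells_csv``/``areas_csv``/``clinical_csv`` paths.
    """

    out_dir: str
    simulate_preset: str | None = None
    cells_csv: str | None = None
    areas_csv: str | None = None
    clinical_csv: str | None = None
    markers: list[str] = field(default_factory=lambda: ["NRF2", "TrxR1"])
    compartments: list[str] = field(default_factory=lambda: ["whole", "tumor", "stroma"])
    cutoff_rule: str = "median"
    #: overrides applied to the simulation preset's fields (e.g. a smaller
    #: n_patients or cells_per_core_mean for quick runs)
    preset_overrides: dict = field(default_factory=dict)
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = SCHEMA_VERSION

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self):
        if self.simulate_preset is None:
            missing = [
                n
                for n in ("cells_csv", "areas_csv", "clinical_csv")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(
                    f"no simulate_preset and missing input paths: {missing}"
                )
            for n in ("cells_csv", "areas_csv", "clinical_csv"):
                p = Path(getattr(self, n))
                if not p.exists():
                    raise FileNotFoundError(f"{n}: {p} does not exist")
        elif self.simulate_preset != "paperlike":
            raise ValueError(f"unknown simulate_preset {self.simulate_preset!r}")
        bad = set(self.markers) - {"NRF2", "TrxR1"}
        if bad:
            raise ValueError(f"unknown markers: {sorted(bad)}")
        bad = set(self.compartments) - {"whole", "tumor", "stroma"}
        if bad:
            raise ValueError(f"unknown compartments: {sorted(bad)}")
        if self.cutoff_rule not in ("median", "roc_youden"):
            raise ValueError(f"unknown cutoff_rule {self.cutoff_rule!r}")


def _write_json(obj, path: Path):
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate_preset == "paperlike":
        sim = synthetic.paperlike_config(cfg.seed)
        if cfg.preset_overrides:
            import dataclasses

            sim = dataclasses.replace(sim, **cfg.preset_overrides)
        tables = synthetic.generate_cohort(sim)
        return tables.cells, tables.areas, tables.clinical.reset_index()
    cells = pd.read_csv(cfg.cells_csv)
    areas = pd.read_csv(cfg.areas_csv)
    clinical = pd.read_csv(cfg.clinical_csv)
    problems = []
    for name, df, req in (
        ("cells", cells, {"patient_id", "core_id", "compartment", "intensity_CK"}),
        ("areas", areas, {"core_id", "compartment", "area_mm2"}),
        ("clinical", clinical, {"patient_id", "relapse_site", "os_months", "os_event"}),
    ):
        miss = req - set(df.columns)
        if miss:
            problems.append(f"{name}: missing columns {sorted(miss)}")
    for m in cfg.markers:
        if f"intensity_{m}" not in cells.columns:
            problems.append(f"cells: missing column intensity_{m}")
    if problems:
        raise ValueError("invalid inputs: " + "; ".join(problems))
    return cells, areas, clinical


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; returns the summary dict.

    Artifacts written under ``cfg.out_dir``: mixture fits (JSON), the
    classified cell table, the per-patient density table, cut-off results,
    the association report (univariate CSV + full JSON), the survival
    curves and log-rank test, and ``summary.json``.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": cfg.schema_version, "seed": cfg.seed}

    t0 = time.perf_counter()
    cells, areas, clinical = _load_inputs(cfg)
    logger.info(
        "inputs: %d cells, %d area rows, %d patients (%.2fs)",
        len(cells), len(areas), len(clinical), time.perf_counter() - t0,
    )

    # --- mixture thresholds, pooled over all cells per marker
    fits = {}
    for marker in ["CK"] + list(cfg.markers):
        t = time.perf_counter()
        fit = mix.fit_mixture(cells[f"intensity_{marker}"].to_numpy())
        mix.find_threshold(fit)
        fits[marker] = fit
        (out / f"fit_{marker}.json").write_text(fit.to_json() + "\n")
        logger.info(
            "threshold[%s]=%.4f (%d EM iter, %.2fs)",
            marker, fit.threshold, fit.n_iter, time.perf_counter() - t,
        )
        cells[f"pos_{marker}"] = mix.classify_cells(
            cells[f"intensity_{marker}"].to_numpy(), fit.threshold
        )
    summary["thresholds"] = {m: f.threshold for m, f in fits.items()}
    classified = cells.drop(
        columns=[c for c in cells.columns if c.startswith("true_label_")]
    )
    classified.to_csv(out / "classified_cells.csv", index=False)

    # --- densities
    densities = dens.compute_densities(classified, areas)
    densities.to_csv(out / "densities.csv")

    # --- cut-offs
    clin = clinical.set_index("patient_id").loc[densities.index]
    cns = (clin["relapse_site"] == "CNS").astype(int)
    cutoffs = {}
    labels = {}
    for marker in cfg.markers:
        for comp in cfg.compartments:
            col = f"{marker.lower()}_ck_density_{comp}"
            vals = densities[col]
            res = co.median_dichotomize(vals.to_numpy(), variable=col)
            if cfg.cutoff_rule == "roc_youden":
                keep = clin["relapse_site"].notna().to_numpy()
                res = co.roc_optimal_cutoff(
                    vals.to_numpy()[keep], cns.to_numpy()[keep], variable=col
                )
                labels[col] = pd.Series(
                    vals > res.cutoff_value, index=densities.index
                )
            else:
                labels[col] = pd.Series(
                    vals > res.cutoff_value, index=densities.index
                )
            cutoffs[col] = {
                "rule": res.rule,
                "cutoff_value": res.cutoff_value,
                "n_high": res.n_high,
                "n_low": res.n_low,
                "skewness": res.skewness,
                "excess_kurtosis": res.excess_kurtosis,
            }
    _write_json(cutoffs, out / "cutoffs.json")
    summary["cutoffs"] = cutoffs
    label_df = pd.DataFrame(labels)

    # --- association
    multi_col = (
        "nrf2_ck_density_whole"
        if "nrf2_ck_density_whole" in label_df.columns
        else label_df.columns[0]
    )
    screens = assoc.relapse_screens(label_df, clin, multivariate_density=multi_col)
    screens["univariate"].to_csv(out / "association_univariate.csv", index=False)
    multi_frame = screens["multivariate"].summary_frame()
    multi_frame.to_csv(out / "association_multivariate.csv")
    or_entries = {}
    complete = clin["relapse_site"].notna()
    for col in label_df.columns:
        table = assoc.ContingencyTable2x2.from_labels(
            label_df.loc[complete, col], cns[complete].astype(bool)
        )
        entry = {
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "fisher_p": assoc.fisher_exact(table),
        }
        try:
            orr = assoc.odds_ratio(table)
            entry.update(
                odds_ratio=orr.or_, ci_low=orr.ci_low, ci_high=orr.ci_high,
                or_method=orr.method,
            )
        except ValueError as exc:
            logger.warning("odds ratio undefined for %s: %s", col, exc)
            entry.update(odds_ratio=None, ci_low=None, ci_high=None,
                         or_method="undefined")
        try:
            chi2_stat, chi2_p = assoc.pearson_chi2(table)
            entry.update(chi2_stat=chi2_stat, chi2_p=chi2_p)
        except ValueError:
            entry.update(chi2_stat=None, chi2_p=None)
        or_entries[col] = entry
    summary["cns_relapse_or"] = or_entries
    summary["multivariate"] = {
        k: (None if not np.isfinite(v) else v)
        for k, v in multi_frame["odds_ratio"].items()
    }

    # --- survival: CNS relapse vs the rest
    surv_clin = clin[complete]
    group = np.where(surv_clin["relapse_site"] == "CNS", "CNS", "other")
    curves = surv.km_estimate(
        surv_clin["os_months"].to_numpy(),
        surv_clin["os_event"].to_numpy().astype(bool),
        group,
    )
    pd.concat([c.as_frame() for c in curves.values()]).to_csv(
        out / "km_curves.csv", index=False
    )
    lr_stat, lr_p = surv.logrank_test(
        surv_clin["os_months"].to_numpy(),
        surv_clin["os_event"].to_numpy().astype(bool),
        group,
    )
    summary["logrank"] = {
        "statistic": lr_stat,
        "p": lr_p,
        "p_rendered": surv.format_p(lr_p),
    }
    _write_json(
        {"statistic": lr_stat, "p": lr_p, "p_rendered": surv.format_p(lr_p)},
        out / "survival.json",
    )

    _write_json(summary, out / "summary.json")
    logger.info("pipeline complete in %.2fs", time.perf_counter() - t0)
    return summary
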
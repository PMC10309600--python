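"""End-to-end pipeline over a directory of pilot-study CSV exports.

:func:`reproduce_study` runs every analysis stage on a directory laid out as
the study's supplementary workbook exported sheet by sheet:

* ``sheet_a.csv`` — paired one-sheet sessions from two samplers (t-test);
* ``sheet_b.csv`` — effort-estimator training sessions;
* ``sheet_c.csv`` / ``sheet_d.csv`` — indoor/outdoor yield-performance
  sessions for both samplers (skew-t fit + exceedance at 10 ng);
* ``sheet_e.csv`` — air-quality covariates with yields (LDA importance).

Each CSV follows the dialects of :mod:`aeroyield.cli_io`. Sheets that are
absent are simply omitted from the returned report.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .air_quality_lda import AirQualityLDA
from .cli_io import AnalysisReport, read_air_csv, read_yield_csv
from .effort_estimation import EffortConfig, SheetEffortModel
from .yield_performance import SkewTYieldModel, compare_yields

__all__ = ["reproduce_study"]


def reproduce_study(
    data_dir,
    *,
    threshold_ng: float = 10.0,
    effort_config: EffortConfig = EffortConfig(),
    seed: int = 0,
) -> AnalysisReport:
    """Run the full analysis over exported pilot CSVs in ``data_dir``."""
    data_dir = Path(data_dir)
    report = AnalysisReport(
        config={"threshold_ng": threshold_ng, "effort": effort_config},
        seeds={"effort": seed},
    )
    res = report.results

    sheet_a = data_dir / "sheet_a.csv"
    if sheet_a.exists():
        ds = read_yield_csv(sheet_a)
        labels = sorted({r.sampler_label for r in ds})
        if len(labels) == 2:
            a, b = (ds.subset(lbl).total_yields for lbl in labels)
            t = compare_yields(a, b, variant="pooled")
            res["sampler_comparison"] = {"groups": labels, **t.__dict__}

    sheet_b = data_dir / "sheet_b.csv"
    if sheet_b.exists():
        ds = read_yield_csv(sheet_b)
        fit = SheetEffortModel(ds, effort_config).fit(seed=seed)
        res["effort"] = fit.estimate

    for sheet, key in (("sheet_c.csv", "indoor"), ("sheet_d.csv", "outdoor")):
        p = data_dir / sheet
        if not p.exists():
            continue
        ds = read_yield_csv(p)
        block = {}
        for label in sorted({r.sampler_label for r in ds}):
            yields = ds.subset(label).total_yields
            entry = {"n": int(yields.size), "mean_ng": float(yields.mean())}
            try:
                fit = SkewTYieldModel(yields).fit()
                for method, r in fit.exceedance_all_methods(threshold_ng).items():
                    entry[f"exceedance_{method}"] = r.probability
                entry["params"] = fit.params
            except Exception as exc:  # degenerate subgroups stay reportable
                entry["exceedance_empirical_ecdf"] = float(
                    (yields >= threshold_ng).mean()
                )
                entry["fit_error"] = str(exc)
            block[label] = entry
        res[f"yield_performance_{key}"] = block

    sheet_e = data_dir / "sheet_e.csv"
    if sheet_e.exists():
        df = read_air_csv(sheet_e)
        by_hour = {}
        if "hour_index" in df.columns:
            fits = AirQualityLDA.fit_by_hour(df, threshold_ng=threshold_ng)
            for hour, fit in fits.items():
                rep = fit.importance()
                by_hour[hour] = {
                    "importance": rep.importance,
                    "raw_auc": rep.raw_auc,
                    "model_auc_resub": fit.auc("resubstitution"),
                    "model_auc_loo": fit.auc("loo"),
                }
        else:
            fit = AirQualityLDA.from_dataframe(df, threshold_ng=threshold_ng).fit()
            rep = fit.importance()
            by_hour["all"] = {
                "importance": rep.importance,
                "raw_auc": rep.raw_auc,
                "model_auc_resub": fit.auc("resubstitution"),
                "model_auc_loo": fit.auc("loo"),
            }
        res["air_quality_lda"] = by_hour

    return report
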
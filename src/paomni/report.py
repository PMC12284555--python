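"""Aggregate evaluation reports, improvement tables and paired t-tests.

An :class:`ImprovementTable` compares two models row-by-row across
datasets.  Column semantics are fixed:

* ``ssim_pct``  — relative SSIM gain, 100 * (SSIM_a - SSIM_b) / SSIM_b;
* ``rmse_pct``  — relative error *reduction*, 100 * (RMSE_b - RMSE_a) / RMSE_b;
* ``psnr_db``   — absolute PSNR difference in dB, PSNR_a - PSNR_b;

positive always means model A is better.  Panel summaries are plain
column means (2-decimal reporting) and the truncated positive fraction
floor(100 * #positive / n).

The package ships the published cross-dataset improvement rows for
PA OmniNet versus U-net baselines on the OADAT, in vivo mouse and
vascular-phantom benchmarks (``data/published_improvements.csv``) so the
aggregation arithmetic can be exercised end-to-end without external
downloads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics as _m

__all__ = [
    "MetricReport", "TTestResult", "evaluate_pairs", "improvement_row",
    "improvement_table", "aggregate_mean", "fraction_positive", "paired_ttest",
    "published_improvements", "render_report", "DegenerateTTestError",
]

COLUMNS = ("ssim_pct", "rmse_pct", "psnr_db")


@dataclass
class MetricReport:
    """Per-image and aggregate SSIM / RMSE / PSNR for one model on one dataset."""

    dataset: str
    model: str
    ssim: np.ndarray
    rmse: np.ndarray
    psnr: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.ssim) == len(self.rmse) == len(self.psnr)):
            raise ValueError("per-image metric arrays must be equally long")

    @property
    def n(self) -> int:
        return len(self.ssim)

    @property
    def mean_ssim(self) -> float:
        return float(np.mean(self.ssim))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))

    @property
    def mean_psnr(self) -> float:
        return float(np.mean(self.psnr))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ssim": self.ssim, "rmse": self.rmse, "psnr": self.psnr})


def evaluate_pairs(preds, truths, dataset: str = "", model: str = "",
                   ssim_params: _m.SSIMParams = _m.SSIMParams()) -> MetricReport:
    """Score a list of reconstructions against ground truths."""
    s, r, p = [], [], []
    for pred, gt in zip(preds, truths, strict=True):
        s.append(_m.ssim(pred, gt, ssim_params))
        r.append(_m.rmse(pred, gt))
        p.append(_m.psnr(pred, gt, ssim_params.data_range))
    return MetricReport(dataset=dataset, model=model,
                        ssim=np.array(s), rmse=np.array(r), psnr=np.array(p))


def improvement_row(report_a: MetricReport, report_b: MetricReport) -> dict:
    """One improvement-table row comparing model A against model B."""
    if report_a.dataset != report_b.dataset:
        raise ValueError(
            f"reports compare different datasets: {report_a.dataset!r} vs {report_b.dataset!r}")
    if report_b.mean_ssim == 0 or report_b.mean_rmse == 0:
        raise ValueError("reference report has zero mean SSIM or RMSE")
    return {
        "dataset": report_a.dataset,
        "ssim_pct": 100.0 * (report_a.mean_ssim - report_b.mean_ssim) / report_b.mean_ssim,
        "rmse_pct": 100.0 * (report_b.mean_rmse - report_a.mean_rmse) / report_b.mean_rmse,
        "psnr_db": report_a.mean_psnr - report_b.mean_psnr,
    }


def improvement_table(rows: list[dict], comparison: str = "") -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["dataset", *COLUMNS])
    if not np.all(np.isfinite(df[list(COLUMNS)].to_numpy(dtype=float))):
        raise ValueError("improvement table contains non-finite entries")
    df.attrs["comparison"] = comparison
    return df


def aggregate_mean(table: pd.DataFrame, decimals: int = 2) -> dict:
    """Per-column arithmetic means, rounded for reporting."""
    if len(table) == 0:
        raise ValueError("cannot aggregate an empty table")
    return {c: round(float(table[c].mean()), decimals) for c in COLUMNS if c in table}


def fraction_positive(table: pd.DataFrame, column: str) -> int:
    """Truncated integer percent of strictly positive entries in a column."""
    vals = table[column].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ValueError("cannot summarize an empty column")
    return math.floor(100.0 * int((vals > 0).sum()) / len(vals))


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n: int
    two_sided: bool = True


class DegenerateTTestError(ValueError):
    """All paired differences identical: the t statistic is undefined."""


def paired_ttest(scores_a, scores_b) -> TTestResult:
    """Two-sided paired t-test on matched score lists (df = n - 1)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired t-test needs two equally long 1-D score lists")
    if len(a) < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise DegenerateTTestError("zero-variance paired differences")
    res = stats.ttest_rel(a, b)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue), n=len(a))


def published_improvements() -> pd.DataFrame:
    """The packaged published improvement rows (long format).

    Columns: comparison, dataset, ssim_pct, rmse_pct, psnr_db.  The
    three comparison panels are PA OmniNet generalized vs U-net
    generalized (10 datasets), specific vs specific (9), and generalized
    vs U-net specific (9).
    """
    with resources.files("paomni.data").joinpath("published_improvements.csv").open() as f:
        return pd.read_csv(f, comment="#")


def render_report(tables: dict[str, pd.DataFrame], ttests: dict[str, TTestResult],
                  out_dir: str | Path) -> list[Path]:
    """Write CSV + JSON + markdown summaries; deterministic ordering."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    summary: dict = {"tables": {}, "ttests": {}}
    lines = ["# Model comparison report", ""]
    for name in sorted(tables):
        df = tables[name]
        csv_path = out / f"{name}.csv"
        df.to_csv(csv_path, index=False, float_format="%.6f")
        written.append(csv_path)
        lines.append(f"## {name}")
        if len(df):
            agg = aggregate_mean(df)
            summary["tables"][name] = agg
            lines.append("```")
            lines.append(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
            lines.append("```")
            lines.append("Average improvement: " + ", ".join(
                f"{c}={v:.2f}" for c, v in agg.items()))
        else:
            summary["tables"][name] = {}
            lines.append("(empty)")
        lines.append("")
    for name in sorted(ttests):
        r = ttests[name]
        summary["ttests"][name] = {"t": r.t, "p": r.p, "n": r.n}
        lines.append(f"Paired t-test [{name}]: t = {r.t:.4f}, p = {r.p:.4f}, n = {r.n}")
    json_path = out / "report.json"
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    md_path = out / "report.md"
    md_path.write_text("\n".join(lines) + "\n")
    return written + [json_path, md_path]
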
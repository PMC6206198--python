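"""Bias / CV / RMSE aggregation of simulation-study output.

Per-parameter accuracy across replicates: bias = mean(estimate) - truth,
SD = across-replicate sample standard deviation (n-1), CV = SD/truth (the
truth is known in simulation; SD/mean is available as an option) and
RMSE = sqrt(bias^2 + SD^2).  Estimates can be binned by an encounter-count
covariate (e.g., total within-season recaptures) to characterize how much
data a given precision requires; default bin edges follow the study's
reporting thresholds at 300 and 1,000 total recaptures.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["PerformanceStats", "performance", "binned_performance", "subset_performance", "report"]

DEFAULT_BIN_EDGES = (300.0, 1000.0)


@dataclass(frozen=True)
class PerformanceStats:
    """Accuracy summary of one estimator across replicates."""

    bias: float
    sd: float
    cv: float
    rmse: float
    n: int
    flagged: bool = False  # too few replicates to trust


def performance(
    estimates, truth: float, cv_denominator: str = "truth", min_n: int = 2
) -> PerformanceStats:
    """Bias, SD, CV and RMSE of a vector of point estimates against truth."""
    est = np.asarray(estimates, dtype=float)
    est = est[np.isfinite(est)]
    if est.size < min_n:
        raise ValueError(f"need at least {min_n} estimates, got {est.size}")
    bias = float(est.mean() - truth)
    sd = float(est.std(ddof=1))
    if cv_denominator == "truth":
        denom = truth
    elif cv_denominator == "mean":
        denom = est.mean()
    else:
        raise ValueError("cv_denominator must be 'truth' or 'mean'")
    cv = float(sd / denom) if denom != 0 else float("nan")
    rmse = float(np.sqrt(bias**2 + sd**2))
    return PerformanceStats(bias=bias, sd=sd, cv=cv, rmse=rmse, n=int(est.size))


def binned_performance(
    study: pd.DataFrame,
    param: str = "F",
    by: str = "f2_total",
    bin_edges=DEFAULT_BIN_EDGES,
    truth: float | None = None,
    cv_denominator: str = "truth",
    min_n: int = 10,
) -> pd.DataFrame:
    """Per-bin accuracy of ``est_<param>`` binned on an encounter-count column.

    Bins are right-closed: with edges (300, 1000) the bins are <=300,
    (300, 1000] and >1000.  Bins holding fewer than ``min_n`` replicates are
    flagged; empty bins are dropped (an error if all are empty).
    """
    col = f"est_{param}"
    if col not in study.columns:
        raise ValueError(f"study table has no column {col!r}")
    if by not in study.columns:
        raise ValueError(f"study table has no column {by!r}")
    if truth is None:
        tcol = f"truth_{param}"
        if tcol not in study.columns:
            raise ValueError(f"no truth column {tcol!r}; pass truth explicitly")
        truths = study[tcol].dropna().unique()
        if len(truths) != 1:
            raise ValueError("truth varies across replicates; pass truth explicitly")
        truth = float(truths[0])
    if len(bin_edges) == 0:
        labels = ["all"]
        cut = pd.Series(pd.Categorical(["all"] * len(study), categories=labels),
                        index=study.index)
    else:
        edges = [-np.inf, *sorted(bin_edges), np.inf]
        labels = [f"<={edges[1]:g}"] + [
            f"({lo:g}, {hi:g}]" for lo, hi in zip(edges[1:-2], edges[2:-1])
        ] + [f">{edges[-2]:g}"]
        cut = pd.cut(study[by], bins=edges, labels=labels)
    rows = []
    for label in labels:
        sub = study.loc[cut == label, col].dropna()
        if sub.empty:
            continue
        if len(sub) < 2:
            rows.append(
                {"bin": label, "bias": np.nan, "sd": np.nan, "cv": np.nan,
                 "rmse": np.nan, "n": len(sub), "flagged": True}
            )
            continue
        stats = performance(sub, truth, cv_denominator)
        row = asdict(stats)
        row["bin"] = label
        row["flagged"] = stats.n < min_n
        rows.append(row)
    if not rows:
        raise ValueError("no replicates fall in any bin")
    return pd.DataFrame(rows).set_index("bin")[["bias", "sd", "cv", "rmse", "n", "flagged"]]


def subset_performance(
    study: pd.DataFrame,
    param: str,
    by: str,
    threshold: float,
    truth: float | None = None,
    cv_denominator: str = "truth",
) -> PerformanceStats:
    """Accuracy among replicates with ``by`` strictly above ``threshold``."""
    if truth is None:
        truth = float(study[f"truth_{param}"].dropna().unique()[0])
    sub = study.loc[study[by] > threshold, f"est_{param}"].dropna()
    return performance(sub, truth, cv_denominator)


def _fmt_sig(v, sig: int = 3) -> str:
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if v is None or not np.isfinite(v):
        return ""
    return f"{float(v):.{sig}g}"


def report(summary: pd.DataFrame, fmt: str, path) -> None:
    """Serialize a performance table as csv, json or a markdown table.

    Numeric markdown cells use 3 significant figures; csv/json round-trip
    losslessly through pandas.
    """
    if fmt == "csv":
        summary.to_csv(path)
    elif fmt == "json":
        summary.reset_index().to_json(path, orient="records", indent=2,
                                      double_precision=15)
    elif fmt == "markdown":
        df = summary.reset_index()
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
        lines = [header, sep]
        for _, row in df.iterrows():
            cells = [v if isinstance(v, str) else _fmt_sig(v) for v in row]
            lines.append("| " + " | ".join(cells) + " |")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")
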
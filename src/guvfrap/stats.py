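"""Condition-level summaries, two-group comparisons and report writing.

Groups of per-vesicle diffusion coefficients are summarized as mean ± sample
standard deviation with N, plus boxplot statistics.  Pairwise comparisons use
Welch's unequal-variance two-sided t-test, flagged at the 0.05 / 0.01 / 0.001
levels.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .frap import FrapResult, InvalidParameterError, results_to_frame

__all__ = [
    "GroupSummary",
    "ComparisonResult",
    "group_summary",
    "compare_groups",
    "summaries_to_frame",
    "write_report",
    "load_report",
]

SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float
    sem: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float


@dataclass
class ComparisonResult:
    labels: tuple[str, str]
    statistic: float
    p_value: float
    significant_at: list[float] = field(default_factory=list)


def group_summary(values: Sequence[float], label: str = "") -> GroupSummary:
    """Mean ± sample sd (n−1), SEM, quartiles by linear interpolation,
    whiskers at the extremes."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InvalidParameterError("group_summary needs at least one value")
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return GroupSummary(
        label=label,
        n=int(v.size),
        mean=float(v.mean()),
        sd=sd,
        sem=sd / math.sqrt(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(v.min()),
        whisker_high=float(v.max()),
    )


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    labels: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Welch's two-sided unequal-variance t-test between two groups.

    Degenerate zero-variance groups follow the convention p = 1 when the
    means coincide and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InvalidParameterError("compare_groups needs >= 2 values per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            stat, p = 0.0, 1.0
        else:
            stat, p = math.copysign(math.inf, a.mean() - b.mean()), 0.0
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        stat, p = float(stat), float(p)
    return ComparisonResult(
        labels=labels,
        statistic=stat,
        p_value=p,
        significant_at=[alpha for alpha in SIGNIFICANCE_LEVELS if p < alpha],
    )


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_report(
    results: Sequence[FrapResult],
    summaries: Sequence[GroupSummary],
    comparisons: Sequence[ComparisonResult] = (),
    outdir: str | Path = ".",
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> dict[str, Path]:
    """Write deterministic TSV + JSON outputs.

    Files: ``results.tsv`` (one row per vesicle), ``summaries.tsv``,
    ``comparisons.tsv`` (when any), and ``report.json`` bundling everything
    with a run-metadata block (config hash, seed, package version).  Re-runs
    on identical inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    res_df = results_to_frame(results)
    paths["results"] = outdir / "results.tsv"
    res_df.to_csv(paths["results"], sep="\t", index=False)

    sum_df = summaries_to_frame(summaries)
    paths["summaries"] = outdir / "summaries.tsv"
    sum_df.to_csv(paths["summaries"], sep="\t", index=False)

    comp_rows = [
        {
            "group_a": c.labels[0],
            "group_b": c.labels[1],
            "statistic": c.statistic,
            "p_value": c.p_value,
            "significant_at": ",".join(str(a) for a in c.significant_at),
        }
        for c in comparisons
    ]
    if comp_rows:
        paths["comparisons"] = outdir / "comparisons.tsv"
        pd.DataFrame(comp_rows).to_csv(paths["comparisons"], sep="\t", index=False)

    config = dict(config or {})
    payload = {
        "metadata": {
            "package": "guvfrap",
            "version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
            "config": config,
        },
        "summaries": [asdict(s) for s in summaries],
        "comparisons": [
            {"labels": list(c.labels), "statistic": c.statistic, "p_value": c.p_value,
             "significant_at": c.significant_at}
            for c in comparisons
        ],
    }
    paths["json"] = outdir / "report.json"
    paths["json"].write_text(json.dumps(payload, indent=2, sort_keys=True, allow_nan=True))
    return paths


def load_report(path: str | Path) -> tuple[list[GroupSummary], list[ComparisonResult]]:
    """Reload a report JSON into summary and comparison objects."""
    payload = json.loads(Path(path).read_text())
    summaries = [GroupSummary(**s) for s in payload["summaries"]]
    comparisons = [
        ComparisonResult(
            labels=tuple(c["labels"]),
            statistic=c["statistic"],
            p_value=c["p_value"],
            significant_at=list(c["significant_at"]),
        )
        for c in payload["comparisons"]
    ]
    return summaries, comparisons
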
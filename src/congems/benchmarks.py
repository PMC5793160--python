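"""Published validity-index benchmark tables and their pairwise comparison.

Two carcinoma case studies (an LUSC expression cohort and a uterine-cervical
methylation cohort) compare the rule-module method against ten TOM-family
gene-module baselines across nine validity indices.  The printed index
tables ship with the package as TSV; recomputing the win-draw-loss tallies
from them exercises the comparison conventions (finite beats Inf, "-" is
invalid, scaled connectivity is lower-better).
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .validity import ValidityReport, win_draw_loss

__all__ = [
    "BASELINE_METHODS",
    "load_benchmark_table",
    "benchmark_reports",
    "benchmark_win_draw_loss",
]

BASELINE_METHODS = (
    "wTOM[pcc]",
    "wTOM[sc]",
    "GTOM0[pcc]",
    "GTOM0[sc]",
    "GTOM1[pcc]",
    "GTOM1[sc]",
    "GTOM2[pcc]",
    "GTOM2[sc]",
    "GTOM3[pcc]",
    "GTOM3[sc]",
)

_DATASETS = {"lusc": "lusc_validity.tsv", "cervical": "cervical_validity.tsv"}


def load_benchmark_table(dataset: str) -> pd.DataFrame:
    """Raw benchmark table; cells are floats, Inf, or NaN for "-" entries."""
    try:
        filename = _DATASETS[dataset]
    except KeyError:
        raise ValueError(f"unknown dataset {dataset!r}; use lusc or cervical")
    with resources.files("congems.data").joinpath(filename).open() as fh:
        # "Inf" parses to +inf, "NA" to NaN.
        df = pd.read_csv(fh, sep="\t", index_col="index", na_values=["NA"])
    return df.astype(float)


def benchmark_reports(dataset: str) -> dict[str, ValidityReport]:
    """One ValidityReport per method column of a benchmark table."""
    df = load_benchmark_table(dataset)
    out: dict[str, ValidityReport] = {}
    for method in df.columns:
        values = {}
        for index, v in df[method].items():
            if pd.isna(v):
                values[index] = None
            else:
                values[index] = float(v)
        out[method] = ValidityReport(values=values, method=method)
    return out


def benchmark_win_draw_loss(dataset: str) -> dict[str, tuple[int, int, int]]:
    """Win-draw-loss of the rule-module method against every baseline."""
    reports = benchmark_reports(dataset)
    proposed = reports["proposed"]
    return {
        method: win_draw_loss(proposed, reports[method])
        for method in BASELINE_METHODS
    }
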
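"""Packaged reference datasets.

Small fixtures bundled with the package so that agreement analyses and the
worked ranking example run fully offline.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["method_comparison_rf", "ranking_worked_example", "trials_for_worked_example"]


def _data(name: str):
    return resources.files("hrvb.data").joinpath(name)


def method_comparison_rf() -> pd.DataFrame:
    """Paired RF values (breaths/min) from 10 participants assessed with
    both the sliding sweep and the stepped-and-ranked method.

    Columns: ``participant``, ``sliding_bpm``, ``stepped_bpm``.
    """
    with resources.as_file(_data("rf_method_pairs.csv")) as p:
        return pd.read_csv(p)


def ranking_worked_example() -> dict:
    """Recorded per-metric frequency orderings for one stepped assessment."""
    return json.loads(_data("rank_worked_example.json").read_text())


def trials_for_worked_example():
    """Metric-only trials inducing the worked example's rank orderings."""
    from .rf import trials_from_metric_values

    orderings = ranking_worked_example()["orderings"]
    values = {
        metric: {f: float(len(order) - k) for k, f in enumerate(order)}
        for metric, order in orderings.items()
    }
    return trials_from_metric_values(values)
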
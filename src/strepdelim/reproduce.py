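"""Recompute every calibrated quantity from the packaged table.

This is the deterministic end-to-end check behind ``strepdelim reproduce``:
it reruns the filter enumerations, the three exponential regressions, the
threshold inversions and the classifier on the packaged 80-pair table and
compares each result with its stored reference value and tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from .delineation import DEFAULT_THRESHOLDS, Thresholds, Verdict, classify_table
from .pair_metrics import Interval, MetricTable, count_where, load_packaged_table
from .regression import fit_all_metric_pairs, invert_at, predict_at

__all__ = ["CheckResult", "run_reproduce", "load_expectations"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    value: float
    expected: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.value - self.expected) <= self.tol


def load_expectations() -> dict:
    ref = resources.files("strepdelim.data").joinpath(
        "reproduce_expectations.json"
    )
    return json.loads(ref.read_text(encoding="utf-8"))


def compute_quantities(table: Optional[MetricTable] = None) -> dict[str, float]:
    """All scalar quantities the calibration produces, from scratch."""
    table = table if table is not None else load_packaged_table()
    fits = fit_all_metric_pairs(table)
    ddh_vs_anim = fits[("ddh", "anim")]
    mlsa_vs_ddh = fits[("mlsa", "ddh")]
    _, summary = classify_table(table, DEFAULT_THRESHOLDS)
    return {
        "record_count": len(table),
        "count_mlsa_ge_0.008_ddh_gt_70": count_where(
            table,
            mlsa_range=Interval.at_least(0.008),
            ddh_range=Interval.greater_than(70),
        ),
        "count_mlsa_ge_0.007_ddh_lt_70_anim_gt_96": count_where(
            table,
            mlsa_range=Interval.at_least(0.007),
            ddh_range=Interval.less_than(70),
            anim_range=Interval.greater_than(96),
        ),
        "count_mlsa_in_0.008_0.014_ddh_lt_70": count_where(
            table,
            mlsa_range=Interval(0.008, 0.014, hi_closed=False),
            ddh_range=Interval.less_than(70),
        ),
        "r2_ddh_vs_anim": ddh_vs_anim.r2,
        "r2_mlsa_vs_ddh": mlsa_vs_ddh.r2,
        "r2_mlsa_vs_anim": fits[("mlsa", "anim")].r2,
        "anim_at_ddh70": invert_at(ddh_vs_anim, 70.0),
        "mlsa_at_ddh70": predict_at(mlsa_vs_ddh, 70.0),
        "borderline_count": summary[Verdict.BORDERLINE_POLYPHASIC],
    }


def run_reproduce(
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[CheckResult], list[tuple[str, str, str, bool]], bool]:
    """Run all checks; returns (metric checks, verdict checks, all passed).

    Verdict checks are 4-tuples (species token a, species token b, verdict
    state, passed): the four emended synonym pairs must classify as
    conspecific by genome metrics.
    """
    exp = load_expectations()
    table = load_packaged_table()
    quantities = compute_quantities(table)
    checks = [
        CheckResult(
            name=name,
            value=float(quantities[name]),
            expected=float(spec["expected"]),
            tol=float(spec["tol"]),
        )
        for name, spec in exp["checks"].items()
    ]
    verdicts, _ = classify_table(table, thresholds)
    by_pair = {v.pair: v for v in verdicts}
    verdict_checks = []
    for tok_a, tok_b in exp["emendation_pairs"]:
        rec = table.find_pair(tok_a, tok_b)
        v = by_pair[(rec.species_a, rec.species_b)]
        verdict_checks.append(
            (tok_a, tok_b, v.state.value, v.state == Verdict.CONSPECIFIC_GENOME)
        )
    ok = all(c.passed for c in checks) and all(p for *_, p in verdict_checks)
    return checks, verdict_checks, ok
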
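"""Three-tier species-delineation rule for *Streptomyces*.

The rule translates pairwise relatedness metrics into a taxonomic verdict:

* With genome-scale metrics available (dDDH and/or ANIm), the pair is
  conspecific if either metric reaches its cut-off (70% dDDH or 96.7%
  ANIm); a pair falling just below both cut-offs — inside a configurable
  borderline band — is deferred to polyphasic evidence (phenotype,
  chemotaxonomy, phylogenomics); otherwise the strains are distinct
  species.
* With only the MLSA distance: below 0.008 substitutions/site the strains
  are conspecific (heterotypic synonyms); at or above 0.014 they are
  distinct species; in between, genome metrics must be obtained before a
  verdict is possible.

Genome metrics, when supplied, take precedence over the MLSA tier.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "Thresholds",
    "Verdict",
    "VerdictResult",
    "classify",
    "classify_table",
    "verdict_report",
    "DEFAULT_THRESHOLDS",
]


@dataclass(frozen=True)
class Thresholds:
    """Cut-offs and borderline band widths of the delineation rule.

    ``mlsa_low``/``mlsa_high`` bound the three MLSA tiers (distances in
    substitutions/site); ``ddh_cut``/``ani_cut`` are the conspecificity
    cut-offs in percent; ``ddh_band``/``ani_band`` are the widths (percent)
    of the just-below-cut-off bands inside which the rule defers to
    polyphasic evidence instead of calling the pair distinct.
    """

    mlsa_low: float = 0.008
    mlsa_high: float = 0.014
    ddh_cut: float = 70.0
    ani_cut: float = 96.7
    ddh_band: float = 2.0
    ani_band: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.mlsa_low < self.mlsa_high):
            raise ValueError(
                f"need 0 < mlsa_low < mlsa_high, got "
                f"({self.mlsa_low}, {self.mlsa_high})"
            )
        if self.ddh_band <= 0 or self.ani_band <= 0:
            raise ValueError("band widths must be > 0")
        for name, cut in (("ddh_cut", self.ddh_cut), ("ani_cut", self.ani_cut)):
            if not (0 < cut < 100):
                raise ValueError(f"{name}={cut} outside (0, 100)")


DEFAULT_THRESHOLDS = Thresholds()


class Verdict(Enum):
    CONSPECIFIC_MLSA = "CONSPECIFIC_MLSA"
    DISTINCT_MLSA = "DISTINCT_MLSA"
    GENOME_METRICS_REQUIRED = "GENOME_METRICS_REQUIRED"
    CONSPECIFIC_GENOME = "CONSPECIFIC_GENOME"
    DISTINCT_GENOME = "DISTINCT_GENOME"
    BORDERLINE_POLYPHASIC = "BORDERLINE_POLYPHASIC"


@dataclass(frozen=True)
class VerdictResult:
    """A verdict with the trace of the rule that fired."""

    state: Verdict
    rationale: str
    pair: Optional[tuple[str, str]] = None


def _validate(name: str, value: Optional[float], lo: float, hi: float) -> None:
    if value is not None and not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


def classify(
    mlsa: Optional[float] = None,
    ddh: Optional[float] = None,
    anim: Optional[float] = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    pair: Optional[tuple[str, str]] = None,
) -> VerdictResult:
    """Apply the delineation rule to one strain pair.

    Genome metrics (dDDH/ANIm), if given, decide the verdict regardless of
    the MLSA distance; either metric reaching its cut-off suffices for
    conspecificity.  With only MLSA the three-tier rule applies.
    """
    if mlsa is None and ddh is None and anim is None:
        raise ValueError("at least one metric must be provided")
    _validate("ddh", ddh, 0, 100)
    _validate("anim", anim, 0, 100)
    if mlsa is not None and mlsa < 0:
        raise ValueError(f"mlsa={mlsa} must be >= 0")
    t = thresholds

    if ddh is not None or anim is not None:
        ddh_hit = ddh is not None and ddh >= t.ddh_cut
        ani_hit = anim is not None and anim >= t.ani_cut
        if ddh_hit or ani_hit:
            parts = []
            if ddh_hit:
                parts.append(f"dDDH {ddh} >= {t.ddh_cut}%")
            if anim is not None and not ani_hit:
                if anim < t.ani_cut - t.ani_band:
                    parts.append(
                        f"conflict: ANIm {anim} < {t.ani_cut - t.ani_band}% "
                        "(below cut-off minus band)"
                    )
            if ani_hit:
                parts.append(f"ANIm {anim} >= {t.ani_cut}%")
            if ddh is not None and not ddh_hit:
                if ddh < t.ddh_cut - t.ddh_band:
                    parts.append(
                        f"conflict: dDDH {ddh} < {t.ddh_cut - t.ddh_band}% "
                        "(below cut-off minus band)"
                    )
            return VerdictResult(
                Verdict.CONSPECIFIC_GENOME,
                "conspecific by genome metrics (either-metric sufficiency): "
                + "; ".join(parts),
                pair,
            )
        ddh_border = ddh is not None and t.ddh_cut - t.ddh_band <= ddh < t.ddh_cut
        ani_border = anim is not None and t.ani_cut - t.ani_band <= anim < t.ani_cut
        if ddh_border or ani_border:
            parts = []
            if ddh_border:
                parts.append(
                    f"dDDH {ddh} within [{t.ddh_cut - t.ddh_band}, {t.ddh_cut})%"
                )
            if ani_border:
                parts.append(
                    f"ANIm {anim} within [{t.ani_cut - t.ani_band}, {t.ani_cut})%"
                )
            return VerdictResult(
                Verdict.BORDERLINE_POLYPHASIC,
                "just below cut-off; phenotypic, chemotaxonomic and "
                "phylogenomic evidence required: " + "; ".join(parts),
                pair,
            )
        given = [
            f"dDDH {ddh} < {t.ddh_cut - t.ddh_band}%" if ddh is not None else "",
            f"ANIm {anim} < {t.ani_cut - t.ani_band}%" if anim is not None else "",
        ]
        return VerdictResult(
            Verdict.DISTINCT_GENOME,
            "distinct species by genome metrics: "
            + "; ".join(p for p in given if p),
            pair,
        )

    # MLSA-only tiers
    if mlsa < t.mlsa_low:
        return VerdictResult(
            Verdict.CONSPECIFIC_MLSA,
            f"MLSA distance {mlsa} < {t.mlsa_low}: heterotypic synonym",
            pair,
        )
    if mlsa >= t.mlsa_high:
        return VerdictResult(
            Verdict.DISTINCT_MLSA,
            f"MLSA distance {mlsa} >= {t.mlsa_high}: distinct species",
            pair,
        )
    return VerdictResult(
        Verdict.GENOME_METRICS_REQUIRED,
        f"MLSA distance {mlsa} within [{t.mlsa_low}, {t.mlsa_high}): "
        "dDDH or ANIm must be calculated",
        pair,
    )


def classify_table(
    table, thresholds: Thresholds = DEFAULT_THRESHOLDS
) -> tuple[list[VerdictResult], Counter]:
    """Classify every record of a metric table using all three metrics.

    Errors are collected per record (re-raised together at the end) rather
    than aborting at the first bad row.
    """
    verdicts: list[VerdictResult] = []
    errors: list[str] = []
    for i, rec in enumerate(table, start=1):
        try:
            verdicts.append(
                classify(
                    mlsa=rec.mlsa,
                    ddh=rec.ddh,
                    anim=rec.anim,
                    thresholds=thresholds,
                    pair=(rec.species_a, rec.species_b),
                )
            )
        except ValueError as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValueError("classification errors: " + "; ".join(errors))
    summary = Counter(v.state for v in verdicts)
    return verdicts, summary


def verdict_report(
    verdicts: Sequence[VerdictResult], format: str = "text"
) -> str:
    """Render verdicts with their rule traces as text or JSON."""
    if format == "json":
        return json.dumps(
            [
                {
                    "pair": list(v.pair) if v.pair else None,
                    "state": v.state.value,
                    "rationale": v.rationale,
                }
                for v in verdicts
            ],
            indent=2,
        )
    if format == "text":
        lines = []
        for v in verdicts:
            label = " vs ".join(v.pair) if v.pair else "(unnamed pair)"
            lines.append(f"{label}: {v.state.value}")
            lines.append(f"    {v.rationale}")
        summary = Counter(v.state for v in verdicts)
        if verdicts:
            lines.append("")
            lines.append("summary: " + ", ".join(
                f"{s.value}={summary[s]}" for s in Verdict if summary[s]
            ))
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r} (expected 'text' or 'json')")
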
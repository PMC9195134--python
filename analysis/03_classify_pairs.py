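#!/usr/bin/env python
"""Run the three-tier delineation rule over the curated table.

Writes results/03_verdicts.json.  With default thresholds the rule marks
exactly five pairs as borderline (just below the 70% dDDH / 96.7% ANIm
cut-offs, requiring polyphasic evidence) and classifies the four pairs
proposed as heterotypic synonyms as conspecific by genome metrics.
"""

import json
from pathlib import Path

from strepdelim import Verdict, classify_table, load_packaged_table, verdict_report

OUT = Path(__file__).resolve().parents[1] / "results"

SYNONYM_PAIRS = [
    ("antimycoticus", "melanosporofaciens"),
    ("filipinensis", "durhamensis"),
    ("recifensis", "griseoluteus"),
    ("olivaceoviridis", "corchorusii"),
]


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = load_packaged_table()
    verdicts, summary = classify_table(table)
    (OUT / "03_verdicts.json").write_text(verdict_report(verdicts, "json"))
    print("verdict summary over", len(table), "pairs:")
    for state in Verdict:
        if summary[state]:
            print(f"  {state.value:<24s} {summary[state]}")
    borderline = [v for v in verdicts if v.state == Verdict.BORDERLINE_POLYPHASIC]
    print(f"\n{len(borderline)} borderline pairs requiring polyphasic review:")
    for v in borderline:
        print("  " + " / ".join(v.pair))
    print("\nproposed-synonym pairs:")
    by_pair = {frozenset(v.pair): v for v in verdicts}
    for tok_a, tok_b in SYNONYM_PAIRS:
        rec = table.find_pair(tok_a, tok_b)
        v = by_pair[rec.pair_key]
        print(f"  {tok_a}/{tok_b}: {v.state.value}")


if __name__ == "__main__":
    main()
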
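#!/usr/bin/env python
"""TRBV/TRBJ segment usage: antigen group versus adjuvant-only control.

Computes read-weighted segment-usage tables per sample over the SJL gene
panel (which lacks the strain's deleted TRBV families) and compares the
groups per segment with the pooled-variance ANOVA-style contrast and Sidak
family-wise correction. The generator boosts TRBV3 among the dominant
clones of the antigen group, so TRBV3 should be flagged and nothing else
should survive correction systematically.

Outputs: ``results/usage_comparison_trbv.tsv`` / ``..._trbj.tsv`` (also
produced by 02 inside the main report; this driver prints the narrative).
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from tcroverlap import (compare_usage, get_panel, read_airr_table,
                        read_manifest, usage_table)
from tcroverlap.pipeline import process_sample

DATA = ROOT / "scratch" / "synthetic" / "main"


def main() -> int:
    if not (DATA / "manifest.tsv").exists():
        print("run analysis/01_simulate_cohorts.py first", file=sys.stderr)
        return 1
    manifest = read_manifest(DATA / "manifest.tsv")
    panel = get_panel("SJL")
    reps = {s.sample_id: process_sample(read_airr_table(manifest.resolve(s.sample_id)),
                                        meta=s)
            for s in manifest.samples}
    for axis in ("TRBV", "TRBJ"):
        groups = {}
        for s in manifest.samples:
            groups.setdefault(s.group, []).append(
                usage_table(reps[s.sample_id], axis, panel))
        cmp = compare_usage(groups["Ag1"], groups["PBS"], method="anova")
        out = ROOT / "results" / f"usage_comparison_{axis.lower()}.tsv"
        out.parent.mkdir(exist_ok=True)
        cmp.to_csv(out, sep="\t", index=False, float_format="%.10g")
        hits = cmp[(cmp["testable"]) & (cmp["p_sidak"] < 0.05)]
        print(f"{axis}: {len(cmp)} segments, flagged after Sidak:")
        if len(hits):
            print(hits[["segment", "mean_a", "mean_b", "p_sidak"]]
                  .to_string(index=False))
        else:
            print("  none")
        print()
    print("TRBV3 carries the antigen-driven enrichment; segments deleted in "
          "the SJL locus never enter the comparison.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
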
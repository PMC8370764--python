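#!/usr/bin/env python
"""Generate the synthetic study: paired lymph-node repertoires per group.

Emulates the experimental design — an antigen-driven group and an
adjuvant-only control group, three mice each, both popliteal lymph nodes
sequenced — at study scale (3×10³ background clonotypes, 10⁶ reads per
sample), plus an antigen-group cohort followed over an early (2 wk) and a
late (7 wk) timepoint with dominant-clone decay.

Sample tables (AIRR TSV), manifests and ground truth go to
``scratch/synthetic/``; a combined main-experiment manifest is written for
the downstream drivers.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from tcroverlap import SynthConfig
from tcroverlap.repertoire_io import Manifest, write_manifest
from tcroverlap.simulate import generate_experiment, write_experiment

SEED = 20211
OUT = ROOT / "scratch" / "synthetic"


def main() -> None:
    # main experiment: Ag vs control at 4 weeks
    main_dir = OUT / "main"
    samples, file_map = [], {}
    for group in ("Ag_like", "PBS_like"):
        cfg = SynthConfig(seed=SEED, n_mice=3, group=group)
        tables, manifest, truth = generate_experiment(cfg)
        write_experiment(tables, manifest, truth, main_dir)
        samples.extend(manifest.samples)
        file_map.update(manifest.file_map)
        print(f"{group}: {len(tables)} samples, "
              f"{sum(len(t) for t in tables.values())} clonotype rows")
    write_manifest(Manifest(samples, file_map, base_dir=main_dir),
                   main_dir / "manifest.tsv")

    # temporal experiment: antigen group at 2 and 7 weeks
    cfg = SynthConfig(seed=SEED + 1, n_mice=3, timepoint_weeks=2.0)
    tables, manifest, truth = generate_experiment(cfg, timepoints=(2.0, 7.0))
    write_experiment(tables, manifest, truth, OUT / "temporal")
    print(f"temporal: {len(tables)} samples")
    print(f"written under {OUT}")


if __name__ == "__main__":
    sys.exit(main())
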
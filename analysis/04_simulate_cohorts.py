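#!/usr/bin/env python
"""Simulate the synthetic cohorts used by the downstream analyses.

One 22-subject cohort per canonical scenario (chunk recoding,
associative noise reduction, plain item-position, item mixture, null),
written in the per-subject pattern-file layout with a provenance JSON
(under scratch/: the cohorts are large and fully regenerable).
"""

import dataclasses
import json
import pathlib

import seqrecode as sq
from seqrecode.io import read_schedule, write_cohort

HERE = pathlib.Path(__file__).resolve().parent.parent
OUT = HERE / "scratch" / "cohorts"
DESIGN = HERE / "results" / "design"
N_SUBJECTS = 22


def main() -> None:
    schedule = read_schedule(DESIGN / "schedule.csv")
    for name, spec in sq.canonical_scenarios(n_voxels=150, seed=11).items():
        cohort = sq.simulate_cohort(schedule, spec, n_subjects=N_SUBJECTS)
        directory = OUT / name
        paths = write_cohort(cohort, directory)
        with open(directory / "provenance.json", "w") as fh:
            json.dump({"scenario": name, "n_subjects": N_SUBJECTS,
                       "spec": dataclasses.asdict(spec)}, fh, indent=2)
        print(f"{name}: {N_SUBJECTS} subjects x {spec.n_voxels} voxels "
              f"(sigma novel/repeating = {spec.noise_sigma}) -> "
              f"{len(paths)} files")
    print(f"wrote cohorts to {OUT}")


if __name__ == "__main__":
    main()
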
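"""Adapter for real BioSemi .bdf recordings (optional; requires a download).

The study's raw eyes-closed recordings are deposited as .bdf files in the
Huggingface dataset ``nagyadam97/EEG_records_raw_schizophrenia_bipolar``
(group labels in its README).  This script is NOT run by the test suite:
it needs the downloaded files and substantial compute at 8192 Hz.

Point --data-dir at a directory of .bdf files named however you like and
provide a labels CSV with columns ``file,group`` (group in CONTROL, PSF,
CTF).  The script preprocesses each recording, builds the feature table
and runs the requested task with the full-scale configuration.
"""

import argparse
import csv
import warnings
from pathlib import Path

warnings.filterwarnings("ignore")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=Path, required=True)
    ap.add_argument("--labels", type=Path, required=True, help="CSV: file,group")
    ap.add_argument("--task", default="C-PSF", choices=["C-PSF", "C-CTF", "CTF-PSF"])
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    from eegsel.io import read_recording
    from eegsel.pipeline import PipelineConfig, TaskSpec, run_task

    recordings = []
    with open(args.labels, newline="") as f:
        for row in csv.DictReader(f):
            rec = read_recording(args.data_dir / row["file"])
            recordings.append(rec.copy_with(group=row["group"]))
    print(f"loaded {len(recordings)} recordings")

    manifest = run_task(recordings, TaskSpec(args.task), PipelineConfig(seed=args.seed))
    print("best pooled accuracies:", manifest.best_accuracy)
    out = Path("results") / f"real_{args.task}.json"
    manifest.to_json(out)
    print("manifest written to", out)


if __name__ == "__main__":
    main()
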
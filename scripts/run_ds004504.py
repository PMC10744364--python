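#!/usr/bin/env python
"""Optional: run the full power-ratio analysis on the OpenNeuro ds004504
deposit (resting-state EEG of FTD patients and controls).

This script needs the dataset downloaded locally (it is not fetched here):

    openneuro download ds004504 --snapshot 1.0.2 <dir>   # or DataLad/HTTP

then:

    python scripts/run_ds004504.py --data <dir>/derivatives --out results/ds004504

Expected layout: BIDS-EEG with preprocessed EEGLAB SET files
(sub-*/eeg/*_eeg.set) and a participants.tsv with Group (A/C/F), Age,
Gender and MMSE columns; the 'A' (Alzheimer) group is dropped, 'F' maps to
FTD and 'C' to CTL. Output is the standard report bundle (band powers,
ratios, screening, diagnostics, logistic models, consistency matrix).
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from specratio.io import SubjectRecord, read_recording
from specratio.pipeline import AnalysisConfig, run_analysis


def load_ds004504(root: Path):
    table = pd.read_csv(root / "participants.tsv", sep="\t")
    group_map = {"F": "FTD", "C": "CTL"}
    recordings, subjects = [], []
    for _, row in table.iterrows():
        grp = group_map.get(str(row.get("Group", "")).strip())
        if grp is None:
            continue  # Alzheimer arm is outside this analysis
        sid = str(row["participant_id"])
        candidates = sorted((root / sid / "eeg").glob("*.set"))
        candidates += sorted((root / sid / "eeg").glob("*.edf"))
        if not candidates:
            print(f"skipping {sid}: no recording found")
            continue
        sex = str(row.get("Gender", "M")).strip().upper()[:1]
        mmse = row.get("MMSE")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=grp,
                age=float(row.get("Age", float("nan"))),
                sex="F" if sex == "F" else "M",
                mmse=None if pd.isna(mmse) else float(mmse),
            )
        )
        recordings.append(read_recording(candidates[0]))
    return recordings, subjects


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, required=True,
                        help="ds004504 derivatives directory (BIDS layout)")
    parser.add_argument("--out", type=Path, required=True)
    args = parser.parse_args()

    recordings, subjects = load_ds004504(args.data)
    n_ftd = sum(s.group == "FTD" for s in subjects)
    n_ctl = sum(s.group == "CTL" for s in subjects)
    print(f"loaded {n_ftd} FTD / {n_ctl} CTL recordings")
    bundle = run_analysis((recordings, subjects), AnalysisConfig())
    out = bundle.save(args.out)
    print(f"report bundle written to {out}")
    print(bundle.consistency[bundle.consistency["tier_0.05"]])


if __name__ == "__main__":
    main()
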
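#!/usr/bin/env python
"""Optional benchmark on locally present MIT-BIH arrhythmia records.

Scans a directory for WFDB records (<name>.hea / <name>.dat, with a
<name>.atr annotation file), runs the full P/R/T detector on the MLII lead
of each, and prints per-record and pooled R-peak SE / +Pr / Err next to the
published reference values for context.  Nothing is asserted and nothing is
downloaded: if the directory holds no records the script says so and exits
cleanly.

Records can be obtained separately from PhysioNet (mitdb); place the files
under --data-dir.

Usage:
    python scripts/mitbih_benchmark.py --data-dir data/mitdb
"""

from __future__ import annotations

import argparse
from pathlib import Path

#: published pooled R-peak figures for the fused detector on the 48-record
#: MIT-BIH arrhythmia database, shown for side-by-side context only
REFERENCE = {"SE": 99.83, "+Pr": 99.90, "Err": 0.00259}


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("data/mitdb"))
    parser.add_argument("--lead", default="MLII")
    parser.add_argument("--tol", type=float, default=0.030,
                        help="match tolerance in seconds")
    args = parser.parse_args()

    headers = sorted(args.data_dir.glob("*.hea")) if args.data_dir.is_dir() else []
    records = [h.with_suffix("") for h in headers
               if h.with_suffix(".atr").exists()]
    if not records:
        print(f"no WFDB records with annotations found under {args.data_dir}; "
              "nothing to benchmark")
        return 0

    from ecgfusion.detector import DetectionReport, detect_all, evaluate
    from ecgfusion.io import read_wfdb, read_wfdb_annotations

    total_tp = total_fp = total_fn = 0
    print(f"{'record':8s} {'beats':>6s} {'SE%':>7s} {'+Pr%':>7s} {'Err':>9s}")
    for rec_path in records:
        try:
            record = read_wfdb(rec_path, channel=args.lead)
        except (ValueError, NotImplementedError) as exc:
            print(f"{rec_path.name:8s} skipped: {exc}")
            continue
        reference = read_wfdb_annotations(rec_path.with_suffix(".atr"))
        detected = detect_all(record)
        rep = evaluate(detected.r_indices, reference.r_indices, record.fs,
                       args.tol)
        total_tp += rep.tp
        total_fp += rep.fp
        total_fn += rep.fn
        err = "inf" if rep.err_infinite else f"{rep.err:.5f}"
        print(f"{rec_path.name:8s} {len(reference.r_indices):6d} "
              f"{rep.se:7.2f} {rep.ppr:7.2f} {err:>9s}")

    pooled = DetectionReport(tp=total_tp, fp=total_fp, fn=total_fn)
    print("-" * 40)
    print(f"pooled    SE {pooled.se:.2f}%  +Pr {pooled.ppr:.2f}%  "
          f"Err {pooled.err:.5f}")
    print(f"published SE {REFERENCE['SE']:.2f}%  +Pr {REFERENCE['+Pr']:.2f}%  "
          f"Err {REFERENCE['Err']:.5f}  (48-record pooled reference)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
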
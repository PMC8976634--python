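"""Optional reproduction on a local MIT-BIH Arrhythmia Database copy.

Requires the 48-record mitdb (.hea/.dat/.atr triplets) in --data-dir;
this script performs no downloading.  It verifies the published beat
counts of the 22/22 train/test partition —

    test  (Data2):  3157 V   46539 non-V   49696 total
    train (Data1):  3648 V   47573 non-V   51221 total
    overall:        6805 V   94112 non-V  100917 total

listing any record whose counts differ, then runs the full pipeline
(features, training, held-out per-record evaluation) and prints the
resulting report.

Usage:  python scripts/reproduce_mitdb.py --data-dir /path/to/mitdb
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from pvcdetect import ecg_io  # noqa: E402
from pvcdetect.model import ModelConfig  # noqa: E402
from pvcdetect.pipeline import features_for_records, fit_and_evaluate  # noqa: E402

EXPECTED = {"test": (3157, 46539, 49696),
            "train": (3648, 47573, 51221),
            "overall": (6805, 94112, 100917)}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", required=True)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    ids = sorted({f[:-4] for f in os.listdir(args.data_dir)
                  if f.endswith(".hea")})
    split = ecg_io.build_split(ids)
    records = {rid: ecg_io.read_record(os.path.join(args.data_dir, rid))
               for rid in split.train_ids + split.test_ids}

    totals = {}
    for role, rids in (("train", split.train_ids),
                       ("test", split.test_ids)):
        n_v = sum(int(records[r].pvc_mask().sum()) for r in rids)
        n_all = sum(len(records[r].annotations) for r in rids)
        totals[role] = (n_v, n_all - n_v, n_all)
    totals["overall"] = tuple(
        a + b for a, b in zip(totals["train"], totals["test"]))

    ok = True
    for role, got in totals.items():
        exp = EXPECTED[role]
        status = "OK" if got == exp else "MISMATCH"
        ok = ok and got == exp
        print(f"{role:>8}: V {got[0]:>6}  non-V {got[1]:>6}  "
              f"total {got[2]:>7}   expected {exp}  [{status}]")
    if not ok:
        print("\nper-record counts for inspection:")
        for rid in split.train_ids + split.test_ids:
            rec = records[rid]
            print(f"  {rid}: {int(rec.pvc_mask().sum())} V / "
                  f"{len(rec.annotations)} beats")

    train_df = features_for_records([records[r] for r in split.train_ids])
    test_df = features_for_records([records[r] for r in split.test_ids])
    result = fit_and_evaluate(train_df, test_df,
                              ModelConfig(seed=args.seed))
    print()
    print(result.report.render())


if __name__ == "__main__":
    main()
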
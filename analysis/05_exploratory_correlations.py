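#!/usr/bin/env python
"""Which drawing features relate to the doctors' gain in understanding?

Exploratory Pearson cross-correlations of the ratings against (a) the
patients' drawing features and (b) the absolute patient-doctor differences
of those features.  p-values are reported uncorrected.
"""

import argparse
from pathlib import Path

import pandas as pd

import paindraw as pdw

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    cfg = pdw.SimulationConfig(seed=args.seed)
    template, records = pdw.simulate_cohort(cfg)
    args.out.mkdir(parents=True, exist_ok=True)

    pat = pdw.features_table([r.patient_drawing for r in records], template)
    doc = pdw.features_table([r.doctor_drawing for r in records], template)
    ratings = pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "understanding": [r.understanding_rating for r in records],
        "decision": [r.decision_rating for r in records],
    })

    for mode, tag in (("raw", "raw"), ("abs_difference", "absdiff")):
        ct = pdw.feature_rating_correlations(pat, ratings, doctor_features=doc,
                                             mode=mode)
        ct.r.to_csv(args.out / f"correlations_{tag}_r.csv")
        ct.p.to_csv(args.out / f"correlations_{tag}_p.csv")
        r = ct.r["understanding"]
        p = ct.p["understanding"]
        print(f"[{mode}] understanding vs extent: r = {r['extent_pct']:.3f} "
              f"(p = {p['extent_pct']:.3g}); vs WPI: r = {r['wpi']:.3f} "
              f"(p = {p['wpi']:.3g})")


if __name__ == "__main__":
    main()
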
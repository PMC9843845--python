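#!/usr/bin/env python
"""Simulate the companion-drug boluses and report peak effect-site Ce.

Runs the literature PK models (Maitre alfentanil, Zomorodi midazolam,
Schnider propofol) for the reference adult (53.3 yr, BMI 23.1, female)
and the bolus scenarios the dosing simulations assume: 1 and 2 mg
midazolam, 250 and 500 ug alfentanil, plus a 40 mg propofol bolus for
context.  Writes trajectory CSVs and a peak table under results/pk/.
The published peaks for comparison: midazolam 21/52 ng/mL, alfentanil
27/55 ng/mL.
"""

import argparse
from pathlib import Path

import pandas as pd

from nlmaz.pk import REFERENCE_ADULT, DoseEvent, build_pk, peak_ce, simulate

SCENARIOS = [
    ("midazolam", 1.0, "mg", 21.0),
    ("midazolam", 2.0, "mg", 52.0),
    ("alfentanil", 250.0, "ug", 27.0),
    ("alfentanil", 500.0, "ug", 55.0),
    ("propofol", 40.0, "mg", None),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/pk"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for drug, amount, unit, published in SCENARIOS:
        pk = build_pk(drug, REFERENCE_ADULT)
        events = [DoseEvent(drug, amount, unit, 0.0)]
        traj = simulate(events, pk, t_end=30.0, dt=0.005)
        peak, t_peak = peak_ce(events, pk)
        name = f"{drug}_{amount:g}{unit}"
        pd.DataFrame(
            {"time_min": traj.time[::20], "cp": traj.cp[::20], "ce": traj.ce[::20]}
        ).to_csv(args.outdir / f"trajectory_{name}.csv", index=False)
        rows.append(
            {"drug": drug, "dose": amount, "unit": unit, "peak_ce": peak,
             "t_peak_min": t_peak, "units": traj.units, "published_peak": published}
        )
        note = f"  [published {published}]" if published else ""
        print(f"{name:<22} peak Ce {peak:7.2f} {traj.units} at {t_peak:5.2f} min{note}")
    pd.DataFrame(rows).to_csv(args.outdir / "peaks.csv", index=False)
    print(f"wrote {args.outdir}/peaks.csv")


if __name__ == "__main__":
    main()
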
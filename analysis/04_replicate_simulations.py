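#!/usr/bin/env python
"""Replicate the published dosing simulations with the packaged surface.

Calibrates the scaled-exponential U50 link against the published
curve-shift anchors, then regenerates:

* the propofol curve-shift families (propofol alone; + 1/2 mg midazolam
  at peak Ce 21/52 ng/mL; + 250/500 ug alfentanil at 27/55 ng/mL; the
  three-drug regimen), with the 5/50/95% LOR concentrations solved
  analytically;
* the ternary U50 surface over the mixture simplex and its nadirs (full
  simplex and the three pairwise edges).

Writes CSV tables (the data of record) and PNG figures under
results/simulation/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from nlmaz.dosing import (
    REFERENCE_ANCHORS,
    REFERENCE_COMPANIONS,
    calibrate_link,
    curve_shift_family,
    solve_cp,
    ternary_grid,
    u50_nadir,
)
from nlmaz.surface import reference_parameters, save_parameters


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/simulation"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    params = calibrate_link(reference_parameters(), REFERENCE_ANCHORS)
    save_parameters(params, args.outdir / "calibrated_parameters.yaml")
    print(
        f"calibrated U50 link: scaled_exp(a={params.link_u50.a:.4f}, "
        f"b={params.link_u50.b:.4f})"
    )

    # curve-shift families
    fam = curve_shift_family(REFERENCE_COMPANIONS, params)
    table = pd.DataFrame(
        [
            {"scenario": r.label, "ce_mid_ng_ml": r.cm, "ce_alf_ng_ml": r.ca,
             "target_lor": r.target, "solved_cp_ug_ml": r.cp}
            for r in fam
        ]
    )
    table.to_csv(args.outdir / "curve_shift.csv", index=False)
    print("\n95%-LOR propofol requirements (published values in brackets):")
    published = {(a.cm, a.ca): a.cp for a in REFERENCE_ANCHORS}
    for r in fam:
        if r.target != 0.95:
            continue
        ref = published.get((r.cm, r.ca))
        note = f"  [published {ref}]" if ref is not None else ""
        print(f"  {r.label:<38} {r.cp:6.3f} ug/mL{note}")

    # figures: one panel per companion drug plus the three-drug overlay
    panels = {
        "midazolam": ["propofol alone", "midazolam 1 mg", "midazolam 2 mg"],
        "alfentanil": ["propofol alone", "alfentanil 250 ug", "alfentanil 500 ug"],
        "three-drug": ["propofol alone", "midazolam 1 mg", "alfentanil 250 ug",
                        "midazolam 1 mg + alfentanil 250 ug"],
    }
    curves = {r.label: r.curve for r in fam}
    fig, axes = plt.subplots(1, 3, figsize=(15, 4.2), sharey=True)
    for ax, (title, labels) in zip(axes, panels.items()):
        for label in labels:
            c = curves[label]
            ax.plot(c.cp, c.probability, label=label)
        for p in (0.05, 0.5, 0.95):
            ax.axhline(p, ls="--", lw=0.6, color="grey")
        ax.set_title(f"curve shift: {title}")
        ax.set_xlabel("propofol Ce (ug/mL)")
        ax.legend(fontsize=7)
    axes[0].set_ylabel("P(loss of response)")
    fig.tight_layout()
    fig.savefig(args.outdir / "curve_shift.png", dpi=150)

    # ternary U50 surface and nadirs
    surf = ternary_grid(params, resolution=100)
    pd.DataFrame(
        {"x_mid": surf.fractions[:, 0], "y_alf": surf.fractions[:, 1],
         "z_prop": surf.fractions[:, 2], "u50": surf.u50}
    ).to_csv(args.outdir / "ternary_u50.csv", index=False)

    print("\nU50 nadirs:")
    rows = []
    for restriction in ("full", "mid-alf", "mid-prop", "alf-prop"):
        value, argmin, _ = u50_nadir(params, restriction)
        rows.append({"domain": restriction, "u50_min": value,
                     "x_mid": argmin.x, "y_alf": argmin.y, "z_prop": argmin.z})
        print(f"  {restriction:<9} min U50 = {value:.3f} at "
              f"(x={argmin.x:.2f}, y={argmin.y:.2f}, z={argmin.z:.2f})")
    pd.DataFrame(rows).to_csv(args.outdir / "u50_nadirs.csv", index=False)

    fig2, ax2 = plt.subplots(figsize=(5.5, 5))
    # barycentric -> cartesian: alfentanil left, propofol right, midazolam top
    x, y = surf.fractions[:, 2] + 0.5 * surf.fractions[:, 0], 0.866 * surf.fractions[:, 0]
    tc = ax2.tricontourf(x, y, surf.u50, levels=20, cmap="viridis")
    fig2.colorbar(tc, label="U50")
    ax2.text(0.02, 0.88, "midazolam", transform=ax2.transAxes)
    ax2.text(0.0, -0.04, "alfentanil", transform=ax2.transAxes)
    ax2.text(0.88, -0.04, "propofol", transform=ax2.transAxes)
    ax2.set_axis_off()
    ax2.set_title("U50 over the mixture simplex")
    fig2.savefig(args.outdir / "ternary_u50.png", dpi=150, bbox_inches="tight")
    print(f"\nwrote tables and figures to {args.outdir}")


if __name__ == "__main__":
    main()
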
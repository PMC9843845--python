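#!/usr/bin/env python
"""Validate the ground-truth and fitted surfaces on the validation cohorts.

For each synthetic validation cohort (ERCP-shaped and bronchoscopy-
shaped) computes the predefined accuracy (|R - P| < 0.5), the ROC curve
and the AUC with a DeLong 95% CI, for (a) the generating truth — the
ceiling any fit can reach — and (b) the surface fitted to the modeling
cohort.  Writes metric YAMLs and ROC/prediction CSVs under
results/validation/.
"""

import argparse
from pathlib import Path

import yaml

from nlmaz.evaluation import roc
from nlmaz.io import read_observations, write_validation_report
from nlmaz.surface import load_parameters, params_from_dict


def load_fitted(path: Path):
    doc = yaml.safe_load("\n".join(
        line for line in path.read_text().splitlines() if not line.startswith("#")
    ))
    flat = {name: entry["estimate"] for name, entry in doc["parameters"].items()}
    flat.update(doc["links"])
    return params_from_dict(flat)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--fit", type=Path, default=Path("results/fit/fit_moaas_lt4.yaml"))
    ap.add_argument("--outdir", type=Path, default=Path("results/validation"))
    args = ap.parse_args()

    models = {"truth": load_parameters(args.cohort_dir / "ground_truth.yaml")}
    if args.fit.exists():
        models["fitted"] = load_fitted(args.fit)
    else:
        print(f"note: {args.fit} not found; validating the ground truth only")

    for cohort in ("modeling", "validation_ercp", "validation_bronch"):
        obs = read_observations(args.cohort_dir / f"{cohort}_observations.csv")
        for model_name, params in models.items():
            rep = roc(obs, params, seed=args.seed)
            write_validation_report(
                rep, args.outdir / f"{cohort}_{model_name}",
                meta={"seed": args.seed, "cohort": cohort, "model": model_name},
            )
            lo, hi = rep.auc_ci
            print(
                f"{cohort:>18} / {model_name:<6}: n={rep.n_obs:4d}  "
                f"accuracy {rep.accuracy:5.1f}%  AUC {rep.auc:.3f} "
                f"(95% CI {lo:.3f}-{hi:.3f})"
            )


if __name__ == "__main__":
    main()
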
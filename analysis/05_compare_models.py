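#!/usr/bin/env python
"""Compare the fitted models: goodness of fit, bull accuracy, re-ranking.

For each trait: adjusted R-squared per linear model, average EBV accuracy
of bulls with at least 20 phenotyped daughters (inbreeding-corrected
prediction-error variances), paired t-tests of per-bull accuracies
between models, and Spearman rank correlations between the bulls' EBVs.
Writes results/comparison/.
"""

from pathlib import Path

import pandas as pd
import yaml

from pedeval.evaluation import build_comparison_report
from pedeval.mixed_model import FitResult, ModelSpec, VarianceComponents
from pedeval.pedigree import inbreeding_coefficients, read_pedigree_csv
from pedeval.pipeline import read_artifact_csv

DATA = Path("results/data")
SCREENED = Path("results/screening")
FITS = Path("results/fits")
OUT = Path("results/comparison")

SCALES = {"stature": "linear", "milking_ease": "ordinal-9"}


def load_fit(d: Path) -> FitResult:
    meta = yaml.safe_load((d / "meta.yaml").read_text())
    ebv = read_artifact_csv(d / "ebv.csv").set_index("animal")
    vc_tab = read_artifact_csv(d / "varcomp.csv").set_index("component")
    est = vc_tab["estimate"]
    vc = VarianceComponents(
        sigma_a2=float(est["sigma_a2"]), sigma_pe2=float(est["sigma_pe2"]),
        sigma_e2=float(est["sigma_e2"]),
        sigma_cg2=float(est["sigma_cg2"]) if "sigma_cg2" in est.index else None)
    fitted = read_artifact_csv(d / "fitted.csv")["fitted"].to_numpy()
    spec = ModelSpec(meta["trait"],
                     ("cg",) if meta["cg_role"] == "fixed" else (),
                     (), meta["cg_role"], meta["scale"])
    import pandas as _pd
    empty = _pd.Series(dtype=float)
    return FitResult(
        spec=spec, varcomp=vc, beta=empty, ebv=ebv["ebv"], pe=empty, cg=empty,
        se_prediction=ebv["se"], loglik=meta["loglik"], iterations=meta["iterations"],
        converged=meta["converged"], rank_x=meta["rank_x"], fitted=fitted,
        n_records=meta["n_records"])


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for trait, scale in SCALES.items():
        ped = read_pedigree_csv(DATA / trait / "pedigree.csv")
        rec = pd.read_csv(SCREENED / f"{trait}_screened_records.csv")
        rec["value"] = rec["value_linear"]  # R2 on the analysed response
        fits = {}
        for d in sorted((FITS / trait).glob("fit_*")):
            label = d.name.replace("fit_", "").replace("_", ":")
            fits[label] = load_fit(d)
        f = inbreeding_coefficients(ped)
        report = build_comparison_report(fits, rec, ped, f)
        print(f"== {trait}: {report.n_bulls} proven bulls ==")
        if len(report.r2_adj):
            print(report.r2_adj.rename("adjusted R2").round(4).to_string())
        print(report.mean_accuracy.round(4).to_string())
        print(report.pairwise.round(4).to_string(index=False))
        for name, tab in report.tables().items():
            tab.reset_index().to_csv(OUT / f"{trait}_{name}.csv", index=False)
    print(f"-> {OUT}/")


if __name__ == "__main__":
    main()
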
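"""Continuous-trait association at the scan peak, by hypertension status.

Nested linear models of the transformed venular trait on the expected
African-allele dosage at the planted locus: local ancestry alone, plus
global ancestry, plus regional (chromosome-arm) ancestry. A normal Z test
compares the hypertensive and non-hypertensive coefficients from the
fully-adjusted model. Writes a regression table and the heterogeneity test.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from admixscan import assoc as A
from admixscan.hmm import default_arms, local_african_dosage, regional_ancestry
from admixscan.io import read_panel

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"
ADJ = ["age", "sex", "site", "map6yr", "glucose"]


def main() -> None:
    keep = np.load(SCRATCH / "qc_keep.npz")
    panel = read_panel(SCRATCH / "panel.tsv").subset(keep["kept_snps"])
    anc = np.load(SCRATCH / "ancestry.npz")
    gamma = anc["gamma"].astype(float)
    gamma /= gamma.sum(axis=2, keepdims=True)
    pheno = pd.read_csv(SCRATCH / "phenotypes.tsv", sep="\t").iloc[
        keep["kept_samples"]
    ].reset_index(drop=True)
    data = np.load(SCRATCH / "cohort.npz", allow_pickle=True)
    locus = int(np.flatnonzero(keep["kept_snps"] == int(data["risk_idx"]))[0])

    resid = A.adjust_phenotype(pheno.crve_like.to_numpy(float), pheno[ADJ])
    adj = A.normal_quantile_transform(resid)
    dosage = local_african_dosage(gamma, locus)
    arm = next(i for i in default_arms(panel).values() if locus in i)
    regional = regional_ancestry(gamma, arm)
    paa = anc["paa"]

    htn = pheno.hypertension.to_numpy() == 1
    rows, fits = [], {}
    for group, mask in (("hypertensive", htn), ("non_hypertensive", ~htn)):
        for label, kw in (
            ("local", {}),
            ("local+global", {"global_paa": paa[mask]}),
            ("local+global+regional", {"global_paa": paa[mask], "regional": regional[mask]}),
        ):
            fit = A.local_ancestry_regression(adj[mask], dosage[mask], **kw)
            fits[(group, label)] = fit
            rows.append({
                "group": group, "model": label, "n": fit.n,
                "beta": round(fit.beta, 2),
                "ci_lo": round(fit.ci95[0], 2), "ci_hi": round(fit.ci95[1], 2),
                "p": float(f"{fit.p:.2g}"),
            })
            print(f"{group:<17} {label:<22} beta {fit.beta:5.2f} "
                  f"({fit.ci95[0]:5.2f}, {fit.ci95[1]:5.2f})  P = {fit.p:.2g}")

    f1 = fits[("hypertensive", "local+global+regional")]
    f2 = fits[("non_hypertensive", "local+global+regional")]
    z, p_het = A.heterogeneity_z(f1.beta, f1.se, f2.beta, f2.se)
    trait_sd = float(pheno.crve_like.std())
    eff_um = A.effect_in_trait_units(f1.beta, trait_sd)
    print(f"\nheterogeneity between strata: Z = {z:.2f}, P = {p_het:.2g}")
    print(f"hypertensive effect: {f1.beta:.2f} Z units per African allele "
          f"(~{eff_um:.2f} um at trait SD {trait_sd:.1f})")

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "regression_table.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "het_z": round(z, 2), "het_p": float(f"{p_het:.2g}"),
        "beta_htn_z_units": round(f1.beta, 2),
        "effect_um_per_allele": round(eff_um, 2),
        "trait_sd_um": round(trait_sd, 1),
    }]).to_csv(RESULTS / "heterogeneity.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'regression_table.tsv'} and {RESULTS / 'heterogeneity.tsv'}")


if __name__ == "__main__":
    main()
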
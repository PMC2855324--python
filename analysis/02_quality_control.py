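"""Run the QC cascade on the simulated study cohort.

Call-rate, duplicate and heterozygosity checks on samples; call-rate,
ancestral-panel Hardy-Weinberg, mixture-consistency (freqcheck) and
proximity/LD pruning (ldcheck) on markers. On a defect-free synthetic
cohort only the stochastic alpha tails of the marker filters should fire.
Writes per-stage survivor counts and the per-SNP report.
"""

import json
from pathlib import Path

import numpy as np

from admixscan.io import read_panel
from admixscan.qc import run_qc

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def main() -> None:
    data = np.load(SCRATCH / "cohort.npz", allow_pickle=True)
    panel = read_panel(SCRATCH / "panel.tsv")
    ancestral = {"A": data["ancestral_A"], "E": data["ancestral_E"]}

    report = run_qc(
        data["genotypes"], panel,
        ancestral_genotypes=ancestral,
        sample_ids=data["sample_id"],
    )
    for stage, c in report.stage_counts.items():
        print(f"{stage:<18} samples={c['samples']:<5} snps={c['snps']}")
    dropped = report.snp_table[report.snp_table.excluded]
    if len(dropped):
        print("dropped SNPs by reason:",
              dropped.reason.value_counts().to_dict())

    (RESULTS / "qc_stage_counts.json").write_text(
        json.dumps(report.stage_counts, indent=2) + "\n"
    )
    report.snp_table.to_csv(SCRATCH / "qc_snps.tsv", sep="\t", index=False)
    np.savez(SCRATCH / "qc_keep.npz",
             kept_samples=report.kept_samples, kept_snps=report.kept_snps)
    print(f"wrote {RESULTS / 'qc_stage_counts.json'}")


if __name__ == "__main__":
    main()
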
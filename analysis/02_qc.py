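#!/usr/bin/env python
"""Variant quality control for the two analysis arms.

Reads the simulated VCFs back through the VCF reader and applies the two QC
profiles: Set-1 (call rate > 95%, HWE exact p ≥ 1e-4, MAF ≥ 0.01) retained
for cis-eQTL training and TWAS, and Set-2 (additionally MAF > 0.05 and a
greedy LD prune at r² < 0.8) for the single-SNP GWAS.  Writes per-rule
removal reports under results/qc/.
"""

from pathlib import Path

import twaskit as tk

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = ROOT / "qc"
    out.mkdir(parents=True, exist_ok=True)
    for tag, profile in (("set1", tk.QcProfile.set1()), ("set2", tk.QcProfile.set2())):
        panel_name = "ref" if tag == "set1" else "test"
        panel = tk.read_genotypes(ROOT / "data" / f"{panel_name}.vcf")
        filtered, report = tk.apply_qc_profile(panel, profile)
        frame = report.to_frame()
        frame.to_csv(out / f"qc_report_{tag}.tsv", sep="\t", index=False)
        filtered.variants.to_csv(
            out / f"variants_{tag}.tsv", sep="\t", index=False
        )
        print(f"{tag} ({panel_name} panel): {panel.n_variants} -> "
              f"{filtered.n_variants} variants")
        for rule, removed, remaining in report.rows:
            print(f"  {rule:<10} removed {removed:>4}  remaining {remaining}")


if __name__ == "__main__":
    main()
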
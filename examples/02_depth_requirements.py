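"""Estimate how many total reads each protocol needs for a detection target.

Thins each library down a depth ladder, fits one shared hyperbolic
detected-genes-vs-exonic-reads curve, and inverts it at a target gene
count; dividing by each group's exonic fraction converts exonic to total
reads. Ribosomal depletion of FFPE tissue needs several-fold more total
reads than poly(A) selection for the same number of quantified genes.
"""
from ffpeseq import SimConfig, simulate_study
from ffpeseq.cli import saturation_stage

config = SimConfig(
    n_genes=23_000, n_tumors=1, input_ng_levels=(500.0,),
    coverage_reads=5_000, coverage_n_transcripts=50, seed=7,
)
bundle = simulate_study(config)

result = saturation_stage(bundle, target_genes=11_000, seed=7)
print(f"shared curve: G_max = {result['summary']['g_max']:.0f} genes, "
      f"K = {result['summary']['k']:.3g} exonic reads, RMSE = {result['summary']['rmse']:.0f}\n")
for req in result["requirements"]:
    print(f"{req['group']:12s} exonic fraction {req['exonic_fraction']:.3f} -> "
          f"{req['required_total_reads'] / 1e6:6.2f} M total reads for "
          f"{req['target_genes']} genes")

polya = next(r for r in result["requirements"] if r["group"] == "FFPE_polyA")
ribo = next(r for r in result["requirements"] if r["group"] == "FFPE_ribo")
ratio = ribo["required_total_reads"] / polya["required_total_reads"]
print(f"\nFFPE ribo / FFPE polyA total-read ratio: {ratio:.2f}")
print("The ratio is the exonic-fraction ratio: the curve is shared, chemistry")
print("only changes how many of the sequenced reads land on exons.")
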
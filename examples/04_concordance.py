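"""Quantify FF/FFPE agreement: correlation, fold-change signs, DE gene sets.

Simulates the default study, then (1) correlates matched FF/FFPE log2
expression per protocol, (2) sweeps the fold-change sign-agreement
statistic over thresholds 1-10, and (3) selects differentially expressed
genes between two tumors and re-checks the correlation restricted to that
clinically interesting panel.
"""
from ffpeseq import SimConfig, expression_matrix, simulate_study
from ffpeseq.concordance import agreement_sweep, de_genes, fold_changes, pairwise_cc

config = SimConfig(
    n_genes=23_000, depth_total_reads=10_000_000,
    coverage_reads=5_000, coverage_n_transcripts=50, seed=7,
)
bundle = simulate_study(config)
expr = expression_matrix(bundle.counts, floor=5.0)

sid = lambda t, ts, pr: f"{t}_{ts}_{pr}_500ng"

print("matched FF vs FFPE correlation (floored log2 expression):")
for protocol in ("polyA", "ribo"):
    for tumor in ("T1", "T2", "T3"):
        cc, n = pairwise_cc(
            expr.column(sid(tumor, "FF", protocol)),
            expr.column(sid(tumor, "FFPE", protocol)),
            floor=5.0,
        )
        print(f"  {tumor} {protocol:6s} cc = {cc:.3f} over {n} genes above the floor")

fc_ffpe = fold_changes(expr.column(sid("T1", "FFPE", "polyA")), expr.column(sid("T2", "FFPE", "polyA")))
fc_ff = fold_changes(expr.column(sid("T1", "FF", "polyA")), expr.column(sid("T2", "FF", "polyA")))
print("\nT1-vs-T2 fold-change sign agreement (poly(A)):")
for rec in agreement_sweep(fc_ffpe, fc_ff, thresholds=(1, 2, 4, 8)):
    print(f"  FC >= {rec.threshold:>2.0f}x in FFPE: {rec.n_selected:5d} genes selected, "
          f"{100 * rec.fraction_agree:.1f}% same direction in FF")

# differential genes between tumors define a panel; concordance is re-checked
# there (all 8 libraries of each tumor serve as that tumor's group)
cols = lambda t: bundle.meta.loc[bundle.meta["tumor_id"] == t, "sample_id"].tolist()
panel = de_genes(expr.values[cols("T1")], expr.values[cols("T2")], fdr=0.001, floor=5.0)
cc_panel, n_panel = pairwise_cc(
    expr.column(sid("T1", "FF", "polyA")), expr.column(sid("T1", "FFPE", "polyA")),
    floor=5.0, gene_subset=panel.gene_ids,
)
print(f"\n{len(panel.gene_ids)} genes differential between T1 and T2 at 0.1% FDR;")
print(f"FF/FFPE correlation restricted to that panel: cc = {cc_panel:.3f} over {n_panel} genes.")
print("High panel-level concordance means the protocols rank clinically relevant")
print("genes the same way even though FFPE coverage is 3'-biased.")
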
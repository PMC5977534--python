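"""Profile 5'->3' coverage and quantify the 3' bias of degraded poly(A) libraries.

Simulates coverage for one tumor under each tissue/protocol combination and
prints the 3'-bias index (mean of the last 10 bins over the first 10).
Fragmented FFPE RNA captured by its poly(A) tail is sequenced mostly near
the 3' end (index >> 1); ribosomal depletion stays flat (index ~ 1) and
intact FF RNA shows only the mild configured tilt.
"""
import numpy as np

from ffpeseq import SimConfig, make_gene_model, simulate_library, simulate_truth
from ffpeseq.coverage import three_prime_bias_index

config = SimConfig(
    n_genes=500, frag_mean_bp=500.0, coverage_reads=100_000,
    coverage_n_transcripts=200, seed=7,
)
gene_model = make_gene_model(config, fixed_length=2000)
truth = simulate_truth(config, gene_ids=gene_model["gene_id"].tolist())
t1 = truth.expr["T1"].to_numpy()

print("tissue  protocol  3'-bias index   coverage in last decile")
for tissue in ("FF", "FFPE"):
    for protocol in ("polyA", "ribo"):
        _, _, profile = simulate_library(t1, gene_model, tissue, protocol, config)
        idx = three_prime_bias_index(profile)
        tail = profile.bins[-10:].mean()
        print(f"{tissue:6s}  {protocol:8s}  {idx:13.2f}   {tail:6.2f}x the transcript mean")

lam = config.frag_mean_bp
print(f"\nWith mean surviving-fragment length {lam:.0f} bp on 2 kb transcripts, a")
print(f"position 1 kb from the 3' end survives at exp(-1000/{lam:.0f}) = "
      f"{np.exp(-1000 / lam):.3f} of the 3'-terminal rate.")
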
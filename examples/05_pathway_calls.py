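"""Map clone demethylation onto cancer-pathway normalization calls.

Complete demethylation of any one member gene (cell-cycle, WNT, p53 or
TGF-β set) re-activates it and counts as normalizing that pathway in that
clone. CDKN2A lacks a promoter-island block and is resolved to the block
most 5' of its exon 1.
"""

import pandas as pd

import epiclone as ec
from epiclone.pathways import DEFAULT_GENE_SETS

params = ec.SimParams(n_loci=40, n_background_loci=10, n_cells=500,
                      n_clones=9, p_demeth=0.3, probes_per_block=2, seed=5)
pop = ec.simulate_population(params)
clones = ec.derive_clones(pop, params)
table, manifest = ec.emit_probe_table(clones, params)
blocks = ec.assemble_blocks(manifest)
betas = ec.aggregate_block_beta(table, blocks)

gene_info = {"CDKN2A": ec.GeneInfo(exon1_start=500, strand="-")}
calls = ec.evaluate_pathways(betas, blocks, [c.label for c in clones],
                             gene_info=gene_info)
print("pathway gene sets:", {k: len(v) for k, v in DEFAULT_GENE_SETS.items()})
print(calls.calls.astype(int))
print("1 = >=1 member gene completely demethylated (β < 0.2) in that clone;")
print("different clones normalize different pathways.")
for (clone, pathway), ev in sorted(calls.evidence.items())[:4]:
    genes = ", ".join(f"{g} (β={b:.2f})" for g, _, b in ev)
    print(f"  {clone} / {pathway}: {genes}")
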
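"""Single-cell UMI statistics: inducible genes, top upregulated, fractions.

A gene is drug-inducible when no untreated cell has more than 2 UMIs of
it; after treatment, random fractions of cells upregulate each such gene
(UMI >= 3), reflecting which cells happened to demethylate it.
"""

import epiclone as ec

params = ec.SimParams(n_loci=20, n_background_loci=5, n_cells=400,
                      p_demeth=0.3, expr_mean=6.0, seed=4)
roles = {g: "TSG" for g in ("CHFR", "FBLN2", "ICAM4", "SFRP1")}
roles.update({"ERVMER61-1": "ERV", "ERVW-1": "ERV", "IFI16": "ISG", "IFI44": "ISG"})
roles.update({f"HK{i:03d}": "background" for i in range(1, 21)})

mock_pop = ec.simulate_population(params, kind="mock")
treated_pop = ec.simulate_population(params, kind="treated")
mock = ec.simulate_umi_matrix(mock_pop, params, roles, condition="mock")
treated = ec.simulate_umi_matrix(treated_pop, params, roles, condition="treated")

inducible = ec.select_inducible_genes(mock)
print(f"{len(inducible)} of {len(roles)} genes are inducible (silent in every mock cell)")
top = ec.top_upregulated(treated, inducible, k=5)
print("top upregulated in treated cells:", top)
for gene in ("CHFR", "SFRP1", "ERVW-1"):
    frac, _ = ec.upregulated_cell_fraction(treated, gene, threshold=3)
    print(f"  {gene}: upregulated (UMI >= 3) in {frac:.1%} of treated cells")
print("each gene lights up in a different random fraction of cells")
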
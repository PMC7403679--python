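"""Per-gene PBS scores and ranked gene-set enrichment.

Plants eight selected loci inside genes that share a GO term, scores every
gene by its highest PBS in 500-bp sliding windows, and runs the
cutoff-free enrichment analysis on each focal branch.  The planted term
should be strongly enriched on the swept (waresley) branch only.
"""

from nichescan import (PlantedLocus, SimConfig, divergence_scan,
                       generate_annotation, gsea, rank_genes, score_genes,
                       simulate_counts)

BRANCHES = ("gamlingay", "waresley", "wales")

loci = tuple(PlantedLocus("contig1", 4000 * k + 1000, "waresley", 0.5)
             for k in (5, 17, 29, 41, 53, 65, 77, 89))
sim = SimConfig(n_contigs=1, contig_length=400_000, n_snps=8000,
                planted_loci=loci, n_go_terms=15, planted_set_size=12, seed=3)

counts = simulate_counts(sim, BRANCHES)
track = divergence_scan(sim, BRANCHES, window_size=500, step=100, counts=counts)
genes, gene_go = generate_annotation(sim)
collection = {go: set(g["gene_id"]) for go, g in gene_go.groupby("go_id")}

for branch in ("gamlingay", "waresley"):
    ranked = rank_genes(score_genes(track, genes, branch))
    print(f"\n{branch}: top 5 genes by max sliding-window PBS")
    print(ranked[["gene_id", "score"]].head(5).to_string(index=False))
    out = gsea(ranked, collection, n_perm=1000, seed=3, min_size=10,
               weight=0.0, branch=branch)
    print(out[["go_id", "size", "es", "nes", "pval", "fdr_q"]]
          .head(3).to_string(index=False))
# The planted term (GO:SYN0001) tops the waresley table with a large NES
# and q ~ 0, while on gamlingay it sits near the null (NES ~ 1).
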
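"""Evolutionary breakpoints and cross-genome conservation of RIDGEs.

Genome A is cut into synteny blocks and reassembled as genome B, with
breakpoints preferentially placed inside high-expression blocks.  Block
ends are treated as evolutionary breakpoints; their enrichment inside
RIDGEs is chi-square-tested, breakpoints are classified cross-species,
and 1-to-1 homolog pairs are scored for joint RIDGE membership.
"""

import ridgescan as rs
from ridgescan.regions import resolve_config

cfg = rs.SimulationConfig(seed=42)
genes, truth = rs.simulate_genome(cfg)
expr = rs.simulate_expression(genes, truth, cfg)
syn = rs.simulate_synteny(genes, truth, cfg)
print(f"{len(syn.blocks)} synteny blocks -> "
      f"{len(rs.blocks_to_breakpoints(syn.blocks))} breakpoints")

# call regions on both genomes (homologs inherit genome-A expression)
tmap_a = rs.build_map(genes, expr)
regions_a = rs.call_regions(tmap_a, resolve_config(tmap_a, rs.CallerConfig(target_coverage=0.10)))
expr_b = expr.rename_genes({p.gene_id_a: p.gene_id_b for p in syn.pairs})
tmap_b = rs.build_map(syn.genes_b, expr_b)
regions_b = rs.call_regions(tmap_b, resolve_config(tmap_b, rs.CallerConfig(target_coverage=0.10)))

bps = rs.blocks_to_breakpoints(syn.blocks)
ridges_a = [r for r in regions_a if r.kind == rs.RIDGE]
rep = rs.breakpoint_enrichment(bps, ridges_a, tmap_a.analyzed_length())
print(f"\nbreakpoints in genome-A RIDGEs: {rep.n_in_regions} of {rep.n_total} "
      f"(expected {rep.expected:.1f})")
print(f"  chi-square = {rep.chi_square:.1f}, p = {rep.p_value:.2g} -> {rep.direction}")

cs = rs.classify_cross_species(bps, regions_a, regions_b)
print(f"\nRIDGE-to-RIDGE breakpoints: {cs.ridge_to_ridge} "
      f"(independence expectation {cs.ridge_expected:.1f}, p = {cs.ridge_p_value:.2g})")

overlap = rs.homolog_region_overlap(syn.pairs, regions_a, regions_b, genes, syn.genes_b)
print(f"\nhomologs in A-RIDGEs: {overlap.n_in_a_ridges}; of those, "
      f"{overlap.n_also_in_b_ridges} also in B-RIDGEs "
      f"({overlap.percent_conserved:.0f}% conserved vs "
      f"{100 * overlap.b_ridge_gene_fraction:.0f}% expected by chance; "
      f"p = {overlap.p_value:.2g})")
print("  conservation above chance = genes in a RIDGE tend to land in a RIDGE again")
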
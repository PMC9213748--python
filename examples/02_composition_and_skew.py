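"""Base composition, AT/GC skew, intergenic regions and the G(A)nT motif."""

from mitocompare.composition import per_gene_skew_table, scan_genome_motifs, total_ign
from mitocompare.simulate import SimConfig, generate_ancestor

genome, truth = generate_ancestor(SimConfig(seed=11))

table = per_gene_skew_table([genome])
whole = table[table.scope == "whole_genome"].iloc[0]
print(f"whole genome: AT% {whole.at_percent:.2f}, "
      f"AT skew {whole.at_skew:+.3f}, GC skew {whole.gc_skew:+.3f}")
# negative AT skew (T over A) and positive GC skew (G over C), as configured

ign, n_regions, longest = total_ign(genome)
print(f"intergenic: {ign} bp over {n_regions} regions, "
      f"longest {longest.length} bp between {longest.flanking_upstream} "
      f"and {longest.flanking_downstream}")

hits = [h for h in scan_genome_motifs(genome, min_run=3) if h.context_region]
cr = [h for h in hits
      if (h.context_region.flanking_upstream, h.context_region.flanking_downstream)
      == ("s-rRNA", "cox2")]
print(f"G(A)nT motif hits in intergenic regions: {len(hits)}; "
      f"in the s-rRNA|cox2 spacer (control-region candidate): {len(cr)}")
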
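"""NMD prediction by transcript reconstruction, and its expression footprint.

Each affected isoform is rebuilt with the cryptic acceptor substituted,
re-translated, and scanned for a premature stop >50 nt upstream of the last
exon-exon junction.  A gene is NMD-predicted when all isoforms using the
affected intron gain a PTC.
"""

import agshift as ag

cfg = ag.SimConfig(seed=42)
genome, isoforms, truth = ag.make_genome_and_annotation(cfg)
data = ag.simulate_counts(isoforms, truth, cfg)
res = ag.analyze(data.junction_counts, data.coverage, data.sample_groups,
                 genome=genome, isoforms=isoforms,
                 expression=data.expression)

calls = res.nmd_calls
n_pred = int(calls["nmd_predicted"].sum())
print(f"NMD-predicted: {n_pred}/{len(calls)} affected genes "
      f"({calls['nmd_predicted'].mean():.0%})")

assoc = res.association
print(f"expression (mean log2 CPM in mutant samples): "
      f"median {assoc['median_log2cpm_nmd']:.2f} (NMD) vs "
      f"{assoc['median_log2cpm_other']:.2f} (non-NMD); "
      f"Kruskal H = {assoc['h']:.1f}, p = {assoc['p']:.2e}")
print("\nGenes whose reconstructed transcripts gain a PTC in every isoform "
      "are flagged for nonsense-mediated decay; on this simulation their "
      "mutant-sample expression is clearly lower, as the generator planted "
      "a 2-fold down-scaling for exactly those genes.")
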
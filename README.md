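# agshift

Analysis of aberrant 3′ splice-site usage from RNA-seq splice-junction counts.

Heterozygous mutations in the spliceosome factor SF3B1 — the commonest
splicing-gene lesions in myelodysplastic syndromes — shift branchpoint choice
and activate *cryptic 3′ splice sites*: alternative AG acceptors a short,
characteristic distance (≈15–24 nt) upstream of the canonical AG, preceded by
a weak polypyrimidine tract and an adenine-enriched branchpoint window.
`agshift` packages the full desk-side analysis of this phenotype for
two-genotype (e.g. mutant vs wild-type) replicate designs:

* **PSI quantification** — percent-spliced-in over *boundary groups*: all
  junctions sharing a donor or acceptor coordinate, plus an intron-retention
  pseudo-member counted from reads covering the 6-bp exon|intron window
  (3 exonic + 3 intronic nt).  PSI(member, sample) = count / group total.
* **Differential splicing** — an empirical-Bayes moderated t-test on PSI.
  Per member *g*, the pooled residual variance s²_g (d_g = n₁+n₂−2 df) is
  shrunk toward a prior (d₀, s₀²) estimated by matching moments of log s²_g
  (digamma/trigamma closed forms, Newton inversion of the trigamma):

      s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)
      t_g  = ΔPSI_g / √( s̃²_g · (1/n₁ + 1/n₂) ),   t_g ~ t(d_g + d₀)

  with Benjamini–Hochberg adjustment; significant members are classified
  (alt-3′ss / alt-5′ss / cassette exon / intron retention) and checked for
  novelty against the transcript annotation.
* **Acceptor sequence context** — −35..+3 windows (AG at −2/−1, strand
  corrected), aberrant-vs-canonical distance spectra with a genome-wide
  background (first AAG/TAG/CAG within 100 nt upstream of each canonical
  3′ss), position×base frequency matrices, adenine enrichment at −18..−8
  (Kruskal–Wallis H), and polypyrimidine-tract scores.
* **NMD prediction** — each isoform containing the affected intron is rebuilt
  with the cryptic acceptor substituted, re-translated, and scanned for a
  premature termination codon more than 50 nt upstream of the last exon–exon
  junction; a gene is NMD-predicted when *all* such isoforms gain a PTC, and
  the association with expression (mean log2 CPM) is tested.
* **Conservation cascade** — for each event's canonical junction mapped to a
  second species: conserved? → cryptic AG in the mutant-preferred −5..−20
  window *and* branchpoint adenosine at −8..−18 from it? → observed spliced?
* **Synthetic data** — a first-class generator that plants all of the above
  structure (offsets, branchpoint adenosines, weak tracts, PTCs, orthology
  truth flags) with negative-binomial replicate counts, for end-to-end
  validation against known truth.

## Worked example

```python
import agshift as ag

cfg = ag.SimConfig(seed=42)                      # 200 genes, 20 planted events
genome, isoforms, truth = ag.make_genome_and_annotation(cfg)
data = ag.simulate_counts(isoforms, truth, cfg)
res = ag.analyze(data.junction_counts, data.coverage, data.sample_groups,
                 genome=genome, isoforms=isoforms,
                 expression=data.expression,
                 orthology=ag.orthology_table(truth))
```

Running the bundled narrative scripts prints, for this dataset:

```text
$ python examples/03_differential_splicing.py
tested members: 720; prior df d0 = 54.23, prior variance s0^2 = 2.66e-04
significant events (q<0.05, |dPSI|>=0.1): 20
...
All 20 calls are novel alt-3'ss events with distances in [15, 24] nt

$ python examples/04_acceptor_motifs.py
adenines in -18..-8: median 5 (aberrant) vs 1 (canonical); H = 25.40, p = 4.67e-07
polypyrimidine fraction (-20..-5): median 0.44 (aberrant) vs 0.84 (canonical)

$ python examples/05_nmd_prediction.py
NMD-predicted: 9/20 affected genes (45%)
expression (mean log2 CPM in mutant samples): median 11.29 (NMD) vs 12.25 (non-NMD);
Kruskal H = 14.1, p = 1.69e-04

$ python examples/06_conservation_cascade.py
cascade: 20 events -> 14 conserved -> 6 cryptic-capable -> 3 observed (15.0% of total)
```

All 20 planted cryptic acceptors are recovered as novel alternative-3′ss
events at their planted distances; the aberrant acceptors show the expected
adenine-rich branchpoint windows and weak tracts; the 9 genes engineered to
gain a PTC in every isoform are exactly the NMD calls, and their planted
2-fold expression down-scaling is detected; the cascade counts equal the
generator's conservation truth.

A thin CLI wraps the same stages for file-based runs:

```bash
agshift simulate --seed 42 --out data/
agshift run-all --config run.toml        # psi → diff → motifs → nmd → conserve
```

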
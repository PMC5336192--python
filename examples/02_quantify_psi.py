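"""Percent-spliced-in over boundary-sharing junctions, retention included.

PSI of a junction in a sample is its read count divided by the summed counts
of all junctions (plus the intron-retention pseudo-member) sharing the same
donor or acceptor boundary.
"""

import pandas as pd

import agshift as ag

# a single donor-shared group: canonical junction, cryptic junction 18 nt
# shorter, and retention reads at the shared boundary
junctions = pd.DataFrame(
    [("chr1", "+", 1000, 1500, 1, 30),
     ("chr1", "+", 1000, 1482, 0, 10)],
    columns=["chrom", "strand", "start", "end", "annotated", "s1"])
coverage = pd.DataFrame(
    [("chr1", 1000, "donor", "s1", 10)],
    columns=["chrom", "pos", "side", "sample", "count"])

members = ag.group_by_boundary(junctions, coverage)
psi = ag.compute_psi(members, min_total=10)
print(psi.long().to_string(index=False))
print("\nPSI splits the group's 50 reads 0.6 / 0.2 / 0.2 between the "
      "canonical junction, the cryptic junction and intron retention; "
      "groups under 10 reads in a sample would be reported missing.")
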
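"""Transcript reconstruction, PTC detection and NMD calls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import agshift as ag
from agshift import nmd
from agshift._seq import revcomp


def _translate(seq: str) -> str:
    from agshift._seq import STOP_CODONS
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        if codon in STOP_CODONS:
            break
        out.append(codon)
    return "".join(out)


def _toy_gene(exon_seqs, intron_seqs, strand="+", pad=50):
    """Build a genome + isoform from transcription-order exon/intron strings."""
    tx_parts = []
    for i, ex in enumerate(exon_seqs):
        tx_parts.append(("exon", ex))
        if i < len(intron_seqs):
            tx_parts.append(("intron", intron_seqs[i]))
    gene_tx = "".join(s for _k, s in tx_parts)
    genome_seq = gene_tx if strand == "+" else revcomp(gene_tx)
    genome = {"c": "T" * pad + genome_seq + "T" * pad}
    exons = []
    pos = pad
    coords = []
    for kind, s in tx_parts:
        coords.append((kind, pos, pos + len(s)))
        pos += len(s)
    if strand == "+":
        exons = [(a, b) for k, a, b in coords if k == "exon"]
    else:
        L = len(genome["c"])
        exons = sorted((L - b, L - a) for k, a, b in coords
                       if k == "exon")
        # genome was built as pad + revcomp(tx) + pad, so mirror coordinates
        exons = [(a, b) for a, b in exons]
    iso = ag.IsoformModel("g", "g.t1", "c", strand, tuple(exons))
    return genome, iso


def test_substitution_length_bookkeeping():
    genome, iso = _toy_gene(["ATG" + "GCT" * 20, "GCA" * 30 + "TAA"],
                            ["GT" + "C" * 80 + "AG"])
    acceptor = iso.introns()[0][1]
    mod = nmd.substitute_acceptor(iso, acceptor, 18)
    assert mod.transcript_length == iso.transcript_length + 18
    assert len(mod.exons) == len(iso.exons)


def test_substitution_identity_and_round_trip():
    genome, iso = _toy_gene(["ATG" + "GCT" * 20, "GCA" * 30 + "TAA"],
                            ["GT" + "C" * 80 + "AG"])
    acceptor = iso.introns()[0][1]
    assert nmd.substitute_acceptor(iso, acceptor, 0) == iso
    mod = nmd.substitute_acceptor(iso, acceptor, 18)
    back = nmd.substitute_acceptor(mod, acceptor - 18, -18)
    assert back == iso


def test_substitution_minus_strand_extends_genomic_end():
    genome, iso = _toy_gene(["ATG" + "GCT" * 20, "GCA" * 30 + "TAA"],
                            ["GT" + "C" * 80 + "AG"], strand="-")
    (s, e) = iso.introns()[0]
    acceptor = s  # minus-strand acceptor is the intron's genomic start
    mod = nmd.substitute_acceptor(iso, acceptor, 18)
    assert mod.transcript_length == iso.transcript_length + 18
    # the downstream exon's genomic END moved up by 18 (transcriptional 5')
    grew = [(a, b) for (a, b), (a0, b0) in zip(mod.exons, iso.exons)
            if (a, b) != (a0, b0)]
    assert len(grew) == 1
    assert grew[0][1] == s + 18


def test_substitution_validation():
    genome, iso = _toy_gene(["ATG" + "GCT" * 20, "GCA" * 30 + "TAA"],
                            ["GT" + "C" * 80 + "AG"])
    acceptor = iso.introns()[0][1]
    with pytest.raises(ValueError, match="crosses"):
        nmd.substitute_acceptor(iso, acceptor, 200)
    with pytest.raises(nmd.ReconstructionError):
        nmd.substitute_acceptor(iso, acceptor + 7, 18)


def test_find_ptc_cases():
    """In-frame TAA in an internal-exon insertion >50 nt upstream of the last
    junction is a PTC; a stop in the last exon is not."""
    # 3 exons; insertion goes into exon 2 which is followed by a junction
    exon2 = "GCA" * 40
    genome, iso = _toy_gene(
        ["ATG" + "GCT" * 20, exon2, "GCC" * 30 + "TAA"],
        ["GT" + "C" * 80 + "AG", "GT" + "C" * 80 + "AG"])
    base = nmd.find_ptc(iso, genome)
    assert not base.ptc and not base.nonstop  # annotated stop, last exon

    acceptor = iso.introns()[0][1]
    # 18-nt extension starting with an in-frame TAA: exon1 length is 63 (0 mod
    # 3), so the insertion is read in frame 0
    genome2, iso2 = _toy_gene(
        ["ATG" + "GCT" * 20, exon2, "GCC" * 30 + "TAA"],
        ["GT" + "C" * 62 + "TAACCCCCCCCCCCCCCC" + "AG",
         "GT" + "C" * 80 + "AG"])
    mod = nmd.substitute_acceptor(iso2, iso2.introns()[0][1], 20)
    res = nmd.find_ptc(mod, genome2)
    assert res.ptc
    assert res.distance_to_last_junction > 50

    # frame-preserving stop-free insertion: stop position unchanged, PTC false
    mod_neutral = nmd.substitute_acceptor(iso, acceptor, 18)
    res_n = nmd.find_ptc(mod_neutral, genome)
    assert not res_n.ptc
    assert res_n.stop_tpos == base.stop_tpos + 18


def test_find_ptc_stop_in_last_exon_and_nonstop():
    genome, iso = _toy_gene(["ATG" + "GCT" * 20, "TAA" + "GCA" * 20],
                            ["GT" + "C" * 80 + "AG"])
    res = nmd.find_ptc(iso, genome)
    assert res.stop_tpos is not None and not res.ptc  # stop in last exon

    genome2, iso2 = _toy_gene(["ATG" + "GCT" * 20, "GCA" * 20],
                              ["GT" + "C" * 80 + "AG"])
    res2 = nmd.find_ptc(iso2, genome2)
    assert res2.nonstop and not res2.ptc


def test_frameshift_changes_downstream_peptide():
    """A stop-free insertion of length not divisible by 3 shifts the frame:
    the downstream peptide differs from the original."""
    genome, iso = _toy_gene(["ATG" + "GCT" * 20, "GCA" * 40],
                            ["GT" + "C" * 80 + "AG"])
    acceptor = iso.introns()[0][1]
    mod = nmd.substitute_acceptor(iso, acceptor, 16)
    pep0 = _translate(iso.transcript_sequence(genome))
    pep1 = _translate(mod.transcript_sequence(genome))
    assert pep1[:20] == pep0[:20]           # upstream unchanged
    assert pep1[25:] != pep0[25:len(pep1)]  # downstream shifted


def _events_frame(rows):
    cols = ["anchor_id", "member_id", "canonical_member", "gene_id", "chrom",
            "strand", "side", "event_class", "novel", "distance_nt",
            "member_start", "member_end", "delta_psi", "t", "p", "q"]
    return pd.DataFrame(rows, columns=cols)


def test_gene_nmd_requires_all_isoforms():
    """Two isoforms share the affected intron: NMD only when both gain a PTC."""
    # isoform A: 3 exons; isoform B: same but longer final exon -> same PTC
    e1, e2, e3 = "ATG" + "GCT" * 20, "GCA" * 40, "GCC" * 30 + "TAA"
    i_ptc = "GT" + "C" * 61 + "TGACTGACTGACCCC" + "AG"  # stop in extension
    i2 = "GT" + "C" * 80 + "AG"
    genome, isoA = _toy_gene([e1, e2, e3], [i_ptc, i2])
    isoB = ag.IsoformModel("g", "g.t2", "c", "+", isoA.exons[:2]
                           + ((isoA.exons[2][0], isoA.exons[2][1] + 0),))
    acceptor = isoA.introns()[0][1]
    ev = _events_frame([["a1", "m1", "c1", "g", "c", "+", "donor", "alt-3ss",
                         True, 17, isoA.exons[0][1], acceptor - 17, 0.3,
                         5.0, 1e-4, 1e-3]])
    calls = nmd.call_gene_nmd(ev, [isoA, isoB], genome)
    assert len(calls) == 1
    assert calls.iloc[0]["n_isoforms"] == 2
    assert bool(calls.iloc[0]["nmd_predicted"]) == (calls.iloc[0]["n_ptc"] == 2)

    # an isoform whose extension stop lands in ITS last exon breaks the call
    isoC = ag.IsoformModel("g", "g.t3", "c", "+", isoA.exons[:2])
    calls2 = nmd.call_gene_nmd(ev, [isoA, isoC], genome)
    assert calls2.iloc[0]["n_isoforms"] == 2
    assert not calls2.iloc[0]["nmd_predicted"]


def test_nmd_truth_table_on_generator():
    """ptc_fraction=1 -> every planted gene NMD; 0 -> none."""
    for frac, expect in ((1.0, True), (0.0, False)):
        cfg = ag.SimConfig(n_genes=40, n_cryptic_events=10, ptc_fraction=frac,
                           seed=29)
        genome, isoforms, truth = ag.make_genome_and_annotation(cfg)
        data = ag.simulate_counts(isoforms, truth, cfg)
        res = ag.analyze(data.junction_counts, data.coverage,
                         data.sample_groups, genome=genome, isoforms=isoforms,
                         run_motifs=False)
        calls = res.nmd_calls
        assert set(calls["gene_id"]) == truth.event_gene_ids()
        assert (calls["n_isoforms"] > 0).all()
        assert (calls["nmd_predicted"] == expect).all()


def test_log2_cpm_formula():
    expr = pd.DataFrame({"s1": [0, 10**6 - 10]}, index=["gA", "gB"])
    expr.loc["gC"] = [10]
    # library size adjusted to exactly 1e6
    cpm = nmd.log2_cpm(expr, ["s1"])
    assert np.isclose(cpm.loc["gA", "s1"], -1.0)


def test_expression_association_null_and_errors():
    calls = pd.DataFrame({"event_id": ["e1", "e2"], "gene_id": ["gA", "gB"],
                          "n_isoforms": [1, 1], "n_ptc": [1, 0],
                          "nmd_predicted": [True, False], "note": ["", ""]})
    expr = pd.DataFrame({"m1": [100, 100], "m2": [100, 100]},
                        index=["gA", "gB"])
    out = nmd.expression_association(calls, expr, ["m1", "m2"])
    assert out["h"] == 0.0 and out["p"] == 1.0
    calls_all = calls.assign(nmd_predicted=[True, True])
    with pytest.raises(ValueError):
        nmd.expression_association(calls_all, expr, ["m1", "m2"])
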
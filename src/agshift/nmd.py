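"""Transcript reconstruction and nonsense-mediated decay (NMD) prediction.

For every aberrant 3' splice-site event, each annotated isoform containing the
affected intron is rebuilt with the cryptic acceptor substituted (the intronic
sequence between the cryptic and canonical AG is absorbed into the downstream
exon), re-translated from its annotated start codon in the original frame, and
scanned for the first in-frame stop.  A stop qualifying as a premature
termination codon (PTC) under the 50-nt rule — more than ``nmd_distance`` nt
upstream of the last exon-exon junction of the modified isoform — flags the
isoform; a gene is called NMD-predicted when *all* its isoforms that contain
the affected intron gain a PTC.  Association between NMD calls and expression
is tested on mean log2 CPM with a Kruskal-Wallis H test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import STOP_CODONS
from .models import IsoformModel
from .motifs import kruskal_h

log = logging.getLogger(__name__)


class ReconstructionError(ValueError):
    pass


def substitute_acceptor(iso: IsoformModel, canonical_acceptor: int,
                        distance_nt: int) -> IsoformModel:
    """Shift one intron's acceptor ``distance_nt`` nt transcriptionally upstream.

    ``canonical_acceptor`` is the internal boundary coordinate of the affected
    intron's 3' splice site (intron end for ``+`` isoforms, intron start for
    ``-``).  The downstream exon's transcriptional 5' boundary is extended by
    ``distance_nt`` so the exon count is unchanged.  A negative distance
    reverses a previous substitution.
    """
    exons = list(iso.exons)
    if iso.strand == "+":
        idx = next((i for i, (s, _e) in enumerate(exons)
                    if s == canonical_acceptor and i > 0), None)
        if idx is None:
            raise ReconstructionError(
                f"{iso.transcript_id}: no intron with acceptor {canonical_acceptor}")
        new_start = exons[idx][0] - distance_nt
        if new_start <= exons[idx - 1][1]:
            raise ValueError("extension crosses the upstream exon")
        if new_start >= exons[idx][1]:
            raise ValueError("extension removes the exon")
        exons[idx] = (new_start, exons[idx][1])
    else:
        idx = next((i for i, (_s, e) in enumerate(exons)
                    if e == canonical_acceptor and i < len(exons) - 1), None)
        if idx is None:
            raise ReconstructionError(
                f"{iso.transcript_id}: no intron with acceptor {canonical_acceptor}")
        new_end = exons[idx][1] + distance_nt
        if new_end >= exons[idx + 1][0]:
            raise ValueError("extension crosses the upstream exon")
        if new_end <= exons[idx][0]:
            raise ValueError("extension removes the exon")
        exons[idx] = (exons[idx][0], new_end)
    return iso.with_exons(exons)


@dataclass(frozen=True)
class PtcResult:
    stop_tpos: int | None      # transcript coordinate of the stop codon's first nt
    ptc: bool
    nonstop: bool
    distance_to_last_junction: int | None


def find_ptc(iso: IsoformModel, genome, nmd_distance: int = 50) -> PtcResult:
    """Locate the first in-frame stop and apply the 50-nt NMD rule.

    The transcript is re-read from the isoform's annotated CDS start in the
    original frame; the first stop codon terminates translation.  The stop is
    a PTC when its 3' end lies more than ``nmd_distance`` nt upstream of the
    last exon-exon junction.  Stops in the last exon (or within the window)
    are not PTCs; transcripts with no stop are flagged nonstop.
    """
    seq = iso.transcript_sequence(genome)
    stop_tpos = None
    for i in range(iso.cds_start, len(seq) - 2, 3):
        if seq[i:i + 3] in STOP_CODONS:
            stop_tpos = i
            break
    ljp = iso.last_junction_tpos()
    if stop_tpos is None:
        return PtcResult(None, False, True, None)
    if ljp is None:
        return PtcResult(stop_tpos, False, False, None)
    dist = ljp - (stop_tpos + 3)
    return PtcResult(stop_tpos, dist > nmd_distance, False, dist)


def call_gene_nmd(events: pd.DataFrame, isoforms: list[IsoformModel],
                  genome, nmd_distance: int = 50) -> pd.DataFrame:
    """Gene-level NMD calls for alt-3'ss events.

    For each event, every CDS-bearing isoform of the event's gene that contains
    the affected intron is reconstructed and scanned; ``nmd_predicted`` is true
    iff all such isoforms gain a PTC.  Genes with no isoform containing the
    affected intron are excluded with a reason.
    """
    by_gene: dict[str, list[IsoformModel]] = {}
    for iso in isoforms:
        by_gene.setdefault(iso.gene_id, []).append(iso)

    rows = []
    alt3 = events[(events["event_class"] == "alt-3ss")
                  & events["distance_nt"].notna()]
    for _, ev in alt3.iterrows():
        gene = ev["gene_id"]
        plus = ev["strand"] != "-"
        ab_bound = int(ev["member_end"] if plus else ev["member_start"])
        d = int(ev["distance_nt"])
        canonical = ab_bound + d if plus else ab_bound - d
        n_iso = n_ptc = 0
        details = []
        for iso in by_gene.get(gene, []):
            try:
                mod = substitute_acceptor(iso, canonical, d)
            except ReconstructionError:
                continue  # isoform does not use the affected intron
            res = find_ptc(mod, genome, nmd_distance)
            n_iso += 1
            n_ptc += int(res.ptc)
            details.append((iso.transcript_id, res.ptc, res.stop_tpos))
        if n_iso == 0:
            rows.append({"event_id": f"{ev['anchor_id']}|{ev['member_id']}",
                         "gene_id": gene, "n_isoforms": 0, "n_ptc": 0,
                         "nmd_predicted": False,
                         "note": "no isoform contains the affected intron"})
            continue
        rows.append({"event_id": f"{ev['anchor_id']}|{ev['member_id']}",
                     "gene_id": gene, "n_isoforms": n_iso, "n_ptc": n_ptc,
                     "nmd_predicted": n_ptc == n_iso, "note": ""})
    calls = pd.DataFrame(rows, columns=["event_id", "gene_id", "n_isoforms",
                                        "n_ptc", "nmd_predicted", "note"])
    log.info("call_gene_nmd: %d events -> %d callable, %d NMD-predicted",
             len(alt3), int((calls["n_isoforms"] > 0).sum()),
             int(calls["nmd_predicted"].sum()))
    return calls


def log2_cpm(expression: pd.DataFrame, samples: list[str] | None = None,
             pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 counts-per-million with a pseudocount added to the raw count."""
    cols = samples or list(expression.columns)
    counts = expression[cols].astype(float)
    lib = counts.sum(axis=0)
    return np.log2((counts + pseudocount) / lib * 1e6)


def expression_association(nmd_calls: pd.DataFrame, expression: pd.DataFrame,
                           mutant_samples: list[str],
                           pseudocount: float = 0.5) -> dict:
    """Kruskal-Wallis test of expression between NMD and non-NMD gene groups.

    Per gene, expression is summarised as the mean log2 CPM across mutant
    samples.  Returns H, p, per-group medians and the direction of the
    difference.
    """
    callable_genes = nmd_calls[nmd_calls["n_isoforms"] > 0]
    nmd_genes = sorted(set(callable_genes.loc[callable_genes["nmd_predicted"],
                                              "gene_id"]))
    other_genes = sorted(set(callable_genes.loc[~callable_genes["nmd_predicted"],
                                                "gene_id"]))
    if not nmd_genes or not other_genes:
        raise ValueError("both NMD and non-NMD groups must be non-empty")
    cpm = log2_cpm(expression, mutant_samples, pseudocount).mean(axis=1)
    g_nmd = cpm.reindex(nmd_genes).dropna().to_numpy()
    g_other = cpm.reindex(other_genes).dropna().to_numpy()
    h, df, p = kruskal_h(g_nmd, g_other)
    med_nmd, med_other = float(np.median(g_nmd)), float(np.median(g_other))
    return {
        "h": h, "df": df, "p": p,
        "n_nmd": int(g_nmd.size), "n_other": int(g_other.size),
        "median_log2cpm_nmd": med_nmd,
        "median_log2cpm_other": med_other,
        "direction": ("nmd_lower" if med_nmd < med_other
                      else "nmd_higher" if med_nmd > med_other else "equal"),
    }
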
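"""Sequence context of 3' splice sites: acceptor windows, distance spectra,
base-frequency matrices, adenine enrichment and polypyrimidine-tract scores.

Positions are numbered relative to the acceptor AG in transcription
orientation: the invariant ``G`` sits at -1 and ``A`` at -2, intronic positions
run upstream from -3 to -35 and the first three exonic bases are +1..+3
(there is no position 0).  The branchpoint-search window -8..-18 and the
polypyrimidine window -5..-20 use this same frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp
from .models import IsoformModel

log = logging.getLogger(__name__)

WINDOW_UP = 35     # intronic positions -35..-1
WINDOW_DOWN = 3    # exonic positions +1..+3
WINDOW_LEN = WINDOW_UP + WINDOW_DOWN

#: position labels of a context window, 5'->3'
POSITIONS = tuple(range(-WINDOW_UP, 0)) + tuple(range(1, WINDOW_DOWN + 1))


def pos_index(pos: int) -> int:
    """Array index of a context position (-35..-1, +1..+3; no 0)."""
    if pos == 0 or pos < -WINDOW_UP or pos > WINDOW_DOWN:
        raise ValueError(f"position {pos} outside context window")
    return pos + WINDOW_UP if pos < 0 else pos + WINDOW_UP - 1


@dataclass(frozen=True)
class AcceptorContext:
    """A -35..+3 window around one 3' splice site, transcription orientation."""

    event_id: str
    seq: str
    source: str  # aberrant | canonical | background

    def __post_init__(self) -> None:
        if len(self.seq) != WINDOW_LEN:
            raise ValueError(f"context window must be {WINDOW_LEN} nt")

    @property
    def has_n(self) -> bool:
        return "N" in self.seq

    @property
    def valid_ag(self) -> bool:
        return self.seq[pos_index(-2):pos_index(-1) + 1] == "AG"

    def at(self, pos: int) -> str:
        return self.seq[pos_index(pos)]


def extract_acceptor_context(genome: Mapping[str, str], chrom: str,
                             boundary: int, strand: str,
                             event_id: str = "", source: str = "aberrant",
                             ) -> AcceptorContext | None:
    """Extract the -35..+3 acceptor window; None if too close to a contig edge.

    ``boundary`` is the internal acceptor coordinate (the exon|intron junction
    point: intron end for ``+``, intron start for ``-``).  Minus-strand windows
    are reverse-complemented so numbering is transcriptional.
    """
    seq = genome[chrom]
    n = len(seq)
    if strand == "+":
        if boundary < WINDOW_UP or boundary + WINDOW_DOWN > n:
            log.info("acceptor %s:%d too close to contig edge; skipped",
                     chrom, boundary)
            return None
        window = str(seq[boundary - WINDOW_UP:boundary + WINDOW_DOWN]).upper()
    elif strand == "-":
        if boundary < WINDOW_DOWN or boundary + WINDOW_UP > n:
            log.info("acceptor %s:%d too close to contig edge; skipped",
                     chrom, boundary)
            return None
        window = revcomp(str(seq[boundary - WINDOW_DOWN:boundary + WINDOW_UP])).upper()
    else:
        return None  # unknown strand: no sequence frame
    return AcceptorContext(event_id=event_id, seq=window, source=source)


def contexts_for_events(genome: Mapping[str, str], events: pd.DataFrame,
                        ) -> list[AcceptorContext]:
    """Aberrant + canonical-partner acceptor contexts for alt-3'ss events.

    The canonical comparison set is the canonical partner of each tested group
    (not all annotated acceptors).
    """
    out: list[AcceptorContext] = []
    alt3 = events[events["event_class"] == "alt-3ss"]
    for _, ev in alt3.iterrows():
        chrom, strand, plus = ev["chrom"], ev["strand"], ev["strand"] != "-"
        ab_bound = int(ev["member_end"] if plus else ev["member_start"])
        ctx = extract_acceptor_context(genome, chrom, ab_bound, strand,
                                       event_id=f"{ev['anchor_id']}|{ev['member_id']}",
                                       source="aberrant")
        if ctx is not None:
            out.append(ctx)
        if not np.isnan(ev["distance_nt"]):
            d = int(ev["distance_nt"])
            can_bound = ab_bound + d if plus else ab_bound - d
            ctx = extract_acceptor_context(genome, chrom, can_bound, strand,
                                           event_id=f"{ev['anchor_id']}|canonical",
                                           source="canonical")
            if ctx is not None:
                out.append(ctx)
    return out


# ---------------------------------------------------------------------------
# distance spectra
# ---------------------------------------------------------------------------

def first_upstream_ag(window: str, min_dist: int = 3, max_dist: int = 100,
                      require_motif: bool = True) -> int | None:
    """Offset of the first AAG/TAG/CAG upstream of a canonical acceptor.

    ``window`` ends at the canonical ``G`` (transcription orientation).  The
    scan starts at the canonical site and walks upstream, so the returned AG is
    the nearest-to-canonical; offsets are G-to-G distances and candidates
    closer than ``min_dist`` (overlapping the canonical AG) are excluded.
    ``require_motif=False`` accepts any AG (GAG included).
    """
    n = len(window)
    for d in range(min_dist, max_dist + 1):
        gi = n - 1 - d
        if gi - 1 < 0:
            return None
        if window[gi] == "G" and window[gi - 1] == "A":
            if not require_motif or (gi - 2 >= 0 and window[gi - 2] != "G"):
                return d
    return None


def background_distances(genome: Mapping[str, str],
                         isoforms: Sequence[IsoformModel],
                         min_dist: int = 3, max_dist: int = 100) -> list[int]:
    """Background AG-distance spectrum over all annotated canonical acceptors:
    for each intron, the first AAG/TAG/CAG within ``max_dist`` nt upstream of
    the canonical 3' splice site.  Junctions without a hit are absent."""
    out: list[int] = []
    for iso in isoforms:
        for s, e in iso.introns():
            ilen = e - s
            w = min(max_dist + 2, ilen)
            seq = genome[iso.chrom]
            if iso.strand == "+":
                window = str(seq[e - w:e]).upper()
            else:
                window = revcomp(str(seq[s:s + w])).upper()
            d = first_upstream_ag(window, min_dist, max_dist)
            if d is not None:
                out.append(d)
    return out


def distance_histogram(events: pd.DataFrame,
                       genome: Mapping[str, str] | None = None,
                       isoforms: Sequence[IsoformModel] | None = None,
                       max_dist: int = 100) -> pd.DataFrame:
    """Aberrant 3'ss distance histogram, with an optional annotation-wide
    background spectrum (first [ATC]AG within ``max_dist`` nt upstream).

    Returns a long frame: distance, source (aberrant/background), count.
    """
    alt3 = events[(events["event_class"] == "alt-3ss")
                  & events["distance_nt"].notna()]
    ab = (alt3["distance_nt"].astype(int).value_counts().sort_index()
          .rename_axis("distance").rename("count").reset_index())
    ab["source"] = "aberrant"
    frames = [ab]
    if genome is not None and isoforms is not None:
        bg = pd.Series(background_distances(genome, isoforms,
                                            max_dist=max_dist), dtype=int)
        bgh = (bg.value_counts().sort_index()
               .rename_axis("distance").rename("count").reset_index())
        bgh["source"] = "background"
        frames.append(bgh)
    return pd.concat(frames, ignore_index=True)[["source", "distance", "count"]]


# ---------------------------------------------------------------------------
# motif matrices and enrichment
# ---------------------------------------------------------------------------

def motif_frequency_matrix(contexts: Iterable[AcceptorContext],
                           ) -> dict[str, pd.DataFrame]:
    """Per-source position x base frequency tables (N excluded per position).

    Each returned frame is indexed by context position with columns A,C,G,T;
    defined columns sum to 1.
    """
    by_source: dict[str, list[str]] = {}
    for ctx in contexts:
        by_source.setdefault(ctx.source, []).append(ctx.seq)
    if not by_source:
        raise ValueError("no contexts")
    out: dict[str, pd.DataFrame] = {}
    for source, seqs in by_source.items():
        arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(
            len(seqs), WINDOW_LEN)
        mat = pd.DataFrame(index=pd.Index(POSITIONS, name="position"),
                           columns=list("ACGT"), dtype=float)
        for bi, base in enumerate(b"ACGT"):
            mat.iloc[:, bi] = (arr == bytes([base])).sum(axis=0)
        denom = mat.sum(axis=1)
        out[source] = mat.div(denom.where(denom > 0), axis=0)
    return out


def adenine_count(seq: str, window: tuple[int, int] = (-18, -8)) -> int:
    """Number of adenines at context positions ``window`` (inclusive ends)."""
    lo, hi = min(window), max(window)
    return sum(seq[pos_index(p)] == "A" for p in range(lo, hi + 1))


@dataclass
class EnrichmentResult:
    """Kruskal-Wallis comparison of per-sequence adenine counts across sources."""

    counts: dict[str, np.ndarray]
    h: float
    df: int
    p: float
    medians: dict[str, float]

    def to_dict(self) -> dict:
        return {"h": self.h, "df": self.df, "p": self.p,
                "medians": self.medians,
                "n": {k: int(v.size) for k, v in self.counts.items()}}


def kruskal_h(*groups: Sequence[float], exact: bool = False,
              ) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p (k-1 df).

    ``exact=True`` computes a permutation p-value by exhaustive enumeration of
    group assignments (two groups with at most 8 observations each); H itself
    is unchanged.  All-tied data give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, len(groups) - 1, 1.0
    h, p = stats.kruskal(*arrays)
    df = len(groups) - 1
    if exact:
        if len(arrays) != 2 or any(a.size > 8 for a in arrays):
            raise ValueError("exact permutation p only for 2 groups of <= 8")
        n1 = arrays[0].size
        idx = range(pooled.size)
        hits = total = 0
        for comb in combinations(idx, n1):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            g1, g2 = pooled[mask], pooled[~mask]
            if np.all(np.concatenate([g1, g2]) == pooled[0]):
                hperm = 0.0
            else:
                hperm = stats.kruskal(g1, g2)[0]
            hits += hperm >= h - 1e-12
            total += 1
        p = hits / total
    return float(h), df, float(p)


def adenine_enrichment(contexts: Iterable[AcceptorContext],
                       window: tuple[int, int] = (-18, -8),
                       exact: bool = False) -> EnrichmentResult:
    """Compare adenine counts in the branchpoint-search window across sources."""
    counts: dict[str, list[int]] = {}
    for ctx in contexts:
        counts.setdefault(ctx.source, []).append(adenine_count(ctx.seq, window))
    if len(counts) < 2:
        raise ValueError("adenine enrichment needs at least 2 sources")
    arrays = {k: np.asarray(v, dtype=float) for k, v in counts.items()}
    h, df, p = kruskal_h(*arrays.values(), exact=exact)
    medians = {k: float(np.median(v)) for k, v in arrays.items()}
    return EnrichmentResult(counts=arrays, h=h, df=df, p=p, medians=medians)


def polypyrimidine_score(seq: str, window: tuple[int, int] = (-20, -5),
                         ) -> float:
    """Fraction of C/T in the tract window (N excluded); NaN if all N."""
    lo, hi = min(window), max(window)
    if lo < -WINDOW_UP or hi > -3:
        raise ValueError("tract window must lie within -35..-3")
    chars = [seq[pos_index(p)] for p in range(lo, hi + 1)]
    defined = [c for c in chars if c != "N"]
    if not defined:
        return float("nan")
    return sum(c in "CT" for c in defined) / len(defined)
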
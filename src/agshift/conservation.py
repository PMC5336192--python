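"""Cross-species conservation cascade for aberrant 3' splice-site events.

Given events called in species A and an orthology table mapping each event's
canonical junction to species B, the cascade counts, in nested order:

1. events whose canonical junction is conserved,
2. conserved events whose species-B acceptor region contains both a potential
   cryptic AG in the mutant-preferred offset window (-5..-20, AG-to-AG) and a
   potential branchpoint adenosine at -8..-18 from that cryptic AG,
3. capable events actually observed spliced in species B (an external evidence
   flag carried by the table).

Offsets are G-anchored: the candidate AG's ``G`` to the canonical AG's ``G``;
branchpoint positions use the acceptor-context frame (cryptic ``G`` at -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

log = logging.getLogger(__name__)

AG_WINDOW = (5, 20)
BP_WINDOW = (8, 18)


def has_cryptic_ag(seq: str, ag_window: tuple[int, int] = AG_WINDOW,
                   ) -> int | None:
    """Offset of the nearest-to-canonical candidate AG, or None.

    ``seq`` must end at the canonical acceptor's ``G`` in transcription
    orientation.  Candidates are AG dinucleotides whose ``G`` lies ``lo..hi``
    nt upstream of the canonical ``G``; the nearest one wins.
    """
    lo, hi = ag_window
    if len(seq) < hi + 3:
        raise ValueError(f"window must cover at least {hi + 3} nt")
    seq = seq.upper()
    n = len(seq)
    for d in range(lo, hi + 1):
        if seq[n - 1 - d] == "G" and seq[n - 2 - d] == "A":
            return d
    return None


def has_bp_adenosine(seq: str, cryptic_offset: int,
                     bp_window: tuple[int, int] = BP_WINDOW,
                     require_full: bool = True) -> bool:
    """Any adenosine at positions -8..-18 relative to the cryptic AG?

    Positions use the acceptor frame (cryptic ``G`` at -1, ``A`` at -2).
    With ``require_full`` (default) a window too short to cover the deepest
    position raises; otherwise only the covered positions are scanned.
    """
    lo, hi = bp_window
    seq = seq.upper()
    n = len(seq)
    deepest = cryptic_offset + hi
    if require_full and n < deepest:
        raise ValueError(
            f"window does not cover position -{hi} of the cryptic AG")
    for p in range(lo, hi + 1):
        i = n - cryptic_offset - p
        if i < 0:
            break
        if seq[i] == "A":
            return True
    return False


@dataclass
class CascadeReport:
    """Nested conservation counts plus per-event capability flags."""

    n_input: int
    n_conserved: int
    n_capable: int
    n_observed: int
    flags: pd.DataFrame  # event_id, conserved, ag_offset, bp, capable, observed

    def to_dict(self) -> dict:
        pct = lambda k: round(100.0 * k / self.n_input, 2) if self.n_input else 0.0
        return {
            "n_input": self.n_input,
            "n_conserved": self.n_conserved,
            "n_capable": self.n_capable,
            "n_observed": self.n_observed,
            "pct_conserved": pct(self.n_conserved),
            "pct_capable": pct(self.n_capable),
            "pct_observed": pct(self.n_observed),
        }


def run_cascade(event_ids: list[str], orthology: pd.DataFrame,
                ag_window: tuple[int, int] = AG_WINDOW,
                bp_window: tuple[int, int] = BP_WINDOW,
                exon_flank: int = 3) -> CascadeReport:
    """Apply the conservation filter cascade to a set of events.

    Every event id must have exactly one orthology record.  The table's
    ``window`` column holds the species-B acceptor sequence -35..+3 (its last
    ``exon_flank`` bases are exonic and are stripped before AG scanning).
    Windows too short to cover the full branchpoint range for a candidate AG
    are scanned over their covered positions only.
    """
    if orthology["event_id"].duplicated().any():
        dup = orthology.loc[orthology["event_id"].duplicated(), "event_id"].iloc[0]
        raise ValueError(f"duplicate orthology record for event {dup!r}")
    recs = orthology.set_index("event_id")
    missing = [e for e in event_ids if e not in recs.index]
    if missing:
        raise ValueError(f"events without orthology records: {missing[:5]}")
    if len(set(event_ids)) != len(event_ids):
        raise ValueError("duplicate event ids")

    rows = []
    for eid in event_ids:
        rec = recs.loc[eid]
        conserved = bool(int(rec["conserved"]))
        ag_offset: int | None = None
        bp = False
        if conserved:
            window = str(rec["window"])
            core = window[:-exon_flank] if exon_flank else window
            ag_offset = has_cryptic_ag(core, ag_window)
            if ag_offset is not None:
                bp = has_bp_adenosine(core, ag_offset, bp_window,
                                      require_full=False)
        capable = conserved and ag_offset is not None and bp
        observed = capable and bool(int(rec["observed"]))
        rows.append({"event_id": eid, "conserved": conserved,
                     "ag_offset": ag_offset, "bp_adenosine": bp,
                     "capable": capable, "observed": observed})
    flags = pd.DataFrame(rows, columns=["event_id", "conserved", "ag_offset",
                                        "bp_adenosine", "capable", "observed"])
    report = CascadeReport(
        n_input=len(flags),
        n_conserved=int(flags["conserved"].sum()),
        n_capable=int(flags["capable"].sum()),
        n_observed=int(flags["observed"].sum()),
        flags=flags,
    )
    log.info("conservation cascade: %d -> %d conserved -> %d capable -> %d observed",
             report.n_input, report.n_conserved, report.n_capable,
             report.n_observed)
    return report
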
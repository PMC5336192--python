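"""Synthetic two-genotype splicing datasets with planted cryptic 3' splice sites.

The generator emulates the study design the analysis assumes: replicate
junction-count tables from a wild-type and a mutant genotype, where a chosen set
of genes carries a cryptic 3' splice site a short distance (default 15-24 nt)
upstream of a canonical acceptor.  Planted events carry the sequence features
associated with mutant-SF3B1 acceptor choice:

* a cryptic ``AG`` whose last ``G`` sits exactly ``offset`` nt upstream of the
  canonical acceptor's ``G`` (no other ``AG`` intervenes),
* a single branchpoint adenosine at a position in ``-8..-18`` relative to the
  cryptic ``AG`` (``G`` at -1, ``A`` at -2, first upstream intronic base at -3),
* a pyrimidine-poor (G/T/C) tract upstream of the cryptic ``AG``, contrasting
  with the pyrimidine-rich, A- and G-free tract of every canonical acceptor.

Counts are negative-binomial around a target boundary-group depth and split
multinomially between the canonical junction, the cryptic junction and an
intron-retention pseudo-member according to group-specific true PSI.  A
configurable fraction of events gains a stop codon inside the exonic extension
("TAAATAAATAA" terminates translation in any reading frame), providing exact
gene-level NMD truth; expression counts of those genes are down-scaled in the
mutant group.  An orthology table with per-event conservation/capability truth
flags exercises the cross-species cascade, including its negative branches.

All randomness flows from ``SimConfig.seed``; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import random_codons, random_seq, revcomp
from .models import IsoformModel

_PTC_BLOCK = "TGACTGACTGA"  # TGA stop in every reading frame, AG-free, A-sparse


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults are the package's reference scenario: 200 multi-exon genes split
    across synthetic chromosomes, 20 planted cryptic-acceptor events with a
    true PSI shift of 0.3 in the mutant group, three replicates per genotype
    and overdispersed counts (variance ``mu + mu^2/dispersion``).
    """

    n_genes: int = 200
    n_cryptic_events: int = 20
    delta_psi: float = 0.3
    cryptic_offset_range: tuple[int, int] = (15, 24)
    bp_offset_range: tuple[int, int] = (8, 18)
    mean_junction_depth: float = 200.0
    dispersion: float = 10.0
    n_reps_per_group: int = 3
    seed: int = 0
    ptc_fraction: float = 0.5
    # baseline composition of every planted boundary group
    cryptic_psi_baseline: float = 0.02
    retention_psi: float = 0.05
    # expression table
    mean_gene_expression: float = 500.0
    nmd_expression_scale: float = 0.5
    # orthology emission (fractions are conditional on the previous tier)
    ortho_conserved_frac: float = 0.8
    ortho_capable_frac: float = 0.6
    ortho_observed_frac: float = 0.5
    # gene geometry
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length_range: tuple[int, int] = (90, 150)
    intron_length_range: tuple[int, int] = (150, 300)
    genes_per_chrom: int = 50

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_cryptic_events > self.n_genes:
            raise ConfigError("n_cryptic_events cannot exceed n_genes")
        if self.n_cryptic_events < 0:
            raise ConfigError("n_cryptic_events must be >= 0")
        lo, hi = self.cryptic_offset_range
        if not (1 <= lo <= hi <= 100):
            raise ConfigError("cryptic_offset_range must lie within [1, 100]")
        if lo < 5:
            raise ConfigError("cryptic offsets below 5 collide with the canonical AG")
        blo, bhi = self.bp_offset_range
        if not (1 <= blo <= bhi <= 50):
            raise ConfigError("bp_offset_range must lie within [1, 50]")
        if bhi > 25:
            raise ConfigError("bp offsets beyond -25 leave the planted tract")
        if not 0.0 <= self.delta_psi <= 1.0:
            raise ConfigError("delta_psi must be a fraction in [0, 1]")
        if not 0.0 <= self.ptc_fraction <= 1.0:
            raise ConfigError("ptc_fraction must be a fraction in [0, 1]")
        top = self.cryptic_psi_baseline + self.delta_psi + self.retention_psi
        if top >= 1.0:
            raise ConfigError("baseline PSI + delta_psi + retention PSI must be < 1")
        if self.mean_junction_depth <= 0 or self.dispersion <= 0:
            raise ConfigError("depth and dispersion must be positive")
        if self.n_reps_per_group < 1:
            raise ConfigError("n_reps_per_group must be >= 1")
        if self.exons_per_gene[0] < 3:
            raise ConfigError("genes need >= 3 exons so extensions stay internal")
        if self.intron_length_range[0] < hi + 30:
            raise ConfigError("introns too short for the requested offsets")

    @property
    def samples(self) -> list[str]:
        n = self.n_reps_per_group
        return [f"WT{i+1}" for i in range(n)] + [f"MUT{i+1}" for i in range(n)]

    @property
    def sample_groups(self) -> dict[str, str]:
        return {s: ("WT" if s.startswith("WT") else "MUT") for s in self.samples}


@dataclass(frozen=True)
class EventTruth:
    """Ground truth for one planted cryptic-acceptor event."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    intron_index: int
    donor_pos: int              # internal 0-based boundary coordinate
    canonical_acceptor: int     # internal boundary coordinate of canonical 3'ss
    cryptic_acceptor: int       # internal boundary coordinate of cryptic 3'ss
    offset: int                 # AG-to-AG distance, transcription orientation
    bp_offset: int              # designated branchpoint A, relative to cryptic AG
    bp_adenosines: tuple[int, ...]  # all planted A offsets within -8..-18
    ptc: bool                   # extension introduces an in-frame stop
    psi_wt: dict[str, float]
    psi_mut: dict[str, float]
    conserved: bool
    capable: bool               # cryptic AG in -5..-20 AND bp A in -8..-18 in species B
    observed: bool              # "seen spliced" evidence flag in species B
    ortho_window: str | None    # species-B acceptor window (-35..+3) if conserved


@dataclass
class SimTruth:
    """Planted-event records plus the sample layout they were simulated under."""

    events: list[EventTruth]
    samples: list[str]
    sample_groups: dict[str, str]
    config: SimConfig

    def event_gene_ids(self) -> set[str]:
        return {ev.gene_id for ev in self.events}

    def nmd_gene_ids(self) -> set[str]:
        return {ev.gene_id for ev in self.events if ev.ptc}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "samples": self.samples,
            "sample_groups": self.sample_groups,
            "config": dataclasses.asdict(self.config),
            "events": [dataclasses.asdict(ev) for ev in self.events],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SimData:
    """Simulated count tables for one dataset."""

    junction_counts: pd.DataFrame   # chrom,strand,start,end,annotated + sample cols
    coverage: pd.DataFrame          # chrom,pos,side,sample,count (pos = inter-base)
    expression: pd.DataFrame        # genes x samples
    samples: list[str]
    sample_groups: dict[str, str]


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _plain_acceptor_tail(rng: np.random.Generator, hi: int) -> str:
    """Canonical-style acceptor tail: AG-free for offsets 3..hi, pyrimidine tract.

    Layout (transcription orientation, ending at the canonical G): a G-free
    far region, a pure-pyrimidine tract covering -5..-20, pyrimidines at -4/-3
    and the invariant AG at -2/-1.  Keeping the whole tail G-free guarantees
    that no AG competes inside the cryptic-offset scan window.
    """
    t = hi + 2  # tail length so that any AG with offset <= hi would sit inside
    far = random_seq(rng, t - 20, "ACT")           # -t .. -21
    tract = random_seq(rng, 16, "CT")              # -20 .. -5, A- and G-free
    return far + tract + random_seq(rng, 2, "CT") + "AG"


def _event_acceptor_tail(rng: np.random.Generator, offset: int, bp_offset: int,
                         ptc: bool) -> tuple[str, tuple[int, ...]]:
    """Aberrant acceptor tail ending at the canonical AG.

    ``[weak 23 nt][cryptic AG][extension interior][canonical AG]`` where the
    weak zone covers positions -3..-25 of the cryptic AG: pyrimidine-poor and
    adenine-rich (branchpoint-like), with an adenosine guaranteed at the
    designated ``bp_offset`` and no AG dinucleotide anywhere, so the cryptic
    AG is the only AG upstream of the canonical one (the extension interior is
    G-free too).  Returns the tail and the realised adenosine offsets within
    the -8..-18 branchpoint-search window of the cryptic AG.
    """
    zone = list(random_seq(rng, 23, "AGTC", probs=[0.35, 0.3, 0.2, 0.15]))
    # zone[i] is position -(25 - i) relative to the cryptic AG's G at -1
    zone[25 - bp_offset] = "A"
    for i in range(len(zone) - 1):
        if zone[i] == "A" and zone[i + 1] == "G":
            zone[i + 1] = "T"
    bps = tuple(p for p in range(8, 19) if zone[25 - p] == "A")
    if ptc:
        interior = _PTC_BLOCK + "C" * (offset - 2 - len(_PTC_BLOCK))
    else:
        interior = "C" * (offset - 2)
    return "".join(zone) + "AG" + interior + "AG", bps


def _build_intron(rng: np.random.Generator, length: int, tail: str) -> str:
    core = random_seq(rng, length - 2 - len(tail))
    return "GT" + core + tail


def make_genome_and_annotation(
    config: SimConfig,
) -> tuple[dict[str, str], list[IsoformModel], SimTruth]:
    """Build the toy genome, one isoform per gene, and the planted-event truth.

    Returns ``(genome, isoforms, truth)`` where ``genome`` maps chromosome name
    to sequence.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([int(config.seed) % (2**31), 11])
    lo, hi = config.cryptic_offset_range
    blo, bhi = config.bp_offset_range

    event_genes = set(
        rng.choice(config.n_genes, size=config.n_cryptic_events, replace=False).tolist()
    )
    frame_neutral = [d for d in range(lo, hi + 1) if d % 3 == 0]
    if not frame_neutral and config.ptc_fraction < 1.0:
        raise ConfigError(
            "cryptic_offset_range contains no multiple of 3; cannot plant "
            "frame-preserving (PTC-free) events"
        )

    c = config.cryptic_psi_baseline
    r = config.retention_psi
    psi_wt = {"canonical": 1.0 - c - r, "cryptic": c, "retention": r}
    psi_mut = {
        "canonical": 1.0 - c - config.delta_psi - r,
        "cryptic": c + config.delta_psi,
        "retention": r,
    }

    genome: dict[str, str] = {}
    isoforms: list[IsoformModel] = []
    events: list[EventTruth] = []

    chrom_parts: list[str] = []
    chrom_cursor = 0
    chrom_idx = 1
    spacer_end = 500
    spacer_mid = 300

    def flush_chrom() -> None:
        nonlocal chrom_parts, chrom_cursor, chrom_idx
        if chrom_parts:
            genome[f"chr{chrom_idx}"] = "".join(chrom_parts)
            chrom_idx += 1
            chrom_parts = []
            chrom_cursor = 0

    for g in range(config.n_genes):
        if g % config.genes_per_chrom == 0 and g > 0:
            chrom_parts.append(random_seq(rng, spacer_end))
            flush_chrom()
        chrom = f"chr{chrom_idx}"
        gene_id = f"g{g+1:04d}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = (rng.integers(config.exon_length_range[0] // 3,
                                  config.exon_length_range[1] // 3 + 1, size=k) * 3)
        intron_lens = rng.integers(config.intron_length_range[0],
                                   config.intron_length_range[1] + 1, size=k - 1)

        is_event = g in event_genes
        if is_event:
            # keep the extension inside an internal exon so NMD truth is clean
            ev_intron = int(rng.integers(0, k - 2))
            ptc = bool(rng.random() < config.ptc_fraction)
            if ptc:
                offset = int(rng.integers(lo, hi + 1))
            else:
                offset = int(frame_neutral[rng.integers(0, len(frame_neutral))])
            bp_offset = int(rng.integers(blo, bhi + 1))
        else:
            ev_intron, ptc, offset, bp_offset = -1, False, 0, 0
        bp_adenosines: tuple[int, ...] = ()

        # whole-transcript coding sequence: start codon, sense codons, stop
        n_codons = int(exon_lens.sum()) // 3
        tx_exonic = "ATG" + random_codons(rng, n_codons - 2) + "TAA"

        # assemble the gene in transcription orientation
        pieces: list[str] = []
        exon_tx: list[tuple[int, int]] = []
        intron_tx: list[tuple[int, int]] = []
        pos = 0
        e_cursor = 0
        for j in range(k):
            exon_seq = tx_exonic[e_cursor:e_cursor + int(exon_lens[j])]
            e_cursor += int(exon_lens[j])
            pieces.append(exon_seq)
            exon_tx.append((pos, pos + len(exon_seq)))
            pos += len(exon_seq)
            if j < k - 1:
                if is_event and j == ev_intron:
                    tail, bp_adenosines = _event_acceptor_tail(
                        rng, offset, bp_offset, ptc)
                else:
                    tail = _plain_acceptor_tail(rng, hi)
                iseq = _build_intron(rng, int(intron_lens[j]), tail)
                pieces.append(iseq)
                intron_tx.append((pos, pos + len(iseq)))
                pos += len(iseq)
        gene_tx = "".join(pieces)
        glen = len(gene_tx)

        gene_start = chrom_cursor + (spacer_end if chrom_cursor == 0 else spacer_mid)
        chrom_parts.append(random_seq(rng, gene_start - chrom_cursor))
        if strand == "+":
            chrom_parts.append(gene_tx)
            exons = [(gene_start + a, gene_start + b) for a, b in exon_tx]
        else:
            chrom_parts.append(revcomp(gene_tx))
            exons = sorted((gene_start + glen - b, gene_start + glen - a)
                           for a, b in exon_tx)
        chrom_cursor = gene_start + glen
        isoforms.append(IsoformModel(gene_id, f"{gene_id}.t1", chrom, strand,
                                     tuple(exons)))

        if is_event:
            a, b = intron_tx[ev_intron]
            if strand == "+":
                s, e = gene_start + a, gene_start + b
                donor, canon_acc = s, e
                cryp_acc = e - offset
            else:
                s, e = gene_start + glen - b, gene_start + glen - a
                donor, canon_acc = e, s
                cryp_acc = s + offset
            conserved = bool(rng.random() < config.ortho_conserved_frac)
            capable = conserved and bool(rng.random() < config.ortho_capable_frac)
            observed = capable and bool(rng.random() < config.ortho_observed_frac)
            window = _ortho_window(rng, offset, capable) if conserved else None
            events.append(EventTruth(
                event_id=f"ev_{gene_id}", gene_id=gene_id, chrom=chrom,
                strand=strand, intron_index=ev_intron, donor_pos=donor,
                canonical_acceptor=canon_acc, cryptic_acceptor=cryp_acc,
                offset=offset, bp_offset=bp_offset,
                bp_adenosines=bp_adenosines, ptc=ptc,
                psi_wt=dict(psi_wt), psi_mut=dict(psi_mut),
                conserved=conserved, capable=capable, observed=observed,
                ortho_window=window,
            ))

    chrom_parts.append(random_seq(rng, spacer_end))
    flush_chrom()

    truth = SimTruth(events=events, samples=config.samples,
                     sample_groups=config.sample_groups, config=config)
    return genome, isoforms, truth


def _ortho_window(rng: np.random.Generator, offset: int, capable: bool) -> str:
    """Species-B acceptor window (-35..+3) for a conserved canonical junction.

    Capable windows contain a cryptic AG at ``min(offset, 17)`` (inside the
    -5..-20 preference window, and far enough from -35 that the full -8..-18
    branchpoint range is assessable) plus exactly one branchpoint adenosine;
    non-capable windows are pyrimidine fill with no candidate AG at all.
    """
    win = list(random_seq(rng, 33, "CT")) + ["A", "G"] + list(random_seq(rng, 3))
    if capable:
        bd = min(offset, 17)
        win[33 - bd] = "A"
        win[34 - bd] = "G"
        p = int(rng.integers(8, 19))
        win[35 - bd - p] = "A"
    return "".join(win)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial with variance ``mean + mean**2 / dispersion``."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_counts(
    isoforms: Sequence[IsoformModel],
    truth: SimTruth,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> SimData:
    """Draw replicate junction, retention-coverage and expression counts.

    ``seed`` overrides the count-level seed (the planted genome structure stays
    that of ``truth``); by default counts derive from ``config.seed`` so a full
    run is reproducible end to end.
    """
    config = config or truth.config
    config.validate()
    count_seed = config.seed if seed is None else seed
    rng = np.random.default_rng([int(count_seed) % (2**31), 23])
    samples = config.samples
    n_s = len(samples)

    event_introns: dict[tuple[str, int, int], EventTruth] = {}
    for ev in truth.events:
        s, e = sorted((ev.donor_pos, ev.canonical_acceptor))
        event_introns[(ev.chrom, s, e)] = ev

    rows: list[tuple] = []   # chrom, strand, start, end, annotated, counts...
    cov_rows: list[tuple] = []
    plain: list[tuple] = []  # (chrom, strand, s, e, donor_pos) for bulk draws

    for iso in isoforms:
        for s, e in iso.introns():
            ev = event_introns.get((iso.chrom, s, e))
            if ev is None:
                donor = s if iso.strand == "+" else e
                plain.append((iso.chrom, iso.strand, s, e, donor))
                continue
            if ev.strand == "+":
                cs, ce = s, e - ev.offset
            else:
                cs, ce = s + ev.offset, e
            canon = np.zeros(n_s, dtype=int)
            cryp = np.zeros(n_s, dtype=int)
            ret = np.zeros(n_s, dtype=int)
            for i, sample in enumerate(samples):
                psi = ev.psi_wt if truth.sample_groups[sample] == "WT" else ev.psi_mut
                total = int(_nb(rng, config.mean_junction_depth, config.dispersion, 1)[0])
                canon[i], cryp[i], ret[i] = rng.multinomial(
                    total, [psi["canonical"], psi["cryptic"], psi["retention"]])
            rows.append((iso.chrom, iso.strand, s, e, 1, *canon))
            rows.append((iso.chrom, iso.strand, cs, ce, 0, *cryp))
            for i, sample in enumerate(samples):
                cov_rows.append((iso.chrom, ev.donor_pos, "donor", sample, int(ret[i])))

    # every exon|intron boundary sees some read-through: non-event introns get
    # retention counts too (constant true retention PSI in both groups)
    if plain:
        totals = _nb(rng, config.mean_junction_depth, config.dispersion,
                     (len(plain), n_s))
        ret = rng.binomial(totals, config.retention_psi)
        canon = totals - ret
        for k, (chrom, strand, s, e, donor) in enumerate(plain):
            rows.append((chrom, strand, s, e, 1, *canon[k]))
            for i, sample in enumerate(samples):
                cov_rows.append((chrom, donor, "donor", sample, int(ret[k, i])))

    junctions = pd.DataFrame(
        rows, columns=["chrom", "strand", "start", "end", "annotated", *samples])
    # STAR does not report unobserved junctions; drop all-zero cryptic rows the
    # same way, per sample, when written out (kept dense here for convenience).
    coverage = pd.DataFrame(cov_rows, columns=["chrom", "pos", "side", "sample", "count"])

    nmd_genes = truth.nmd_gene_ids()
    gene_ids = sorted({iso.gene_id for iso in isoforms})
    expr = np.empty((len(gene_ids), n_s), dtype=int)
    for gi, gid in enumerate(gene_ids):
        for si, sample in enumerate(samples):
            mean = config.mean_gene_expression
            if gid in nmd_genes and truth.sample_groups[sample] == "MUT":
                mean *= config.nmd_expression_scale
            expr[gi, si] = _nb(rng, mean, config.dispersion, 1)[0]
    expression = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                              columns=samples)

    return SimData(junction_counts=junctions, coverage=coverage,
                   expression=expression, samples=samples,
                   sample_groups=config.sample_groups)


def orthology_table(truth: SimTruth) -> pd.DataFrame:
    """Orthology records for every planted event (cascade input).

    ``event_id`` uses the pipeline's event key (``anchor_id|member_id`` of the
    cryptic junction) so detected events join directly; ``name`` keeps the
    generator's own event label.
    """
    rows = []
    for ev in truth.events:
        s, e = sorted((ev.donor_pos, ev.cryptic_acceptor))
        eid = (f"{ev.chrom}:{ev.strand}:{ev.donor_pos}:donor"
               f"|{ev.chrom}:{s}-{e}:{ev.strand}")
        rows.append({
            "event_id": eid,
            "name": ev.event_id,
            "conserved": int(ev.conserved),
            "window": ev.ortho_window or "",
            "observed": int(ev.observed),
        })
    return pd.DataFrame(rows, columns=["event_id", "name", "conserved",
                                       "window", "observed"])


# ---------------------------------------------------------------------------
# planted-structure audit and mirroring
# ---------------------------------------------------------------------------

def acceptor_upstream_window(genome: Mapping[str, str], chrom: str, boundary: int,
                             strand: str, length: int) -> str:
    """Intronic sequence ending at the acceptor's G, transcription orientation."""
    seq = genome[chrom]
    if strand == "+":
        return str(seq[boundary - length:boundary]).upper()
    return revcomp(str(seq[boundary:boundary + length])).upper()


def audit_planted_structure(genome: Mapping[str, str],
                            truth: SimTruth) -> pd.DataFrame:
    """Independently re-scan the genome for each planted event's structure.

    Returns one row per event with the recovered cryptic-AG offsets (every AG
    within the engineered acceptor region, offsets ``3..offset+20`` upstream of
    the canonical AG) and the recovered branchpoint adenosine offsets
    (positions in -8..-18 of the cryptic AG that hold an A).  On a correctly
    planted genome each set is exactly the singleton recorded in the truth.
    """
    recs = []
    for ev in truth.events:
        n = ev.offset + 25
        w = acceptor_upstream_window(genome, ev.chrom, ev.canonical_acceptor,
                                     ev.strand, n)
        ags = [d for d in range(3, ev.offset + 21)
               if w[-1 - d] == "G" and w[-2 - d] == "A"]
        bps = tuple(p for p in range(8, 19)
                    if w[n - ev.offset - p] == "A")
        recs.append({"event_id": ev.event_id, "offset": ev.offset,
                     "bp_offset": ev.bp_offset,
                     "bp_adenosines": ev.bp_adenosines,
                     "found_ags": ags, "found_bps": bps})
    return pd.DataFrame(recs)


def mirror_genome(genome: Mapping[str, str]) -> dict[str, str]:
    """Reverse-complement every chromosome (strand-mirroring the dataset)."""
    return {chrom: revcomp(seq) for chrom, seq in genome.items()}


def mirror_isoforms(isoforms: Sequence[IsoformModel],
                    chrom_lengths: Mapping[str, int]) -> list[IsoformModel]:
    out = []
    for iso in isoforms:
        L = chrom_lengths[iso.chrom]
        exons = sorted((L - e, L - s) for s, e in iso.exons)
        strand = "-" if iso.strand == "+" else "+"
        out.append(IsoformModel(iso.gene_id, iso.transcript_id, iso.chrom,
                                strand, tuple(exons), iso.cds_start, iso.cds_end))
    return out


def mirror_junction_counts(junctions: pd.DataFrame,
                           chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    df = junctions.copy()
    L = df["chrom"].map(chrom_lengths)
    start = L - df["end"]
    end = L - df["start"]
    df["start"], df["end"] = start, end
    df["strand"] = df["strand"].map({"+": "-", "-": "+", ".": "."})
    return df


def mirror_coverage(coverage: pd.DataFrame,
                    chrom_lengths: Mapping[str, int]) -> pd.DataFrame:
    df = coverage.copy()
    df["pos"] = df["chrom"].map(chrom_lengths) - df["pos"]
    return df
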
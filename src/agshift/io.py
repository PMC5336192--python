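"""Readers and writers for the pipeline's file formats.

Internally everything is 0-based half-open; the 1-based closed conventions of
GTF and STAR ``SJ.out.tab`` are converted here and nowhere else.

Formats:

* STAR ``SJ.out.tab`` dialect — 9 tab-separated columns: chrom, intron start
  (1-based, first intronic base), intron end (1-based, last intronic base),
  strand code (0 unknown / 1 ``+`` / 2 ``-``), intron motif code, annotated
  flag, unique-read count, multi-mapping-read count, max overhang.  Only the
  unique-read count is used downstream.
* boundary-coverage TSV — chrom, pos, side, sample, count; ``pos`` is the
  0-based inter-base coordinate of the exon|intron boundary (strand-free), and
  ``count`` is the number of reads fully covering the 6-bp window (3 exonic +
  3 intronic nt) at that boundary.
* expression TSV — gene x sample raw counts, first column ``gene_id``.
* orthology TSV — event_id, conserved (0/1), window (species-B acceptor
  sequence -35..+3 in transcription orientation, empty if not conserved),
  observed (0/1).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .models import IsoformModel

log = logging.getLogger(__name__)

_STRAND_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_STRAND = {v: k for k, v in _STRAND_CODE.items()}

SJ_COLUMNS = ["chrom", "start1", "end1", "strand_code", "motif",
              "annotated", "unique", "multi", "overhang"]


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# junction tables
# ---------------------------------------------------------------------------

def read_sj_table(path: str | Path) -> pd.DataFrame:
    """Read one STAR-dialect junction table into internal coordinates.

    Returns a DataFrame with columns chrom, strand, start, end, annotated,
    count (unique reads only; multi-mappers are dropped as non-conservative).
    Unknown-strand rows (code 0) are retained with strand ``"."``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, names=SJ_COLUMNS,
                          dtype={"chrom": str}, comment="#")
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=SJ_COLUMNS)
    if raw.empty:
        log.warning("junction table %s is empty", path)
        return pd.DataFrame(columns=["chrom", "strand", "start", "end",
                                     "annotated", "count"])
    if raw.shape[1] != 9 or raw[SJ_COLUMNS[1:]].isna().any().any():
        raise ParseError(f"{path}: expected 9 tab-separated columns")
    for col in ("start1", "end1", "unique"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            bad = int(vals.isna().idxmax()) + 1
            raise ParseError(f"{path}: malformed numeric field in line {bad}")
        raw[col] = vals.astype(int)
    if (raw["unique"] < 0).any():
        bad = int((raw["unique"] < 0).idxmax()) + 1
        raise ParseError(f"{path}: negative count in line {bad}")
    if (raw["start1"] > raw["end1"]).any():
        bad = int((raw["start1"] > raw["end1"]).idxmax()) + 1
        raise ParseError(f"{path}: intron start after end in line {bad}")
    out = pd.DataFrame({
        "chrom": raw["chrom"],
        "strand": raw["strand_code"].map(_STRAND_CODE),
        "start": raw["start1"] - 1,          # first intronic base, 0-based
        "end": raw["end1"],                  # half-open end
        "annotated": raw["annotated"].astype(int),
        "count": raw["unique"],
    })
    if out["strand"].isna().any():
        raise ParseError(f"{path}: invalid strand code")
    return out


def combine_sj_tables(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Outer-join per-sample junction tables on the junction key.

    Junctions absent from a sample get count 0.  Returns chrom, strand, start,
    end, annotated plus one count column per sample.
    """
    key = ["chrom", "strand", "start", "end"]
    merged: pd.DataFrame | None = None
    ann: pd.Series | None = None
    for sample, df in tables.items():
        part = df.set_index(key)[["count"]].rename(columns={"count": sample})
        a = df.set_index(key)["annotated"]
        merged = part if merged is None else merged.join(part, how="outer")
        ann = a if ann is None else ann.combine_first(a)
    if merged is None:
        raise ValueError("no junction tables given")
    merged = merged.fillna(0).astype(int)
    merged.insert(0, "annotated", ann.reindex(merged.index).fillna(0).astype(int))
    return merged.reset_index()


def write_sj_table(junctions: pd.DataFrame, sample: str, path: str | Path,
                   drop_zero: bool = True) -> None:
    """Write one sample's counts from a combined junction frame as SJ.out.tab."""
    df = junctions
    if drop_zero:
        df = df[df[sample] > 0]
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start1": df["start"] + 1,
        "end1": df["end"],
        "strand_code": df["strand"].map(_CODE_STRAND),
        "motif": df["strand"].map({"+": 1, "-": 2, ".": 0}),
        "annotated": df.get("annotated", 0),
        "unique": df[sample],
        "multi": 0,
        "overhang": 30,
    })
    out.sort_values(["chrom", "start1", "end1"]).to_csv(
        path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# coverage / expression / orthology
# ---------------------------------------------------------------------------

def read_coverage_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "side": str,
                                            "sample": str})
    expected = {"chrom", "pos", "side", "sample", "count"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: coverage table needs columns {sorted(expected)}")
    if (df["count"] < 0).any():
        raise ParseError(f"{path}: negative coverage count")
    return df


def write_coverage_table(coverage: pd.DataFrame, path: str | Path) -> None:
    coverage.to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    return df


def write_expression_table(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t")


def read_orthology_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "window": str},
                     keep_default_na=False)
    expected = {"event_id", "conserved", "window", "observed"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: orthology table needs columns {sorted(expected)}")
    return df


def write_orthology_table(ortho: pd.DataFrame, path: str | Path) -> None:
    ortho.to_csv(path, sep="\t", index=False)


def read_samples_table(path: str | Path) -> pd.DataFrame:
    """Sample sheet: sample, group, sj_path (one junction table per sample)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"sample", "group", "sj_path"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: sample sheet needs columns {sorted(expected)}")
    return df


# ---------------------------------------------------------------------------
# FASTA / GTF
# ---------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA into memory via pyfaidx.

    Desk-scale genomes fit comfortably in memory; the analysis functions also
    accept a ``pyfaidx.Fasta`` object directly for larger inputs.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_gtf(isoforms: Sequence[IsoformModel], path: str | Path) -> None:
    """Write transcripts with exon and CDS features (1-based closed coords)."""
    with open(path, "w") as fh:
        for iso in isoforms:
            attrs = f'gene_id "{iso.gene_id}"; transcript_id "{iso.transcript_id}";'
            fh.write("\t".join([iso.chrom, "agshift", "transcript",
                                str(iso.start + 1), str(iso.end), ".",
                                iso.strand, ".", attrs]) + "\n")
            for s, e in iso.exons:
                fh.write("\t".join([iso.chrom, "agshift", "exon",
                                    str(s + 1), str(e), ".", iso.strand, ".",
                                    attrs]) + "\n")
            for s, e in iso.exons:
                fh.write("\t".join([iso.chrom, "agshift", "CDS",
                                    str(s + 1), str(e), ".", iso.strand, "0",
                                    attrs]) + "\n")


def read_gtf(path: str | Path) -> list[IsoformModel]:
    """Load transcript models from a GTF via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            disable_infer_genes=True,
                            disable_infer_transcripts=True,
                            merge_strategy="create_unique")
    isoforms: list[IsoformModel] = []
    tx_exons: dict[str, list] = {}
    tx_meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features(featuretype="exon"):
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes["gene_id"][0]
        tx_exons.setdefault(tid, []).append((feat.start - 1, feat.end))
        tx_meta[tid] = (gid, feat.seqid, feat.strand)
    for tid, exons in tx_exons.items():
        gid, chrom, strand = tx_meta[tid]
        isoforms.append(IsoformModel(gid, tid, chrom, strand,
                                     tuple(sorted(exons))))
    isoforms.sort(key=lambda iso: (iso.chrom, iso.start, iso.transcript_id))
    return isoforms
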
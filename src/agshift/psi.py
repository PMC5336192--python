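"""Boundary-group construction and percent-spliced-in (PSI) quantification.

A *boundary group* is the denominator unit for PSI: two or more junctions that
share one boundary coordinate (donor-shared or acceptor-shared) but have
distinct far ends, optionally extended by an intron-retention pseudo-member
whose counts are reads fully covering the 6-bp exon|intron window at the shared
boundary.  PSI of a member in a sample is its count divided by the group total
in that sample; groups below a coverage floor in a sample are missing there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RETENTION_MEMBER = "RET"


@dataclass
class PsiMatrix:
    """PSI values plus the group totals they were computed from.

    ``psi`` is indexed by (anchor_id, member_id) with one column per sample;
    missing values (group total below ``min_total``) are NaN.  ``totals`` is
    indexed by anchor_id.
    """

    psi: pd.DataFrame
    totals: pd.DataFrame
    min_total: int

    def long(self) -> pd.DataFrame:
        out = (self.psi.stack(future_stack=True)
               .rename("psi").reset_index())
        out.columns = ["anchor_id", "member_id", "sample", "psi"]
        tot = (self.totals.stack(future_stack=True)
               .rename("total").reset_index())
        tot.columns = ["anchor_id", "sample", "total"]
        return out.merge(tot, on=["anchor_id", "sample"], how="left")


def anchor_id(chrom: str, strand: str, pos: int, side: str) -> str:
    return f"{chrom}:{strand}:{pos}:{side}"


def member_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


def _with_anchor_columns(junctions: pd.DataFrame) -> pd.DataFrame:
    """Add donor/acceptor boundary coordinates (strand-aware)."""
    df = junctions.copy()
    plus = df["strand"] != "-"
    df["donor_pos"] = np.where(plus, df["start"], df["end"])
    df["acceptor_pos"] = np.where(plus, df["end"], df["start"])
    return df


def count_intron_retention(coverage: pd.DataFrame, chrom: str, pos: int,
                           side: str, samples: list[str]) -> tuple[pd.Series, bool]:
    """Per-sample retention counts for one boundary anchor.

    Returns ``(counts, has_data)``; a boundary absent from the coverage table
    yields zeros with ``has_data=False`` ("no-coverage-data").
    """
    sel = coverage[(coverage["chrom"] == chrom) & (coverage["pos"] == pos)
                   & (coverage["side"] == side)]
    if sel.empty:
        return pd.Series(0, index=samples), False
    counts = sel.groupby("sample")["count"].sum().reindex(samples).fillna(0)
    return counts.astype(int), True


def group_by_boundary(junctions: pd.DataFrame,
                      coverage: pd.DataFrame | None = None) -> pd.DataFrame:
    """Build boundary groups from a combined junction frame.

    ``junctions`` must have chrom, strand, start, end plus one count column per
    sample (``combine_sj_tables`` output).  Returns a *members* frame with one
    row per (group, member): anchor_id, chrom, strand, anchor_pos, side,
    member_id, start, end, is_retention, plus the per-sample counts.  A
    junction can appear in up to two groups (donor-shared and acceptor-shared).
    Single-junction anchors are kept only when the coverage table provides a
    retention pseudo-member for the anchor boundary.
    """
    meta_cols = {"chrom", "strand", "start", "end", "annotated",
                 "donor_pos", "acceptor_pos"}
    samples = [c for c in junctions.columns if c not in meta_cols]
    df = _with_anchor_columns(junctions)

    cov_wide = None
    if coverage is not None and len(coverage):
        cov_wide = (coverage.groupby(["chrom", "pos", "side", "sample"])["count"]
                    .sum().unstack("sample").fillna(0).astype(int).reset_index())
        for s in samples:
            if s not in cov_wide.columns:
                cov_wide[s] = 0

    parts: list[pd.DataFrame] = []
    for side, anchor_col, far_col in (("donor", "donor_pos", "acceptor_pos"),
                                      ("acceptor", "acceptor_pos", "donor_pos")):
        keys = ["chrom", "strand", anchor_col]
        dup = df.duplicated(subset=keys + [far_col], keep=False)
        if dup.any():
            bad = df.loc[dup.idxmax()]
            raise ValueError(
                f"duplicate junction far-ends in group "
                f"{bad['chrom']}:{bad['strand']}:{bad[anchor_col]}")
        size = df.groupby(keys)[far_col].transform("size")

        cov_here = None
        if cov_wide is not None:
            cov_here = cov_wide[cov_wide["side"] == side]
        if cov_here is not None and len(cov_here):
            cov_anchor = set(zip(cov_here["chrom"], cov_here["pos"]))
            has_cov = pd.Series(
                [(c, p) in cov_anchor
                 for c, p in zip(df["chrom"], df[anchor_col])], index=df.index)
        else:
            has_cov = pd.Series(False, index=df.index)

        kept = df[(size >= 2) | has_cov].copy()
        if kept.empty:
            continue
        kept["anchor_pos"] = kept[anchor_col]
        kept["side"] = side
        kept["anchor_id"] = (kept["chrom"] + ":" + kept["strand"] + ":"
                             + kept["anchor_pos"].astype(str) + ":" + side)
        kept["member_id"] = (kept["chrom"] + ":" + kept["start"].astype(str)
                             + "-" + kept["end"].astype(str) + ":" + kept["strand"])
        kept["is_retention"] = False
        parts.append(kept[["anchor_id", "chrom", "strand", "anchor_pos", "side",
                           "member_id", "start", "end", "is_retention", *samples]])

        if cov_here is not None and len(cov_here):
            anchors = kept[["anchor_id", "chrom", "strand", "anchor_pos",
                            "side"]].drop_duplicates()
            ret = anchors.merge(cov_here.rename(columns={"pos": "anchor_pos"}),
                                on=["chrom", "anchor_pos"], how="inner",
                                suffixes=("", "_cov"))
            if len(ret):
                ret["member_id"] = RETENTION_MEMBER
                ret["start"] = -1
                ret["end"] = -1
                ret["is_retention"] = True
                parts.append(ret[["anchor_id", "chrom", "strand", "anchor_pos",
                                  "side", "member_id", "start", "end",
                                  "is_retention", *samples]])

    columns = ["anchor_id", "chrom", "strand", "anchor_pos", "side",
               "member_id", "start", "end", "is_retention", *samples]
    if parts:
        members = (pd.concat(parts, ignore_index=True)
                   .sort_values(["anchor_id", "is_retention", "start", "end"])
                   .reset_index(drop=True))
    else:
        members = pd.DataFrame(columns=columns)
    log.info("group_by_boundary: %d junctions -> %d groups (%d member rows)",
             len(junctions), members["anchor_id"].nunique() if len(members) else 0,
             len(members))
    return members


def compute_psi(members: pd.DataFrame, min_total: int = 10) -> PsiMatrix:
    """PSI per (group, member, sample); groups under ``min_total`` are missing.

    The retention pseudo-member enters both the numerator set and the group
    denominator.  Within a group and sample with a defined total, member PSI
    sums to 1.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    meta_cols = {"anchor_id", "chrom", "strand", "anchor_pos", "side",
                 "member_id", "start", "end", "is_retention"}
    samples = [c for c in members.columns if c not in meta_cols]
    counts = members.set_index(["anchor_id", "member_id"])[samples].astype(float)
    totals = counts.groupby(level="anchor_id").sum()
    denom = totals.reindex(counts.index.get_level_values("anchor_id"))
    denom.index = counts.index
    psi = counts / denom.where(denom >= min_total)
    return PsiMatrix(psi=psi, totals=totals.astype(int), min_total=min_total)
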
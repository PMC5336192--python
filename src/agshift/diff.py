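"""Two-group differential splicing with an empirical-Bayes moderated t-test.

Per boundary-group member, PSI is compared between genotypes with a pooled
two-sample t whose residual variance is shrunk toward a prior estimated from
all members (Smyth's hierarchical model: residual variances follow a scaled
inverse chi-square with prior df ``d0`` and prior value ``s0^2``).  The
hyperparameters are estimated by matching the first two moments of
``log s^2_g`` using digamma/trigamma closed forms, with a Newton inversion of
the trigamma function.  The moderated statistic is

    t_g = delta_g / sqrt(s2_post_g * (1/n1 + 1/n2)),
    s2_post_g = (d0 * s0^2 + d_g * s^2_g) / (d0 + d_g),

referred to a Student-t distribution on ``d_g + d0`` degrees of freedom.
P-values are Benjamini-Hochberg adjusted.  Significant members are then
classified by their geometry within the boundary group (alternative 3'/5'
splice site, cassette exon, intron retention) and checked for novelty against
the transcript annotation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .models import IsoformModel
from .psi import RETENTION_MEMBER, PsiMatrix

log = logging.getLogger(__name__)

EVENT_CLASSES = ("alt-3ss", "alt-5ss", "cassette-exon", "intron-retention", "other")


# ---------------------------------------------------------------------------
# hyperparameter estimation
# ---------------------------------------------------------------------------

def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ``trigamma(x) = y`` for ``x > 0`` by Newton iteration.

    Uses the standard monotone reparameterisation (Newton on 1/trigamma),
    which converges from the asymptotic starting value ``0.5 + 1/y``.
    """
    if y <= 0:
        raise ValueError("trigamma is positive; target must be > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < tol * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matching estimate of (prior df d0, prior variance s0^2).

    ``s2`` are positive residual variances with residual df ``df``.  Returns
    ``d0 = inf`` when the observed spread of ``log s2`` is no larger than
    expected from the residual df alone (no excess variability to model).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size == 0:
        raise ValueError("no positive variances to estimate a prior from")
    z = np.log(s2)
    e = z - special.psi(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    n = e.size
    if n < 2:
        return math.inf, float(np.exp(emean))
    target = float(np.mean((e - emean) ** 2 * n / (n - 1)
                           - special.polygamma(1, df / 2.0)))
    if target <= 0:
        return math.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(target)
    s0sq = float(np.exp(emean + special.psi(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0sq


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

@dataclass
class ModeratedFit:
    """Per-event moderated-t table plus the shared prior."""

    table: pd.DataFrame        # indexed (anchor_id, member_id)
    d0: float
    s0sq: float
    n_tested: int
    n_skipped: int
    skip_reasons: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def summary(self) -> dict:
        return {
            "d0": self.d0 if math.isfinite(self.d0) else "inf",
            "s0sq": self.s0sq,
            "n_tested": self.n_tested,
            "n_skipped": self.n_skipped,
        }


def reference_members(psi: PsiMatrix, wt_samples: list[str]) -> pd.Series:
    """The canonical (reference) member of each group: the junction member with
    the highest mean wild-type PSI.  Retention pseudo-members never serve as
    the reference."""
    mat = psi.psi[wt_samples]
    mean_wt = mat.mean(axis=1, skipna=True)
    frame = mean_wt.rename("mean_wt").reset_index()
    frame = frame[frame["member_id"] != RETENTION_MEMBER]
    frame = frame.sort_values(["anchor_id", "mean_wt", "member_id"],
                              ascending=[True, False, True])
    ref = frame.drop_duplicates("anchor_id").set_index("anchor_id")["member_id"]
    return ref


def fit_moderated_t(psi: PsiMatrix, sample_groups: dict[str, str],
                    contrast: tuple[str, str] = ("WT", "MUT"),
                    exclude_reference: bool = True,
                    d0_override: float | None = None,
                    arcsine: bool = False) -> ModeratedFit:
    """Moderated two-group t-test on every testable boundary-group member.

    ``contrast = (baseline, treatment)``; effects are treatment minus baseline
    on the PSI scale (``delta_psi``).  Members need at least two non-missing
    samples per group; the group's reference (canonical) member is excluded
    from testing by default since its change is the mirror image of the
    aberrant members'.  ``d0_override`` forces the prior df (0 gives the
    ordinary pooled t, ``inf`` the fully pooled variance).  ``arcsine`` applies
    an arcsine-square-root variance stabilisation before testing (off by
    default; the test is applied to raw PSI fractions).
    """
    base, treat = contrast
    samples = list(psi.psi.columns)
    g1 = [s for s in samples if sample_groups[s] == base]
    g2 = [s for s in samples if sample_groups[s] == treat]
    if not g1 or not g2:
        raise ValueError(f"contrast groups {contrast} not found in samples")

    mat = psi.psi
    if exclude_reference:
        ref = reference_members(psi, g1)
        anchors = mat.index.get_level_values("anchor_id")
        member = mat.index.get_level_values("member_id")
        is_ref = member == ref.reindex(anchors).to_numpy()
        mat = mat[~is_ref]

    x = mat[g1 + g2].to_numpy(dtype=float)
    if arcsine:
        x = np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))
    x1, x2 = x[:, :len(g1)], x[:, len(g1):]

    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.where(n1 > 0, np.nansum(x1, axis=1) / np.maximum(n1, 1), np.nan)
        m2 = np.where(n2 > 0, np.nansum(x2, axis=1) / np.maximum(n2, 1), np.nan)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    dg = n1 + n2 - 2.0
    testable = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(dg > 0, (ss1 + ss2) / np.maximum(dg, 1), np.nan)
    delta = m2 - m1

    def _prior() -> tuple[float, float]:
        try:
            return estimate_prior(s2[testable], dg[testable])
        except ValueError:
            # all residual variances zero: no spread to model
            return math.inf, float(np.nanmean(s2[testable])) if testable.any() else 0.0

    if d0_override is not None:
        d0 = float(d0_override)
        s0sq = float("nan") if d0 == 0 else _prior()[1]
    else:
        d0, s0sq = _prior()
        if math.isinf(d0):
            log.warning("no excess variance spread: d0 estimated infinite, "
                        "all posterior variances set to s0^2")

    if d0 == 0:
        s2_post = s2
        df_total = dg
    elif math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.full_like(dg, np.inf)
    else:
        s2_post = (d0 * s0sq + dg * s2) / (d0 + dg)
        df_total = dg + d0

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = delta / se
    # degenerate members: zero posterior variance (only possible with d0=0)
    zero_se = testable & ~(se > 0)
    t[zero_se & (delta == 0)] = 0.0
    t[zero_se & (delta != 0)] = np.sign(delta[zero_se & (delta != 0)]) * np.inf

    dfp = np.where(np.isinf(df_total), 1e9, df_total)
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), dfp)
    p[zero_se & (delta == 0)] = 1.0

    table = pd.DataFrame({
        "n_base": n1, "n_treat": n2,
        "mean_base": m1, "mean_treat": m2,
        "delta_psi": delta, "s2": s2, "df_resid": dg,
        "s2_post": s2_post, "t": t,
        "df_total": df_total, "p": p,
    }, index=mat.index)
    table.loc[~testable, ["t", "p"]] = np.nan
    table["q"] = bh_adjust(table["p"])

    reasons = pd.Series("", index=mat.index, dtype=object)
    reasons[~testable] = "fewer than 2 observations in a group"
    n_skip = int((~testable).sum())
    log.info("fit_moderated_t: %d members tested, %d skipped, d0=%.4g s0sq=%.4g",
             int(testable.sum()), n_skip, d0, s0sq)
    return ModeratedFit(table=table, d0=d0, s0sq=s0sq,
                        n_tested=int(testable.sum()), n_skipped=n_skip,
                        skip_reasons=reasons[reasons != ""])


def bh_adjust(p) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    NaN entries are ignored (and returned as NaN); ties receive their common
    step-up value through the cumulative-minimum from the largest rank.
    """
    arr = np.asarray(p, dtype=float)
    out = np.full(arr.shape, np.nan)
    ok = ~np.isnan(arr)
    if ((arr[ok] < 0) | (arr[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        out[ok] = multipletests(arr[ok], method="fdr_bh")[1]
    if isinstance(p, pd.Series):
        return pd.Series(out, index=p.index, name="q")
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass
class AnnotationIndex:
    """Fast lookups against a transcript annotation."""

    exon_starts: set[tuple[str, int]]
    exon_ends: set[tuple[str, int]]
    gene_spans: list[tuple[str, int, int, str, str]]  # chrom,start,end,strand,gene
    gene_exons: dict[str, list[tuple[int, int]]]

    @classmethod
    def from_isoforms(cls, isoforms: list[IsoformModel]) -> "AnnotationIndex":
        starts, ends = set(), set()
        spans = []
        gene_exons: dict[str, list[tuple[int, int]]] = {}
        bounds: dict[str, tuple[str, int, int, str]] = {}
        for iso in isoforms:
            for s, e in iso.exons:
                starts.add((iso.chrom, s))
                ends.add((iso.chrom, e))
                gene_exons.setdefault(iso.gene_id, []).append((s, e))
            cur = bounds.get(iso.gene_id)
            if cur is None:
                bounds[iso.gene_id] = (iso.chrom, iso.start, iso.end, iso.strand)
            else:
                chrom, s, e, strand = cur
                bounds[iso.gene_id] = (chrom, min(s, iso.start),
                                       max(e, iso.end), strand)
        for gid, (chrom, s, e, strand) in bounds.items():
            spans.append((chrom, s, e, strand, gid))
        spans.sort()
        return cls(starts, ends, spans, gene_exons)

    def gene_at(self, chrom: str, pos: int) -> str:
        for c, s, e, _strand, gid in self.gene_spans:
            if c == chrom and s <= pos < e:
                return gid
        return ""

    def is_annotated_acceptor(self, chrom: str, strand: str, boundary: int) -> bool:
        if strand == "+":
            return (chrom, boundary) in self.exon_starts
        return (chrom, boundary) in self.exon_ends

    def is_annotated_donor(self, chrom: str, strand: str, boundary: int) -> bool:
        if strand == "+":
            return (chrom, boundary) in self.exon_ends
        return (chrom, boundary) in self.exon_starts

    def contains_exon(self, gene_id: str, start: int, end: int) -> bool:
        """Is any annotated exon of ``gene_id`` fully inside (start, end)?"""
        for s, e in self.gene_exons.get(gene_id, ()):
            if start < s and e < end:
                return True
        return False


def classify_events(fit: ModeratedFit, members: pd.DataFrame,
                    annotation: AnnotationIndex,
                    psi: PsiMatrix, sample_groups: dict[str, str],
                    contrast: tuple[str, str] = ("WT", "MUT"),
                    q_max: float = 0.05,
                    min_abs_delta_psi: float = 0.1) -> pd.DataFrame:
    """Select significant members and classify them as splice-event calls.

    An event is a tested member with ``q < q_max`` and
    ``|delta_psi| >= min_abs_delta_psi``.  Class follows the geometry of the
    member relative to the group's canonical (reference) member; novelty is
    whether the member's far-end boundary coincides with any annotated exon
    boundary; ``distance_nt`` is the signed offset of the aberrant boundary
    from the canonical one in transcription orientation (positive = upstream).
    """
    base, _treat = contrast
    wt_samples = [s for s in psi.psi.columns if sample_groups[s] == base]
    ref = reference_members(psi, wt_samples)

    meta = members.set_index(["anchor_id", "member_id"])
    tab = fit.table
    sig = tab[(tab["q"] < q_max)
              & (tab["delta_psi"].abs() >= min_abs_delta_psi)].copy()

    rows = []
    for (aid, mid), row in sig.iterrows():
        m = meta.loc[(aid, mid)]
        if isinstance(m, pd.DataFrame):
            m = m.iloc[0]
        chrom, strand, side = m["chrom"], m["strand"], m["side"]
        canonical = ref.get(aid, "")
        distance = np.nan
        gene = annotation.gene_at(chrom, int(m["anchor_pos"]))
        novel = False

        if bool(m["is_retention"]):
            event_class = "intron-retention"
        else:
            cm = meta.loc[(aid, canonical)] if canonical in meta.loc[aid].index else None
            if isinstance(cm, pd.DataFrame):
                cm = cm.iloc[0]
            if gene and annotation.contains_exon(gene, int(m["start"]),
                                                 int(m["end"])) and (
                    cm is None or not annotation.contains_exon(
                        gene, int(cm["start"]), int(cm["end"]))):
                event_class = "cassette-exon"
            elif side == "donor":
                event_class = "alt-3ss"
            elif side == "acceptor":
                event_class = "alt-5ss"
            else:
                event_class = "other"

            plus = strand != "-"
            if side == "donor":
                far = int(m["end"]) if plus else int(m["start"])
                novel = not annotation.is_annotated_acceptor(chrom, strand, far)
                if cm is not None and event_class in ("alt-3ss", "cassette-exon"):
                    far_c = int(cm["end"]) if plus else int(cm["start"])
                    distance = (far_c - far) if plus else (far - far_c)
            elif side == "acceptor":
                far = int(m["start"]) if plus else int(m["end"])
                novel = not annotation.is_annotated_donor(chrom, strand, far)
                if cm is not None and event_class in ("alt-5ss", "cassette-exon"):
                    far_c = int(cm["start"]) if plus else int(cm["end"])
                    distance = (far_c - far) if plus else (far - far_c)

        rows.append({
            "anchor_id": aid, "member_id": mid, "canonical_member": canonical,
            "gene_id": gene, "chrom": chrom, "strand": strand, "side": side,
            "event_class": event_class, "novel": bool(novel),
            "distance_nt": distance,
            "member_start": int(m["start"]), "member_end": int(m["end"]),
            "delta_psi": row["delta_psi"], "t": row["t"], "p": row["p"],
            "q": row["q"],
        })
    events = pd.DataFrame(rows, columns=[
        "anchor_id", "member_id", "canonical_member", "gene_id", "chrom",
        "strand", "side", "event_class", "novel", "distance_nt",
        "member_start", "member_end", "delta_psi", "t", "p", "q"])
    log.info("classify_events: %d tested -> %d significant events",
             fit.n_tested, len(events))
    return events
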
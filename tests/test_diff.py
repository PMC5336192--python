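"""Moderated t-test, BH adjustment and event classification."""

from __future__ import annotations

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

import agshift as ag
from agshift import diff
from agshift.psi import PsiMatrix


def _psi_matrix(x: np.ndarray, k1: int, k2: int) -> tuple[PsiMatrix, dict]:
    samples = [f"A{i}" for i in range(k1)] + [f"B{i}" for i in range(k2)]
    idx = pd.MultiIndex.from_tuples([(f"g{i}", "m") for i in range(x.shape[0])],
                                    names=["anchor_id", "member_id"])
    psi = PsiMatrix(psi=pd.DataFrame(x, index=idx, columns=samples),
                    totals=pd.DataFrame(100, index=[f"g{i}" for i in
                                                    range(x.shape[0])],
                                        columns=samples),
                    min_total=10)
    groups = {s: ("A" if s.startswith("A") else "B") for s in samples}
    return psi, groups


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def test_pooled_t_textbook_example():
    """With d0 forced to 0 the statistic is the ordinary pooled two-sample t:
    groups (0.1,0.2,0.3) vs (0.4,0.5,0.6) give |t| = 0.3/sqrt(0.01*2/3)."""
    x = np.array([[0.1, 0.2, 0.3, 0.4, 0.5, 0.6]])
    psi, groups = _psi_matrix(x, 3, 3)
    fit = diff.fit_moderated_t(psi, groups, contrast=("A", "B"),
                               exclude_reference=False, d0_override=0)
    expected = 0.3 / math.sqrt(0.01 * (2 / 3))
    assert np.isclose(fit.table["t"].iloc[0], expected, atol=1e-12)
    assert np.isclose(fit.table["delta_psi"].iloc[0], 0.3)


def test_pooled_t_matches_scipy_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(100):
        k1, k2 = rng.integers(2, 6, size=2)
        x = rng.random((rng.integers(3, 12), k1 + k2))
        psi, groups = _psi_matrix(x, k1, k2)
        fit = diff.fit_moderated_t(psi, groups, contrast=("A", "B"),
                                   exclude_reference=False, d0_override=0)
        ref = stats.ttest_ind(x[:, k1:], x[:, :k1], axis=1, equal_var=True)
        assert np.allclose(fit.table["t"], ref.statistic, atol=1e-10)
        assert np.allclose(fit.table["p"], ref.pvalue, atol=1e-10)


def test_infinite_prior_pools_all_variances():
    rng = np.random.default_rng(2)
    x = rng.random((40, 6))
    psi, groups = _psi_matrix(x, 3, 3)
    fit = diff.fit_moderated_t(psi, groups, contrast=("A", "B"),
                               exclude_reference=False,
                               d0_override=math.inf)
    assert np.allclose(fit.table["s2_post"], fit.s0sq)


def test_posterior_variance_between_obs_and_prior():
    rng = np.random.default_rng(3)
    x = rng.random((60, 6))
    psi, groups = _psi_matrix(x, 3, 3)
    fit = diff.fit_moderated_t(psi, groups, contrast=("A", "B"),
                               exclude_reference=False)
    lo = np.minimum(fit.table["s2"], fit.s0sq)
    hi = np.maximum(fit.table["s2"], fit.s0sq)
    assert ((fit.table["s2_post"] >= lo - 1e-15)
            & (fit.table["s2_post"] <= hi + 1e-15)).all()


def test_skips_events_with_single_observation():
    x = np.array([[0.1, np.nan, np.nan, 0.4, 0.5, 0.6],
                  [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]])
    psi, groups = _psi_matrix(x, 3, 3)
    fit = diff.fit_moderated_t(psi, groups, contrast=("A", "B"),
                               exclude_reference=False)
    assert fit.n_skipped == 1 and fit.n_tested == 1
    assert np.isnan(fit.table["t"].iloc[0])


def test_zero_spread_gives_infinite_d0(caplog):
    x = np.tile(np.array([[0.2, 0.2, 0.2, 0.4, 0.4, 0.4]]), (5, 1))
    psi, groups = _psi_matrix(x, 3, 3)
    fit = diff.fit_moderated_t(psi, groups, contrast=("A", "B"),
                               exclude_reference=False)
    assert math.isinf(fit.d0)
    assert np.allclose(fit.table["s2_post"], fit.s0sq)


def test_trigamma_inverse_inverts():
    for y in [1e-5, 0.01, 0.2, 1.0, 5.0, 100.0, 1e6]:
        x = diff.trigamma_inverse(y)
        assert np.isclose(float(special.polygamma(1, x)), y, rtol=1e-6)


def test_prior_recovery_from_hierarchical_draws():
    """s2 drawn from the scaled inverse-chi-square hierarchy are summarised by
    hyperparameters close to the generating ones."""
    rng = np.random.default_rng(9)
    d0_true, s0_true, dg = 8.0, 0.04, 4.0
    n = 20000
    s2_prior = d0_true * s0_true / rng.chisquare(d0_true, n)
    s2 = s2_prior * rng.chisquare(dg, n) / dg
    d0, s0 = diff.estimate_prior(s2, np.full(n, dg))
    assert abs(d0 - d0_true) / d0_true < 0.1
    assert abs(s0 - s0_true) / s0_true < 0.05


def test_moderated_t_matches_limma():
    """Independent cross-check of the full moderated pipeline (prior
    estimation, posterior variances, t, p) against limma's eBayes."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the limma cross-check")
    rng = np.random.default_rng(0)
    n, k = 50, 3
    scale = rng.gamma(2.0, 0.05, size=n)
    x = np.clip(0.5 + rng.normal(0, scale[:, None], size=(n, 2 * k)), 0, 1)
    psi, groups = _psi_matrix(x, k, k)
    fit = diff.fit_moderated_t(psi, groups, contrast=("A", "B"),
                               exclude_reference=False)
    script = (
        "suppressMessages(library(limma));"
        "m <- matrix(scan('stdin', quiet=TRUE), ncol=%d, byrow=TRUE);"
        "design <- cbind(1, c(rep(0,%d), rep(1,%d)));"
        "f <- eBayes(lmFit(m, design));"
        "cat(f$df.prior, f$s2.prior, f$t[,2], sep='\\n')" % (2 * k, k, k))
    out = subprocess.run(["Rscript", "-e", script],
                         input="\n".join(" ".join(map(str, row)) for row in x),
                         capture_output=True, text=True, check=True)
    vals = [float(v) for v in out.stdout.split()]
    d0_l, s0_l, t_l = vals[0], vals[1], np.array(vals[2:])
    assert np.isclose(fit.d0, d0_l, rtol=1e-6)
    assert np.isclose(fit.s0sq, s0_l, rtol=1e-6)
    assert np.allclose(fit.table["t"].to_numpy(), t_l, atol=1e-8)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def _bh_brute(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        q[i] = val
        prev = val
    return q


def test_bh_examples():
    assert np.allclose(ag.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert np.allclose(ag.bh_adjust([0.005, 0.05, 0.5]), [0.015, 0.075, 0.5])
    assert np.allclose(ag.bh_adjust([0.2]), [0.2])


def test_bh_matches_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(100):
        p = rng.random(rng.integers(1, 40))
        assert np.allclose(ag.bh_adjust(p), _bh_brute(p), atol=1e-12)


def test_bh_permutation_invariance():
    rng = np.random.default_rng(6)
    p = rng.random(25)
    perm = rng.permutation(25)
    q = ag.bh_adjust(p)
    q_perm = ag.bh_adjust(p[perm])
    inv = np.empty(25, dtype=int)
    inv[perm] = np.arange(25)
    assert np.allclose(q, q_perm[inv], atol=1e-15)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=1, max_size=40))
def test_bh_bounds_and_dominance(p_list):
    """q-values never fall below their p-values and never exceed 1."""
    p = np.array(p_list)
    q = ag.bh_adjust(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()


def test_bh_validation_and_monotonicity():
    with pytest.raises(ValueError):
        ag.bh_adjust([0.5, 1.2])
    rng = np.random.default_rng(7)
    p = rng.random(50)
    q = ag.bh_adjust(p)
    assert (q >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _toy_case(strand: str, donor: int, canon_acc: int, cryp_acc: int,
              annotated_cryptic: bool = False):
    """Two junctions sharing a donor, the cryptic shifted on the acceptor."""
    if strand == "+":
        rows = [("chr1", strand, donor, canon_acc, 1, 90, 90, 90, 60, 60, 60),
                ("chr1", strand, donor, cryp_acc, 0, 2, 2, 2, 32, 32, 32)]
    else:
        rows = [("chr1", strand, canon_acc, donor, 1, 90, 90, 90, 60, 60, 60),
                ("chr1", strand, cryp_acc, donor, 0, 2, 2, 2, 32, 32, 32)]
    samples = ["WT1", "WT2", "WT3", "MUT1", "MUT2", "MUT3"]
    junctions = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end",
                                            "annotated", *samples])
    groups = {s: s[:-1] for s in samples}
    # a plausible annotation: one gene spanning the region with exons abutting
    # the canonical boundaries
    if strand == "+":
        exons = ((donor - 100, donor), (canon_acc, canon_acc + 100))
        alt_exons = ((donor - 100, donor), (cryp_acc, cryp_acc + 100))
    else:
        exons = ((canon_acc - 100, canon_acc), (donor, donor + 100))
        alt_exons = ((cryp_acc - 100, cryp_acc), (donor, donor + 100))
    isoforms = [ag.IsoformModel("gX", "gX.t1", "chr1", strand,
                                tuple(sorted(exons)))]
    if annotated_cryptic:
        # the cryptic acceptor is a known alternative exon start on a
        # second isoform
        isoforms.append(ag.IsoformModel("gX", "gX.t2", "chr1", strand,
                                        tuple(sorted(alt_exons))))
    members = ag.group_by_boundary(junctions)
    psi = ag.compute_psi(members)
    fit = diff.fit_moderated_t(psi, groups)
    return diff.classify_events(
        fit, members, diff.AnnotationIndex.from_isoforms(isoforms), psi,
        groups)


def test_alt3_plus_strand_distance():
    ev = _toy_case("+", 1000, 1500, 1482)
    assert len(ev) == 1
    row = ev.iloc[0]
    assert row["event_class"] == "alt-3ss"
    assert row["distance_nt"] == 18
    assert row["novel"]
    assert row["delta_psi"] > 0.2
    assert row["gene_id"] == "gX"


def test_alt3_minus_strand_distance():
    """On the minus strand the aberrant acceptor at canonical+18 genomic is 18
    nt transcriptionally upstream."""
    ev = _toy_case("-", 2000, 1500, 1518)
    assert len(ev) == 1
    row = ev.iloc[0]
    assert row["event_class"] == "alt-3ss"
    assert row["distance_nt"] == 18
    assert row["novel"]


def test_annotated_alternative_acceptor_not_novel():
    ev = _toy_case("+", 1000, 1500, 1482, annotated_cryptic=True)
    assert len(ev) == 1
    assert not ev.iloc[0]["novel"]


def test_retention_member_classified():
    samples = ["WT1", "WT2", "WT3", "MUT1", "MUT2", "MUT3"]
    junctions = pd.DataFrame(
        [("chr1", "+", 1000, 1500, 1, 95, 95, 95, 60, 60, 60)],
        columns=["chrom", "strand", "start", "end", "annotated", *samples])
    cov = pd.DataFrame([("chr1", 1000, "donor", s, c) for s, c in
                        zip(samples, [5, 5, 5, 40, 40, 40])],
                       columns=["chrom", "pos", "side", "sample", "count"])
    groups = {s: s[:-1] for s in samples}
    members = ag.group_by_boundary(junctions, cov)
    psi = ag.compute_psi(members)
    fit = diff.fit_moderated_t(psi, groups)
    ev = diff.classify_events(fit, members,
                              diff.AnnotationIndex.from_isoforms([]), psi,
                              groups)
    assert len(ev) == 1
    assert ev.iloc[0]["event_class"] == "intron-retention"


def test_cassette_exon_classified():
    """A junction skipping an entire annotated exon is a cassette event."""
    samples = ["WT1", "WT2", "WT3", "MUT1", "MUT2", "MUT3"]
    junctions = pd.DataFrame(
        [("chr1", "+", 1000, 1200, 1, 90, 90, 90, 55, 55, 55),
         ("chr1", "+", 1000, 1500, 0, 2, 2, 2, 37, 37, 37)],
        columns=["chrom", "strand", "start", "end", "annotated", *samples])
    iso = ag.IsoformModel("gY", "gY.t1", "chr1", "+",
                          ((900, 1000), (1200, 1300), (1500, 1600)))
    groups = {s: s[:-1] for s in samples}
    members = ag.group_by_boundary(junctions)
    psi = ag.compute_psi(members)
    fit = diff.fit_moderated_t(psi, groups)
    ev = diff.classify_events(fit, members,
                              diff.AnnotationIndex.from_isoforms([iso]), psi,
                              groups)
    assert len(ev) == 1
    assert ev.iloc[0]["event_class"] == "cassette-exon"


def test_effect_floor_filters_small_shifts():
    ev = _toy_case("+", 1000, 1500, 1482)
    # same data, but an effect floor above the true shift suppresses the call
    samples = ["WT1", "WT2", "WT3", "MUT1", "MUT2", "MUT3"]
    junctions = pd.DataFrame(
        [("chr1", "+", 1000, 1500, 1, 90, 90, 90, 60, 60, 60),
         ("chr1", "+", 1000, 1482, 0, 2, 2, 2, 32, 32, 32)],
        columns=["chrom", "strand", "start", "end", "annotated", *samples])
    groups = {s: s[:-1] for s in samples}
    members = ag.group_by_boundary(junctions)
    psi = ag.compute_psi(members)
    fit = diff.fit_moderated_t(psi, groups)
    ev2 = diff.classify_events(fit, members,
                               diff.AnnotationIndex.from_isoforms([]), psi,
                               groups, min_abs_delta_psi=0.9)
    assert len(ev) == 1 and len(ev2) == 0
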
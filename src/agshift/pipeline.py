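"""End-to-end orchestration: PSI -> differential splicing -> motifs -> NMD ->
conservation, from in-memory objects or from files via a flat TOML config.

Stages are idempotent and individually re-runnable from persisted
intermediates; identical config + inputs give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import conservation, diff, io, motifs, nmd
from .models import IsoformModel
from .psi import PsiMatrix, compute_psi, group_by_boundary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full file-based run."""

    genome: str
    annotation: str
    samples: str                 # sample sheet TSV: sample, group, sj_path
    coverage: str | None = None
    expression: str | None = None
    orthology: str | None = None
    out: str = "agshift_out"
    contrast: tuple[str, str] = ("WT", "MUT")
    min_total: int = 10
    q_max: float = 0.05
    min_abs_delta_psi: float = 0.1
    nmd_distance: int = 50
    ag_window: tuple[int, int] = conservation.AG_WINDOW
    bp_window: tuple[int, int] = conservation.BP_WINDOW
    background_max: int = 100
    seed: int = 0
    stages: tuple[str, ...] = ("psi", "diff", "motifs", "nmd", "conserve")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("contrast", "ag_window", "bp_window", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if len(self.contrast) != 2 or self.contrast[0] == self.contrast[1]:
            raise ValueError("contrast must name two distinct group labels")
        if self.min_total < 1:
            raise ValueError("min_total must be >= 1")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must lie in (0, 1]")
        if not 0 <= self.min_abs_delta_psi <= 1:
            raise ValueError("min_abs_delta_psi must lie in [0, 1]")
        if self.nmd_distance < 0:
            raise ValueError("nmd_distance must be >= 0")
        for p in (self.genome, self.annotation, self.samples):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if "conserve" in self.stages and not self.orthology:
            raise ValueError("conserve stage requested but no orthology path")
        if "nmd" in self.stages and not self.expression:
            raise ValueError("nmd stage requested but no expression path")


@dataclass
class RunResult:
    """In-memory results of a full run."""

    psi: PsiMatrix
    members: pd.DataFrame
    fit: diff.ModeratedFit
    events: pd.DataFrame
    contexts: list = field(default_factory=list)
    distance_hist: pd.DataFrame | None = None
    motif_matrices: dict | None = None
    enrichment: motifs.EnrichmentResult | None = None
    nmd_calls: pd.DataFrame | None = None
    association: dict | None = None
    cascade: conservation.CascadeReport | None = None

    def summary(self) -> dict:
        out: dict = {
            "n_groups": int(self.psi.totals.shape[0]),
            "n_members_tested": self.fit.n_tested,
            "fit": self.fit.summary(),
            "n_events": int(len(self.events)),
            "event_class_tally": {
                k: int(v) for k, v in
                self.events["event_class"].value_counts().sort_index().items()},
            "n_novel": int(self.events["novel"].sum()) if len(self.events) else 0,
        }
        if self.distance_hist is not None:
            ab = self.distance_hist[self.distance_hist["source"] == "aberrant"]
            out["aberrant_distance_histogram"] = {
                int(d): int(c) for d, c in zip(ab["distance"], ab["count"])}
        if self.enrichment is not None:
            out["adenine_enrichment"] = self.enrichment.to_dict()
        if self.nmd_calls is not None and len(self.nmd_calls):
            callable_ = self.nmd_calls[self.nmd_calls["n_isoforms"] > 0]
            out["nmd"] = {
                "n_callable": int(len(callable_)),
                "n_predicted": int(callable_["nmd_predicted"].sum()),
                "fraction_predicted": (
                    float(callable_["nmd_predicted"].mean())
                    if len(callable_) else float("nan")),
            }
        if self.association is not None:
            out["expression_association"] = self.association
        if self.cascade is not None:
            out["conservation_cascade"] = self.cascade.to_dict()
        return out


def analyze(junctions: pd.DataFrame,
            coverage: pd.DataFrame | None,
            sample_groups: Mapping[str, str],
            genome: Mapping[str, str] | None = None,
            isoforms: Sequence[IsoformModel] | None = None,
            expression: pd.DataFrame | None = None,
            orthology: pd.DataFrame | None = None,
            event_id_map: Mapping[str, str] | None = None,
            contrast: tuple[str, str] = ("WT", "MUT"),
            min_total: int = 10, q_max: float = 0.05,
            min_abs_delta_psi: float = 0.1, nmd_distance: int = 50,
            background_max: int = 100,
            run_motifs: bool = True) -> RunResult:
    """Run the analysis stages on in-memory inputs.

    ``junctions`` is a combined per-sample count frame
    (:func:`agshift.io.combine_sj_tables` layout).  Optional inputs switch the
    downstream stages on: annotation+genome enable classification context,
    motifs and NMD; ``expression`` the NMD/expression association; and
    ``orthology`` the conservation cascade.  ``event_id_map`` maps this run's
    event ids (``anchor_id|member_id``) to the orthology table's ids when they
    differ.
    """
    members = group_by_boundary(junctions, coverage)
    psi = compute_psi(members, min_total=min_total)
    fit = diff.fit_moderated_t(psi, dict(sample_groups), contrast=contrast)

    annotation = diff.AnnotationIndex.from_isoforms(list(isoforms or []))
    events = diff.classify_events(fit, members, annotation, psi,
                                  dict(sample_groups), contrast=contrast,
                                  q_max=q_max,
                                  min_abs_delta_psi=min_abs_delta_psi)
    result = RunResult(psi=psi, members=members, fit=fit, events=events)

    if genome is not None and run_motifs:
        result.contexts = motifs.contexts_for_events(genome, events)
        result.distance_hist = motifs.distance_histogram(
            events, genome, isoforms, max_dist=background_max)
        if result.contexts:
            result.motif_matrices = motifs.motif_frequency_matrix(result.contexts)
            sources = {c.source for c in result.contexts}
            if {"aberrant", "canonical"} <= sources:
                result.enrichment = motifs.adenine_enrichment(result.contexts)

    if genome is not None and isoforms:
        result.nmd_calls = nmd.call_gene_nmd(events, list(isoforms), genome,
                                             nmd_distance=nmd_distance)
        if expression is not None and len(result.nmd_calls):
            mutant = [s for s, g in sample_groups.items() if g == contrast[1]]
            callable_ = result.nmd_calls[result.nmd_calls["n_isoforms"] > 0]
            if (callable_["nmd_predicted"].any()
                    and (~callable_["nmd_predicted"]).any()):
                result.association = nmd.expression_association(
                    result.nmd_calls, expression, mutant)

    if orthology is not None and len(events):
        ids = [f"{a}|{m}" for a, m in zip(events["anchor_id"],
                                          events["member_id"])]
        if event_id_map is not None:
            ids = [event_id_map.get(i, i) for i in ids]
        known = set(orthology["event_id"])
        ids = sorted(set(i for i in ids if i in known))
        if ids:
            result.cascade = conservation.run_cascade(ids, orthology)
    return result


# ---------------------------------------------------------------------------
# file-based run
# ---------------------------------------------------------------------------

def run_all(config: RunConfig) -> dict:
    """Execute the configured stages from files and write per-stage outputs.

    Returns the summary dict (also written as ``summary.json``).  Any stage
    failure aborts with the stage name in the exception message.
    """
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)

    sheet = io.read_samples_table(config.samples)
    groups = dict(zip(sheet["sample"], sheet["group"]))
    levels = set(groups.values())
    if levels != set(config.contrast):
        raise ValueError(f"sample sheet groups {sorted(levels)} do not match "
                         f"contrast {config.contrast}")

    stage = "inputs"
    try:
        tables = {row["sample"]: io.read_sj_table(row["sj_path"])
                  for _, row in sheet.iterrows()}
        junctions = io.combine_sj_tables(tables)
        coverage = (io.read_coverage_table(config.coverage)
                    if config.coverage else None)
        genome = io.read_fasta(config.genome)
        isoforms = io.read_gtf(config.annotation)
        expression = (io.read_expression_table(config.expression)
                      if config.expression else None)
        orthology = (io.read_orthology_table(config.orthology)
                     if config.orthology else None)

        stage = "analysis"
        result = analyze(
            junctions, coverage, groups, genome=genome, isoforms=isoforms,
            expression=expression if "nmd" in config.stages else None,
            orthology=orthology if "conserve" in config.stages else None,
            contrast=config.contrast, min_total=config.min_total,
            q_max=config.q_max, min_abs_delta_psi=config.min_abs_delta_psi,
            nmd_distance=config.nmd_distance,
            background_max=config.background_max,
            run_motifs="motifs" in config.stages)

        stage = "outputs"
        result.psi.long().to_csv(outdir / "psi_long.tsv", sep="\t", index=False)
        result.fit.table.reset_index().to_csv(outdir / "moderated_fit.tsv",
                                              sep="\t", index=False)
        (outdir / "fit_summary.json").write_text(
            json.dumps(result.fit.summary(), indent=1, sort_keys=True))
        result.events.to_csv(outdir / "events.tsv", sep="\t", index=False)
        if result.distance_hist is not None:
            result.distance_hist.to_csv(outdir / "distance_histogram.tsv",
                                        sep="\t", index=False)
        if result.motif_matrices:
            for source, mat in result.motif_matrices.items():
                mat.to_csv(outdir / f"motif_freq_{source}.tsv", sep="\t")
        if result.enrichment is not None:
            (outdir / "adenine_enrichment.json").write_text(
                json.dumps(result.enrichment.to_dict(), indent=1, sort_keys=True))
        if result.nmd_calls is not None:
            result.nmd_calls.to_csv(outdir / "nmd_calls.tsv", sep="\t",
                                    index=False)
        if result.association is not None:
            (outdir / "expression_association.json").write_text(
                json.dumps(result.association, indent=1, sort_keys=True))
        if result.cascade is not None:
            result.cascade.flags.to_csv(outdir / "cascade_flags.tsv", sep="\t",
                                        index=False)
            (outdir / "cascade_report.json").write_text(
                json.dumps(result.cascade.to_dict(), indent=1, sort_keys=True))

        summary = result.summary()
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        return summary
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
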
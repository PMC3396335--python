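"""Pipeline configuration and end-to-end orchestration.

Stage order: median normalization -> de-waving -> MAD QC -> CBS
segmentation -> mode normalization -> mixture calling -> region
reduction -> group comparison (frequencies, chi-square + FDR,
genome-wide odds) -> weighted clustering -> survival statistics.
Every results JSON embeds the full configuration, package version and
seeds for provenance.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as aio
from .calling import call_profiles, fit_call_mixture, mode_normalize
from .clinical import CohortTable
from .clustering import ClusterResult, call_similarity, cluster_samples, to_newick
from .group_compare import genome_wide_odds_test, region_chisq_fdr, region_frequencies
from .preprocess import dewave, drop_excluded, drop_sparse_probes, mad_qc, median_normalize
from .profiles import AcghProfileSet
from .regions import reduce_regions, region_weights
from .segmentation import CbsParams, segment_profileset
from .survival import km_estimate, logrank, pearson_chi2_2x2, rmst

log = logging.getLogger("acghcall")

STAGES = (
    "normalize", "dewave", "qc", "segment", "call", "regions",
    "compare", "cluster", "survival",
)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with documented defaults.

    Unknown keys are rejected when loading from a mapping or YAML file.
    """

    # preprocessing
    mad_threshold: float = 0.50
    qc_chromosome: int = 2
    qc_arm: str = "q"
    dewave_span: float = 0.3
    max_probe_missing: float = 0.2
    # segmentation
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 10_000
    cbs_min_width: int = 2
    cbs_prune_sd: float = 1.5
    # calling
    call_prob_cutoff: float = 0.5
    mixture_init_means: tuple = (-0.45, 0.0, 0.3, 0.9)
    # regions / testing
    region_threshold: float = 0.01
    fdr_level: float = 0.15
    odds_n_perm: int = 10_000
    # clustering / survival
    cluster_linkage: str = "average"
    rmst_tau: float | None = None   # None = largest observed time per group
    # io / misc
    seed: int = 0
    input_matrix: str | None = None
    input_clinical: str | None = None
    out_dir: str = "results"
    stages: tuple = STAGES

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} is not a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mixture_init_means"] = list(self.mixture_init_means)
        d["stages"] = list(self.stages)
        return d


def survival_report(
    clinical: CohortTable,
    by: str = "cluster",
    tau: float | None = None,
) -> dict:
    """KM + RMST per group and the Mantel-Cox log-rank test on OS.

    ``by`` is 'cluster', 'stage_group', or 'grade1_vs_23'.
    """
    if by == "cluster":
        groups = {r.sample_id: r.cluster for r in clinical
                  if r.cluster in ("A", "B")}
    elif by == "stage_group":
        groups = {r.sample_id: r.stage_group for r in clinical}
    elif by == "grade1_vs_23":
        groups = {r.sample_id: ("grade1" if r.grade == 1 else "grade2-3")
                  for r in clinical}
    else:
        raise ValueError(f"unknown grouping {by!r}")
    recs = [r for r in clinical if r.sample_id in groups]
    times = [r.os_months for r in recs]
    events = [r.dead for r in recs]
    labels = [groups[r.sample_id] for r in recs]
    names = sorted(set(labels))
    out = {"by": by, "groups": {}}
    for g in names:
        t = [tt for tt, l in zip(times, labels) if l == g]
        e = [ee for ee, l in zip(events, labels) if l == g]
        curve = km_estimate(t, e)
        est = rmst(curve, tau)
        out["groups"][g] = {
            "n": len(t),
            "events": int(sum(e)),
            "km_times": curve.event_times,
            "km_survival": curve.survival,
            "rmst": {"mean": est.mean, "se": est.se,
                     "ci95": list(est.ci95), "tau": est.tau},
        }
    lr = logrank(times, events, labels)
    out["logrank"] = {"statistic": lr.statistic, "df": lr.df, "p": lr.p}
    return out


def run_pipeline(
    config: PipelineConfig,
    profiles: AcghProfileSet | None = None,
    clinical: CohortTable | None = None,
    pairing: dict[str, str] | None = None,
    write: bool = True,
) -> dict:
    """Run the configured stages; return (and optionally write) all results.

    Inputs may be given in memory or through ``config.input_matrix`` /
    ``config.input_clinical``.  Stage errors abort with the stage name
    attached.
    """
    cfg = config
    if profiles is None:
        if cfg.input_matrix is None:
            raise ValueError("no probe matrix: pass `profiles` or set input_matrix")
        profiles = aio.read_probe_matrix(cfg.input_matrix)
    if clinical is None and cfg.input_clinical is not None:
        clinical = CohortTable.read_tsv(cfg.input_clinical)
    if clinical is not None and not profiles.stage_labels:
        profiles.stage_labels.update(
            {r.sample_id: r.stage_group for r in clinical}
        )

    out_dir = Path(cfg.out_dir)
    if write:
        out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "config": cfg.to_dict(),
        "version": __version__,
        "seed": cfg.seed,
        "stage_seconds": {},
    }
    bundle: dict = {"results": results}
    stages = tuple(cfg.stages)

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                log.info("stage %s: start", stage)
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                results["stage_seconds"][stage] = round(dt, 3)
                if exc is not None:
                    log.error("stage %s: failed after %.1fs: %s", stage, dt, exc)
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
                log.info("stage %s: done in %.1fs", stage, dt)
                return False
        return _T()

    current = profiles
    if "normalize" in stages:
        with timed("normalize"):
            current = median_normalize(drop_sparse_probes(current, cfg.max_probe_missing))
    if "dewave" in stages:
        with timed("dewave"):
            current = dewave(current, span=cfg.dewave_span)
    if "qc" in stages:
        with timed("qc"):
            from .preprocess import DEFAULT_CENTROMERES_BP
            centromeres = dict(DEFAULT_CENTROMERES_BP)
            try:
                sl = current.chromosome_slice(cfg.qc_chromosome)
                pos = current.probes["position"].to_numpy()[sl]
                if centromeres.get(cfg.qc_chromosome, 0) >= pos.max():
                    # grid does not reach the genomic centromere (e.g. a
                    # scaled-down synthetic grid): split the arm mid-span
                    centromeres[cfg.qc_chromosome] = int(np.median(pos))
            except KeyError:
                pass  # mad_qc reports the missing chromosome itself
            report = mad_qc(
                current, qc_arm=(cfg.qc_chromosome, cfg.qc_arm),
                threshold=cfg.mad_threshold, pairing=pairing,
                centromeres=centromeres,
            )
            results["qc"] = report.to_dict()
            current = drop_excluded(current, report)
            if write:
                aio.write_json(report.to_dict(), out_dir / "qc.json")
    bundle["preprocessed"] = current

    segmented = None
    if "segment" in stages:
        with timed("segment"):
            params = CbsParams(
                alpha=cfg.cbs_alpha, n_perm=cfg.cbs_n_perm,
                min_width=cfg.cbs_min_width, prune_sd=cfg.cbs_prune_sd,
                seed=cfg.seed,
            )
            segmented = segment_profileset(current, params)
            if write:
                aio.write_segments(segmented, current, out_dir / "segments.tsv")
        bundle["segmented"] = segmented

    callmat = None
    if "call" in stages:
        with timed("call"):
            segmented = [mode_normalize(sp) for sp in segmented]
            model = fit_call_mixture(segmented, init_means=tuple(cfg.mixture_init_means))
            callmat = call_profiles(model, segmented, current.probes,
                                    prob_cutoff=cfg.call_prob_cutoff)
            results["mixture"] = {
                "means": model.means, "sds": model.sds, "weights": model.weights,
                "degraded": model.degraded, "converged": model.converged,
                "n_iterations": len(model.loglik_trace) - 1,
            }
            if write:
                aio.write_calls(callmat, out_dir / "calls.tsv")
        bundle["calls"] = callmat

    regioncalls = None
    if "regions" in stages:
        with timed("regions"):
            regioncalls = reduce_regions(callmat, threshold=cfg.region_threshold)
            results["regions"] = {
                "n_regions": regioncalls.n_regions,
                "achieved_loss": regioncalls.achieved_loss,
            }
            if write:
                aio.write_regions(regioncalls, out_dir / "regions.tsv")
        bundle["regions"] = regioncalls

    if "compare" in stages:
        with timed("compare"):
            groups = {s: current.stage_of(s) for s in regioncalls.samples}
            freq = region_frequencies(regioncalls, groups)
            tests = region_chisq_fdr(regioncalls, groups, fdr_level=cfg.fdr_level)
            odds = genome_wide_odds_test(
                regioncalls, groups, pairing=pairing,
                n_perm=cfg.odds_n_perm, seed=cfg.seed,
            )
            results["compare"] = {
                "fdr_level": cfg.fdr_level,
                "n_discoveries": int(tests.discovery.sum()),
                "frequencies": {
                    g: {"gain": freq.gain[g], "loss": freq.loss[g]}
                    for g in freq.groups
                },
                "chisq": {"statistic": tests.statistic, "p": tests.p, "q": tests.q,
                          "discovery": tests.discovery},
                "genome_wide_odds": {
                    "statistic": odds.statistic, "p": odds.p,
                    "n_permutations": odds.n_permutations,
                    "exhaustive": odds.exhaustive, "paired": odds.paired,
                    "groups": list(odds.groups), "seed": odds.seed,
                },
            }
        bundle["compare"] = results["compare"]

    cluster_result: ClusterResult | None = None
    if "cluster" in stages:
        with timed("cluster"):
            sim = call_similarity(regioncalls, region_weights(regioncalls))
            cluster_result = cluster_samples(sim, regioncalls.samples,
                                             linkage=cfg.cluster_linkage)
            results["cluster"] = {
                "labels": cluster_result.labels_k2,
                "linkage": cfg.cluster_linkage,
                "newick": to_newick(cluster_result),
            }
            if write:
                (out_dir / "dendrogram.nwk").write_text(
                    results["cluster"]["newick"] + "\n")
                labels_df = [(s, cluster_result.labels_k2[s])
                             for s in regioncalls.samples]
                import pandas as pd
                pd.DataFrame(labels_df, columns=["sample", "cluster"]).to_csv(
                    out_dir / "clusters.tsv", sep="\t", index=False)
        bundle["cluster"] = cluster_result

    if "survival" in stages:
        with timed("survival"):
            if clinical is None:
                raise ValueError("survival stage needs a clinical table")
            if cluster_result is not None:
                relabeled = []
                for r in clinical:
                    lab = cluster_result.labels_k2.get(r.sample_id, r.cluster)
                    relabeled.append(type(r)(**{**asdict_record(r), "cluster": lab}))
                clinical = CohortTable(relabeled)
            surv = {
                "cluster": survival_report(clinical, "cluster", cfg.rmst_tau),
                "stage_group": survival_report(clinical, "stage_group", cfg.rmst_tau),
                "grade1_vs_23": survival_report(clinical, "grade1_vs_23", cfg.rmst_tau),
            }
            ab = [[0, 0], [0, 0]]
            for r in clinical:
                if r.cluster in ("A", "B"):
                    i = 0 if r.cluster == "A" else 1
                    j = 0 if r.stage_group == "early" else 1
                    ab[i][j] += 1
            if all(sum(row) for row in ab) and all(sum(col) for col in zip(*ab)):
                chi = pearson_chi2_2x2(np.array(ab))
                surv["cluster_by_stage_chi2"] = {
                    "table": chi.table, "statistic": chi.statistic, "p": chi.p,
                }
            results["survival"] = surv
        bundle["survival"] = results["survival"]

    if write:
        aio.write_json(results, out_dir / "results.json")
    return bundle


def asdict_record(r) -> dict:
    return {
        "sample_id": r.sample_id, "age": r.age, "stage_group": r.stage_group,
        "figo_stage": r.figo_stage, "histology": r.histology, "grade": r.grade,
        "chemo": r.chemo, "staging_quality": r.staging_quality,
        "status": r.status, "os_months": r.os_months,
        "progression": r.progression, "pfs_months": r.pfs_months,
        "cluster": r.cluster,
    }
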
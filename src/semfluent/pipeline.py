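"""End-to-end analysis pipeline.

Stages, in order: clean the fluency table, estimate one semantic network per
participant (censored-walk MAP), compute graph statistics, and run the
default-Bayes-factor test battery (group comparisons on creativity;
correlations of creativity with each network statistic, with mean items
listed, and with intelligence — each both two-sided and with the
literature-motivated directional prior).  Every stage writes its outputs
before the next starts; a rerun with an unchanged configuration reuses
stage outputs via content hashing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as fio
from .bayes import (
    CorrSummary,
    PriorSettings,
    jzs_ttest_bf,
    pearson_bf,
    results_table,
    summary_to_t,
)
from .netstats import MetricSettings, compute_all
from .uinvite import PriorSpec, SearchParams, estimate_network

logger = logging.getLogger("semfluent")

__all__ = ["RunConfig", "ResultsBundle", "run_pipeline", "report_table"]

# directional priors used alongside the two-sided test, per the hypotheses
# motivating each correlation (more creative: shorter paths, higher
# clustering, lower modularity, lower small-worldness, more items, higher
# intelligence)
CORRELATION_DIRECTIONS = {
    "aspl": "negative",
    "clustering": "positive",
    "modularity": "negative",
    "small_world": "negative",
    "mean_items": "positive",
    "intelligence": "positive",
}


@dataclass
class RunConfig:
    fluency_path: str
    score_path: str
    out_dir: str
    lexicon_path: str | None = None       # None: bundled toy lexicon
    reference_path: str | None = None     # None: bundled toy reference network
    p_present: float = 2.0 / 3.0
    p_absent: float = 2.0 / 5.0
    p_unknown: float = 1.0 / 2.0
    max_sweeps: int = 100
    tolerance: float = 1e-12
    modularity_restarts: int = 10
    n_random: int = 100
    clustering_variant: str = "average"
    run_group_tests: bool = True
    run_correlation_tests: bool = True
    master_seed: int = 0
    resume: bool = True


@dataclass
class ResultsBundle:
    networks: dict[str, nx.Graph]
    metrics: pd.DataFrame
    tests: pd.DataFrame | None
    cleaning: fio.CleaningReport
    manifest: dict = field(default_factory=dict)


def _hash_parts(*parts) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, (str, int, float, bool, type(None))):
            h.update(repr(part).encode())
        elif isinstance(part, bytes):
            h.update(part)
        else:
            h.update(json.dumps(part, sort_keys=True, default=str).encode())
    return h.hexdigest()


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_manifest(out: Path) -> dict:
    p = out / "manifest.json"
    if p.exists():
        return json.loads(p.read_text())
    return {}


def _save_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: RunConfig, until: str = "tests") -> ResultsBundle:
    """Run clean -> estimate -> metrics -> tests, writing each stage's files.

    ``until`` stops the pipeline after the named stage ("clean",
    "estimate", "metrics" or "tests").  Reruns with identical configuration
    and inputs are byte-identical; with ``resume=True`` unchanged stages are
    loaded from disk instead of recomputed.  Participants whose estimation
    or metrics fail are excluded from the test battery with a logged
    reason, never silently.
    """
    if until not in ("clean", "estimate", "metrics", "tests"):
        raise ValueError(f"unknown stage {until!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _load_manifest(out) if config.resume else {}
    manifest.setdefault("stages", {})
    manifest["config"] = asdict(config)

    lexicon = (
        fio.read_lexicon(config.lexicon_path)
        if config.lexicon_path
        else fio.bundled_lexicon()
    )
    reference = (
        fio.read_edge_list(config.reference_path)
        if config.reference_path
        else fio.bundled_reference_network()
    )

    # ---- stage 1: clean ----------------------------------------------------
    clean_hash = _hash_parts(
        "clean", _file_digest(config.fluency_path), sorted(lexicon)
    )
    clean_csv = out / "cleaned_fluency.csv"
    clean_json = out / "cleaning_report.json"
    if (
        config.resume
        and manifest["stages"].get("clean") == clean_hash
        and clean_csv.exists()
        and clean_json.exists()
    ):
        logger.info("clean: unchanged, reusing %s", clean_csv)
        cleaned_df = fio.read_fluency_table(clean_csv)
        rep = json.loads(clean_json.read_text())
        report = fio.CleaningReport(
            rep["n_responses_total"], rep["n_intrusions"], rep["n_perseverations"],
            tuple(map(tuple, rep["empty_lists"])),
        )
        lists = _lists_from_table(cleaned_df)
    else:
        table = fio.read_fluency_table(config.fluency_path)
        lists, report = fio.clean_lists(table, lexicon)
        cleaned_df = pd.DataFrame(
            [
                {"id": fl.participant_id, "listnum": fl.list_index,
                 "position": pos, "item": item}
                for fl in lists
                for pos, item in enumerate(fl.items)
            ],
            columns=["id", "listnum", "position", "item"],
        )
        fio.write_fluency_table(cleaned_df, clean_csv)
        clean_json.write_text(json.dumps({
            "n_responses_total": report.n_responses_total,
            "n_intrusions": report.n_intrusions,
            "n_perseverations": report.n_perseverations,
            "intrusion_rate": report.intrusion_rate,
            "empty_lists": [list(e) for e in report.empty_lists],
        }, indent=2))
        manifest["stages"]["clean"] = clean_hash
        _save_manifest(out, manifest)
        logger.info(
            "clean: %d responses, %d intrusions, %d perseverations",
            report.n_responses_total, report.n_intrusions, report.n_perseverations,
        )

    by_pid: dict[str, list[fio.FluencyList]] = {}
    for fl in lists:
        by_pid.setdefault(fl.participant_id, []).append(fl)
    pids = sorted(by_pid)

    if until == "clean":
        return ResultsBundle(
            networks={}, metrics=pd.DataFrame(), tests=None,
            cleaning=report, manifest=manifest,
        )

    # ---- stage 2: estimate -------------------------------------------------
    prior = PriorSpec(reference, config.p_present, config.p_absent, config.p_unknown)
    est_hash = _hash_parts(
        "estimate", manifest["stages"].get("clean"),
        config.p_present, config.p_absent, config.p_unknown,
        config.max_sweeps, config.tolerance, config.master_seed,
        sorted(tuple(sorted(e)) for e in reference.edges),
    )
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    est_json = out / "estimation_summary.json"
    networks: dict[str, nx.Graph] = {}
    failed: dict[str, str] = {}
    if (
        config.resume
        and manifest["stages"].get("estimate") == est_hash
        and est_json.exists()
    ):
        logger.info("estimate: unchanged, reusing %s", net_dir)
        summary = json.loads(est_json.read_text())
        failed = summary.get("failed", {})
        for pid in pids:
            path = net_dir / f"{pid}.tsv"
            if path.exists():
                g = fio.read_edge_list(path)
                g.add_nodes_from(summary["nodes"][pid])
                networks[pid] = g
    else:
        summary = {"seed": config.master_seed, "participants": {}, "nodes": {}, "failed": {}}
        for i, pid in enumerate(pids):
            nonempty = [fl for fl in by_pid[pid] if len(fl) > 0]
            if not nonempty:
                failed[pid] = "all lists empty after cleaning"
                logger.warning("estimate: %s skipped (%s)", pid, failed[pid])
                continue
            params = SearchParams(
                seed=int(np.random.SeedSequence([config.master_seed, i]).generate_state(1)[0] % (2**31)),
                max_sweeps=config.max_sweeps,
                tolerance=config.tolerance,
            )
            g, lp, trace = estimate_network(nonempty, prior, params)
            networks[pid] = g
            fio.write_edge_list(g, net_dir / f"{pid}.tsv")
            summary["participants"][pid] = {
                "log_posterior": lp,
                "sweeps": len(trace),
                "seed": params.seed,
            }
            summary["nodes"][pid] = sorted(g.nodes)
            logger.info("estimate: %s done (%d sweeps)", pid, len(trace))
        summary["failed"] = failed
        est_json.write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest["stages"]["estimate"] = est_hash
        _save_manifest(out, manifest)

    if until == "estimate":
        return ResultsBundle(
            networks=networks, metrics=pd.DataFrame(), tests=None,
            cleaning=report, manifest=manifest,
        )

    # ---- stage 3: metrics --------------------------------------------------
    met_hash = _hash_parts(
        "metrics", manifest["stages"].get("estimate"),
        config.modularity_restarts, config.n_random, config.clustering_variant,
        config.master_seed,
    )
    met_csv = out / "metrics.csv"
    if config.resume and manifest["stages"].get("metrics") == met_hash and met_csv.exists():
        logger.info("metrics: unchanged, reusing %s", met_csv)
        metrics = pd.read_csv(met_csv, dtype={"id": str}).set_index("id")
    else:
        counts = fio.fluency_counts(lists)
        rows = []
        settings = MetricSettings(
            seed=config.master_seed,
            modularity_restarts=config.modularity_restarts,
            n_random=config.n_random,
            clustering=config.clustering_variant,
        )
        for pid in pids:
            row = {"id": pid, "mean_items": counts.loc[pid, "mean_items"]}
            if pid in networks:
                try:
                    row.update(compute_all(networks[pid], settings).as_dict())
                except ValueError as exc:
                    failed.setdefault(pid, f"metrics failed: {exc}")
                    logger.warning("metrics: %s excluded (%s)", pid, exc)
            rows.append(row)
        metrics = pd.DataFrame(rows).set_index("id")
        metrics.to_csv(met_csv)
        # reload so fresh and resumed runs see bit-identical values (text
        # round-trip of floats can differ from the in-memory result by 1 ulp)
        metrics = pd.read_csv(met_csv, dtype={"id": str}).set_index("id")
        manifest["stages"]["metrics"] = met_hash
        _save_manifest(out, manifest)

    # ---- stage 4: tests ----------------------------------------------------
    scores = fio.read_score_table(config.score_path)
    tests = None
    if until != "metrics" and (config.run_group_tests or config.run_correlation_tests):
        tests = _test_battery(metrics, scores, config)
        tests.to_csv(out / "tests.csv", index=False)
        manifest["stages"]["tests"] = _hash_parts(
            "tests", manifest["stages"].get("metrics"), _file_digest(config.score_path),
            config.run_group_tests, config.run_correlation_tests,
        )
        _save_manifest(out, manifest)
    else:
        manifest["stages"].pop("tests", None)
        _save_manifest(out, manifest)

    return ResultsBundle(
        networks=networks, metrics=metrics, tests=tests,
        cleaning=report, manifest=manifest,
    )


def _lists_from_table(table: pd.DataFrame) -> list[fio.FluencyList]:
    out = []
    for (pid, ln), grp in table.groupby(["id", "listnum"], sort=True):
        items = tuple(grp.sort_values("position")["item"])
        out.append(fio.FluencyList(str(pid), int(ln), items))
    return out


def _group_ttest_row(name, scores, mask1, mask2, label1, label2):
    g1 = scores.loc[mask1, "creativity"]
    g2 = scores.loc[mask2, "creativity"]
    if len(g1) < 2 or len(g2) < 2 or g1.std(ddof=1) == 0 or g2.std(ddof=1) == 0:
        logger.warning("group test %s skipped (degenerate groups)", name)
        return None
    summ = summary_to_t(
        g1.mean(), g1.std(ddof=1), len(g1), g2.mean(), g2.std(ddof=1), len(g2)
    )
    res = jzs_ttest_bf(summ, PriorSettings(side="two_sided"))
    return {
        "test_name": f"{name} ({label1} vs {label2})",
        "side": "two_sided", "t": summ.t, "n1": summ.n1, "n2": summ.n2,
        "bf10": res.bf10,
    }


def _test_battery(metrics: pd.DataFrame, scores: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rows = []
    joined = metrics.join(scores, how="inner")
    if config.run_group_tests:
        grp = joined["group"]
        specs = [
            ("creativity t-test", grp == "SE", grp == "ES", "SE", "ES"),
            ("creativity t-test", grp.isin(("SE", "ES")), grp == "monolingual",
             "bilingual", "monolingual"),
            ("creativity t-test", grp.isin(("ES", "monolingual")), grp == "SE",
             "native English", "native Spanish"),
        ]
        for name, m1, m2, l1, l2 in specs:
            row = _group_ttest_row(name, joined, m1, m2, l1, l2)
            if row:
                rows.append(row)
    if config.run_correlation_tests:
        for var, direction in CORRELATION_DIRECTIONS.items():
            if var not in joined.columns:
                continue
            sub = joined[["creativity", var]].dropna()
            if len(sub) < 4:
                logger.warning("correlation with %s skipped (n=%d < 4)", var, len(sub))
                continue
            r = float(np.corrcoef(sub["creativity"], sub[var])[0, 1])
            if not math.isfinite(r) or abs(r) >= 1:
                logger.warning("correlation with %s skipped (degenerate r)", var)
                continue
            summ = CorrSummary(r=r, n=len(sub))
            for side in ("two_sided", direction):
                res = pearson_bf(summ, PriorSettings(side=side))
                rows.append({
                    "test_name": f"creativity ~ {var}",
                    "side": side, "r": r, "n": len(sub), "bf10": res.bf10,
                })
    return results_table(rows)


def report_table(bundle: ResultsBundle) -> str:
    """The test report as CSV text (BF01 before BF10, Jeffreys labels)."""
    if bundle.tests is None:
        return ""
    return bundle.tests.to_csv(index=False)
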
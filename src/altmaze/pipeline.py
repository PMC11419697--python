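"""End-to-end pipeline: simulate -> classify -> seqstats -> ddCRP -> markov -> errors.

Each stage reads/writes plain-text artifacts in an output directory and a
run manifest records the seed, configuration and package versions, so a run
is reproducible from (config, seed).
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, codec, cohort, ddcrp, lapse, markov, mazes, seqstats
from .codec import encode_actions
from .io import read_visit_logs, write_visit_logs

DEFAULT_CONFIG = {
    "cohort": {},               # CohortConfig overrides
    "first_trials_patterns": 30,  # window for sequence-probability vectors
    "first_trials_ddcrp": 50,     # window for ddCRP fits
    "last_sessions_errors": 5,
    "mcmc": {"n_chains": 4, "n_samples": 1000, "n_warmup": 1000},
    "grid_step": 0.05,
    "stages": ["simulate", "classify", "seqstats", "fit-ddcrp", "markov-sim", "errors"],
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _phase2_by_rat(logs):
    by_rat = {}
    for log in logs:
        if log.phase == 2:
            by_rat.setdefault(log.rat_id, []).append(log)
    for rat in by_rat:
        by_rat[rat].sort(key=lambda l: (l.day, l.session))
    return by_rat


def early_trace(logs_for_rat, n_trials: int):
    """Action trace of a rat's first ``n_trials`` plus-maze visits
    (sessions in recording order, encoded without session-boundary
    transitions)."""
    return codec.encode_first_n(logs_for_rat, mazes.PLUS_MAZE, n_trials)


def stage_classify(logs, out_dir: Path) -> pd.DataFrame:
    rows = []
    for log in logs:
        if log.phase != 2:
            continue
        trace = encode_actions(log, mazes.PLUS_MAZE)
        props = codec.third_order_proportions(trace)
        rows.append(
            {
                "rat_id": log.rat_id, "group": log.group,
                "day": log.day, "session": log.session,
                "reward_rate": codec.reward_rate(log),
                **props,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "classify.csv", index=False)
    # group comparison of the turn/straight proportion, session by session
    fam = {}
    for (day, sess), sub in df.groupby(["day", "session"]):
        a = sub.loc[sub.group == "non-switching", "turn_straight"]
        b = sub.loc[sub.group == "switching", "turn_straight"]
        if len(a) >= 2 and len(b) >= 2:
            fam[f"d{day}s{sess}"] = (a.values, b.values)
    tests = seqstats.pairwise_wilcoxon_bh(fam)
    tests.to_csv(out_dir / "classify_tests.csv", index=False)
    return df


def stage_seqstats(logs, out_dir: Path, n_trials: int = 30) -> dict:
    by_rat = _phase2_by_rat(logs)
    rats = sorted(by_rat)
    traces = [early_trace(by_rat[r], n_trials) for r in rats]
    groups = [by_rat[r][0].group for r in rats]
    enc = seqstats.SequenceProbabilityEncoder().fit(traces)
    X = enc.transform(traces)
    pd.DataFrame(X, index=rats, columns=enc.sequences_).to_csv(
        out_dir / "sequence_probabilities.csv"
    )
    scores = seqstats.pca_embed(X)
    pd.DataFrame(
        scores, index=rats, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    ).to_csv(out_dir / "pca_scores.csv")
    within, across = seqstats.cosine_similarity_groups(scores, groups)
    from scipy.stats import mannwhitneyu

    p = float(mannwhitneyu(within, across, alternative="two-sided").pvalue)
    # one dendrogram export per group (mean probability vector)
    for group in sorted(set(groups)):
        vec = pd.Series(
            X[[g == group for g in groups]].mean(axis=0), index=enc.sequences_
        )
        tag = group.replace("-", "_")
        seqstats.export_dendrogram(
            vec,
            csv_path=out_dir / f"dendrogram_{tag}.csv",
            graphml_path=out_dir / f"dendrogram_{tag}.graphml",
        )
    summary = {
        "within_mean": float(np.mean(within)),
        "across_mean": float(np.mean(across)),
        "rank_sum_p": p,
        "n_within_pairs": int(len(within)),
        "n_across_pairs": int(len(across)),
    }
    with open(out_dir / "cosine_similarity.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def stage_ddcrp(logs, out_dir: Path, n_trials: int, mcmc: dict, seed) -> pd.DataFrame:
    by_rat = _phase2_by_rat(logs)
    root = np.random.SeedSequence(seed)
    rows = []
    for (rat, sess_logs), child in zip(sorted(by_rat.items()), root.spawn(len(by_rat))):
        trace = early_trace(sess_logs, n_trials)
        fit = ddcrp.fit_mcmc(
            trace, seed=int(child.generate_state(1)[0] % (2**31)), **mcmc
        )
        row = {"rat_id": rat, "group": sess_logs[0].group, "converged": fit.converged}
        row.update(fit.point_estimate.as_dict())
        row.update({f"rhat_{k}": v for k, v in fit.rhat.items()})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "ddcrp_fits.csv", index=False)
    return df


def stage_markov(logs, out_dir: Path, grid_step: float = 0.05) -> pd.DataFrame:
    by_rat = {}
    for log in logs:
        by_rat.setdefault(log.rat_id, []).append(log)
    vals = np.round(np.arange(0.0, 1.0 + 1e-9, grid_step), 10)
    grid = [(qe, qs) for qe in vals for qs in vals]
    frames = []
    for rat, rat_logs in sorted(by_rat.items()):
        chains = markov.estimate_phase1_chains(rat_logs)
        p2 = [l for l in rat_logs if l.phase == 2]
        acts = []
        for log in sorted(p2, key=lambda l: (l.day, l.session)):
            acts.extend(encode_actions(log, mazes.PLUS_MAZE).actions)
        observed = codec.turn_after_straight_frequency(acts)
        df = markov.sweep_mixture(chains, grid, observed)
        df.insert(0, "rat_id", rat)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(out_dir / "mixture_sweep.csv", index=False)
    return out


def stage_errors(logs, out_dir: Path, n_sessions: int = 5) -> pd.DataFrame:
    df = pd.DataFrame(lapse.error_report(logs, n_sessions=n_sessions))
    df.to_csv(out_dir / "errors.csv", index=False)
    fam = {}
    for col in ("alternation_rate", "reference_rate", "difference"):
        a = df.loc[df.group == "non-switching", col]
        b = df.loc[df.group == "switching", col]
        if len(a) >= 2 and len(b) >= 2:
            fam[col] = (a.values, b.values)
    if fam:
        seqstats.pairwise_wilcoxon_bh(fam).to_csv(
            out_dir / "error_tests.csv", index=False
        )
    return df


def run_pipeline(config: dict | None = None, out_dir="results", seed: int = 0) -> dict:
    """Execute the configured stages; returns a report bundle (dict)."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg["stages"]
    report: dict = {"seed": seed, "stages": list(stages)}
    logs = None
    visits_path = out / "visits.csv"
    current = None
    try:
        if "simulate" in stages:
            current = "simulate"
            cohort_cfg = cohort.CohortConfig(seed=seed, **cfg["cohort"])
            logs = cohort.generate_cohort(cohort_cfg)
            write_visit_logs(logs, visits_path)
            report["n_logs"] = len(logs)
        if logs is None:
            current = "read"
            logs = read_visit_logs(visits_path)
        if "classify" in stages:
            current = "classify"
            stage_classify(logs, out)
        if "seqstats" in stages:
            current = "seqstats"
            report["seqstats"] = stage_seqstats(
                logs, out, cfg["first_trials_patterns"]
            )
        if "fit-ddcrp" in stages:
            current = "fit-ddcrp"
            df = stage_ddcrp(logs, out, cfg["first_trials_ddcrp"], cfg["mcmc"], seed)
            report["ddcrp_median_tau"] = {
                g: float(sub.tau.median()) for g, sub in df.groupby("group")
            }
        if "markov-sim" in stages:
            current = "markov-sim"
            stage_markov(logs, out, cfg["grid_step"])
        if "errors" in stages:
            current = "errors"
            df = stage_errors(logs, out, cfg["last_sessions_errors"])
            report["error_difference_by_group"] = {
                g: float(sub["difference"].median()) for g, sub in df.groupby("group")
            }
    except Exception as e:
        raise RuntimeError(f"pipeline stage {current!r} failed: {e}") from e
    manifest = {
        "altmaze_version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config": {k: v for k, v in cfg.items() if k != "cohort_obj"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return report
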
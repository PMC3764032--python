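"""End-to-end orchestration: simulate -> preprocess -> spectral -> decode -> stats.

`run_experiment` reproduces the full analysis on synthetic penetrations:
for each penetration it generates (or loads) a session, notch-filters the
LFP, rejects clipped trials, computes Morlet band power for the adapter and
test epochs, builds the four stimulus conditions, equalizes N_tot, decodes
every requested band (plus optionally the spike-count MUA comparator) and
aggregates accuracies across penetrations into a condition x band summary
(mean +- SEM) with repeated-measures statistics.  Everything is
deterministic under the master seed: per-penetration seeds are spawned from
it, so results are independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimulationConfig, SessionRecording, generate_session
from .preprocess import PreprocessParams, notch_filter, reject_clipped_trials
from .spectral import BANDS, compute_band_power
from .decode import (
    FeatureSet,
    build_conditions,
    decode_condition,
    decode_mua,
    equalize_n_tot,
    shuffle_control,
    subsample_site_indices,
)
from .stats import rm_anova

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "summarize",
    "shuffle_null_experiment",
]


@dataclass
class ExperimentConfig:
    """Structured configuration of a full run (YAML-serializable)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_penetrations: int = 2
    bands: Sequence[str] = tuple(BANDS)
    n_classifiers: int = 1000
    n_permutations: int = 0  # label-shuffle controls per condition; 0 = skip
    include_mua: bool = True
    subsample_fraction: float | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        pre_kwargs = raw.pop("preprocess", {})
        for key in ("notch_band", "window", "input_range"):
            if key in pre_kwargs and pre_kwargs[key] is not None:
                pre_kwargs[key] = tuple(pre_kwargs[key])
        pre = PreprocessParams(**pre_kwargs)
        return cls(simulation=sim, preprocess=pre, **raw)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["bands"] = list(self.bands)
        return json.loads(json.dumps(d, default=lambda o: list(o)))


@dataclass
class ExperimentResult:
    results: pd.DataFrame  # tidy per penetration x band x condition
    summary: pd.DataFrame  # condition x band mean +- SEM
    stats_reports: dict[str, pd.DataFrame]
    manifest: dict


def analyze_session(
    session: SessionRecording,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> tuple[list[dict], dict]:
    """Run preprocessing, spectral estimation and decoding for one session."""
    sim = session.config
    pre = config.preprocess
    if pre.input_range is None and sim is not None:
        pre = PreprocessParams(
            notch_band=pre.notch_band,
            notch_order=pre.notch_order,
            clip_low=pre.clip_low,
            clip_high=pre.clip_high,
            window=pre.window,
            input_range=tuple(sim.input_range),
        )
    trials = session.trials
    keep_mask = ~trials["aborted"].to_numpy(dtype=bool)
    lfp = session.lfp[keep_mask]
    trials = trials[keep_mask].reset_index(drop=True)

    kept_ids, rejection_report = reject_clipped_trials(
        lfp, trials["trial_id"].to_numpy(), pre
    )
    keep = trials["trial_id"].isin(kept_ids).to_numpy()
    lfp = lfp[keep]
    trials = trials[keep].reset_index(drop=True)

    lfp = notch_filter(lfp, session.sampling_rate, pre)

    if config.subsample_fraction is not None:
        site_idx = subsample_site_indices(
            session.n_sites, config.subsample_fraction
        )
        lfp = lfp[:, site_idx, :]

    bands = {b: BANDS[b] for b in config.bands}
    bpt = compute_band_power(
        lfp,
        session.sampling_rate,
        trials["trial_id"].to_numpy(),
        epoch_onsets_ms={
            "adapter": sim.adapter_onset_ms,
            "test": sim.test_onset_ms,
        },
        window_ms=pre.window,
        bands=bands,
    )

    conditions = build_conditions(trials)
    n_tot = equalize_n_tot(conditions)
    rows: list[dict] = []
    for band in config.bands:
        features = FeatureSet.from_band_power(bpt, band)
        for cond in conditions.values():
            res = decode_condition(
                features,
                cond,
                n_tot,
                config.n_classifiers,
                rng,
                band=band,
                penetration=session.penetration,
            )
            # every condition's classifiers see identical sizes by construction
            assert res.n_tot == n_tot
            shuffle_mean = np.nan
            if config.n_permutations:
                shuffle_mean, _ = shuffle_control(
                    features, cond, n_tot, config.n_permutations, rng
                )
            rows.append(_result_row(res, shuffle_mean))
    if config.include_mua and session.spikes is not None:
        spikes = session.spikes[keep_mask][keep]
        sess_kept = SessionRecording(
            lfp=lfp,
            trials=trials,
            sampling_rate=session.sampling_rate,
            spikes=spikes,
            config=None,
            penetration=session.penetration,
        )
        for res in decode_mua(
            sess_kept, conditions, n_tot, config.n_classifiers, rng
        ):
            rows.append(_result_row(res, np.nan))
    info = {
        "penetration": session.penetration,
        "n_rejected_clipped": len(rejection_report),
        "n_aborted": int((~keep_mask).sum()),
        "n_tot": n_tot,
    }
    return rows, info


def shuffle_null_experiment(
    sim_config: SimulationConfig | None = None,
    band: str = "alpha",
    condition: str = "Test_rep",
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Full-pipeline label-shuffle control on one synthetic penetration.

    Simulates a session, preprocesses it, computes Morlet band power for
    ``band``, builds the stimulus conditions, equalizes N_tot, then runs the
    label-shuffle control: for every permutation the class labels are
    randomly permuted across trials and one linear-SVM half-split is trained
    and tested.  The mean accuracy across permutations estimates the
    empirical chance level (50 %).
    """
    ss = np.random.SeedSequence(seed)
    sim_seed = int(ss.generate_state(1)[0] % (2**31))
    sim = _with_seed(sim_config or SimulationConfig(), sim_seed)
    session = generate_session(sim, with_spikes=False)
    pre = PreprocessParams(input_range=tuple(sim.input_range))
    trials = session.trials[~session.trials["aborted"]].reset_index(drop=True)
    lfp = session.lfp[~session.trials["aborted"].to_numpy(dtype=bool)]
    kept_ids, _ = reject_clipped_trials(lfp, trials["trial_id"].to_numpy(), pre)
    keep = trials["trial_id"].isin(kept_ids).to_numpy()
    lfp = notch_filter(lfp[keep], session.sampling_rate, pre)
    trials = trials[keep].reset_index(drop=True)
    bpt = compute_band_power(
        lfp,
        session.sampling_rate,
        trials["trial_id"].to_numpy(),
        {"adapter": sim.adapter_onset_ms, "test": sim.test_onset_ms},
        window_ms=pre.window,
        bands={band: BANDS[band]},
    )
    conditions = build_conditions(trials)
    n_tot = equalize_n_tot(conditions)
    features = FeatureSet.from_band_power(bpt, band)
    rng = np.random.default_rng(ss.spawn(1)[0])
    mean, dist = shuffle_control(
        features, conditions[condition], n_tot, n_permutations, rng
    )
    return {
        "mean_shuffled_accuracy": mean,
        "distribution": dist,
        "n_tot": n_tot,
        "n_test_trials_per_class": n_tot // 2,
        "band": band,
        "condition": condition,
        "n_permutations": n_permutations,
    }


def _result_row(res, shuffle_mean) -> dict:
    return {
        "penetration": res.penetration,
        "band": res.band,
        "condition": res.condition,
        "mean_accuracy": res.mean_accuracy,
        "shuffle_mean": shuffle_mean,
        "n_tot": res.n_tot,
        "n_sites": res.n_sites,
    }


def run_experiment(
    config: ExperimentConfig, out_dir=None
) -> ExperimentResult:
    """Simulate and analyze ``n_penetrations`` penetrations end to end."""
    t_start = time.time()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_penetrations)
    rows: list[dict] = []
    pen_info = []
    for p, child in enumerate(children):
        sim_seed = int(child.generate_state(1)[0] % (2**31))
        sim = _with_seed(config.simulation, sim_seed)
        session = generate_session(sim, penetration=f"pen{p:02d}")
        rng = np.random.default_rng(child.spawn(1)[0])
        pen_rows, info = analyze_session(session, config, rng)
        rows.extend(pen_rows)
        pen_info.append(info)

    results = pd.DataFrame(rows)
    summary = summarize(results)
    stats_reports = _group_stats(results)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_jsonable(),
        "penetrations": pen_info,
        "elapsed_s": round(time.time() - t_start, 2),
        "digests": {"results": _digest(results), "summary": _digest(summary)},
    }
    result = ExperimentResult(results, summary, stats_reports, manifest)
    if out_dir is not None:
        _write_outputs(result, out_dir)
    return result


def _with_seed(sim: SimulationConfig, seed: int) -> SimulationConfig:
    d = asdict(sim)
    d["seed"] = seed
    return SimulationConfig(**d)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Condition x band table of mean and SEM across penetrations."""
    n_pen = results["penetration"].nunique()
    if n_pen < 2:
        raise ValueError("SEM undefined for a single penetration")
    g = results.groupby(["band", "condition"])["mean_accuracy"]
    out = g.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)),
                n="count").reset_index()
    out["n_penetrations"] = n_pen
    return out


def _group_stats(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-band one-way and overall two-way repeated-measures ANOVA."""
    reports: dict[str, pd.DataFrame] = {}
    lfp_results = results[results["band"] != "MUA"]
    if results["penetration"].nunique() < 2:
        return reports
    for band, sub in lfp_results.groupby("band"):
        wide = sub.pivot(
            index="penetration", columns="condition", values="mean_accuracy"
        )
        reports[f"oneway_{band}"] = rm_anova(wide)
    if lfp_results["band"].nunique() > 1:
        wide2 = lfp_results.pivot(
            index="penetration",
            columns=["band", "condition"],
            values="mean_accuracy",
        )
        reports["twoway_band_x_condition"] = rm_anova(wide2)
    return reports


def _digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        df.round(10).to_csv(index=False).encode()
    ).hexdigest()[:16]


def _write_outputs(result: ExperimentResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.results.to_csv(out / "decoding_results.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    for name, rep in result.stats_reports.items():
        rep.to_csv(out / f"stats_{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
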
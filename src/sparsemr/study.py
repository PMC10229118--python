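"""Simulation study runners: the two-block illustrative experiment and the
high-dimensional benchmarking grid.

Both experiments share the block-structured generator.  Study conditions:

* **Illustrative** — six exposures in two blocks, the first block causal,
  two components fixed a priori, an n-grid spanning conditionally weak to
  conditionally strong instruments (mean CFS from a few units to several
  tens); tests at alpha/2.
* **High-dimensional grid** — K in {32, 30, 60} exposures in B in {4, 6}
  equal blocks (combinations chosen so the blocks divide K), with ~1.5
  SNPs per exposure as in the workflow's real application, so the joint
  MVMR design is strongly collinear and conditionally weak.  Sample sizes are set analytically so the
  mean instrument F-statistic spans roughly 220-1100 across settings.
  Five analyses are scored per replicate: plain PCA, elastic-net sparse
  PCA, SCA (each with permutation retention and alpha/B component tests),
  and per-exposure IVW MVMR with and without Bonferroni correction.

Per setting, classification counts are pooled over replicates; methods are
compared by median sensitivity/specificity/Youden's J across settings and
by the AUC of the bivariate meta-analytic summary ROC.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .data import SnpExposureMatrix
from .evaluate import (
    ClassificationResult,
    classify_calls,
    merge_classifications,
    sroc_auc,
    summarize,
)
from .mr import instrument_strength, ivw_mvmr
from .pipeline import PcMrPipeline
from .simulate import SimulationConfig, sample_size_for_mean_f, simulate_dataset

__all__ = [
    "HIGH_DIM_COMBOS",
    "HIGH_DIM_F_TARGETS",
    "high_dim_config",
    "illustrative_config",
    "run_high_dimensional_study",
    "run_illustrative_study",
]

#: (K, B) combinations of the high-dimensional grid; K must divide into B
#: equal blocks, so the paper-scale span 30-60 exposures / 4-6 blocks is
#: realized as these four divisible combinations.
HIGH_DIM_COMBOS: tuple[tuple[int, int], ...] = ((32, 4), (30, 6), (60, 4), (60, 6))

#: target mean instrument F-statistics defining the sample-size axis
HIGH_DIM_F_TARGETS: tuple[float, ...] = (220.0, 500.0, 1100.0)

PIPELINE_METHODS = ("pca", "spca", "sca")
METHOD_LABELS = {"pca": "PCA", "spca": "SPCA", "sca": "SCA"}


def _derive_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))


def high_dim_config(K: int, B: int, rng_seed: int = 0) -> SimulationConfig:
    """Base configuration of one high-dimensional grid cell (n set later).

    The SNP count keeps the instrument-to-exposure ratio of the workflow's
    real application (~1.5 SNPs per exposure), rounded to a multiple of B.
    """
    p = B * int(round(1.5 * K / B))
    return SimulationConfig(
        n=p + 2,
        p=p,
        K=K,
        B=B,
        gamma_effect=0.5,
        gamma_cv=0.12,
        confounder_effect_x=0.5,
        confounder_effect_y=0.5,
        noise_sd_x=0.5,
        noise_sd_y=1.0,
        beta_effect=0.45,
        rng_seed=rng_seed,
    )


def illustrative_config(rng_seed: int = 0) -> SimulationConfig:
    """Two blocks of three exposures; block 1 causal."""
    return SimulationConfig(
        n=1000,
        p=12,
        K=6,
        B=2,
        gamma_effect=0.5,
        gamma_cv=0.25,
        confounder_effect_x=0.5,
        confounder_effect_y=0.5,
        noise_sd_x=0.5,
        noise_sd_y=1.0,
        beta_effect=0.3,
        rng_seed=rng_seed,
    )


def _pipeline_analyses(
    exposures: SnpExposureMatrix,
    outcome,
    truth,
    alpha: float,
    n_permutations: int,
    seed: int,
    methods=PIPELINE_METHODS,
    n_components: int | None = None,
    retention: str = "permutation",
) -> dict[str, ClassificationResult]:
    out: dict[str, ClassificationResult] = {}
    for method in methods:
        pipe = PcMrPipeline(
            method=method,
            retention=retention,
            n_components=n_components,
            alpha=alpha,
            n_permutations=n_permutations,
            random_state=seed,
        ).fit(exposures, outcome)
        out[METHOD_LABELS[method]] = classify_calls(
            pipe.result_, truth, method_label=METHOD_LABELS[method]
        )
    return out


def _mvmr_analyses(exposures, outcome, truth, alpha: float):
    fit = ivw_mvmr(
        exposures.gamma,
        outcome.Gamma,
        outcome.se,
        predictor_ids=list(exposures.exposure_ids),
    )
    K = exposures.n_exposures
    return {
        "MVMR": classify_calls(fit, truth, alpha, method_label="MVMR"),
        "MVMR_B": classify_calls(fit, truth, alpha / K, method_label="MVMR_B"),
    }


def run_high_dimensional_study(
    seed: int = 0,
    reps: int = 50,
    combos=HIGH_DIM_COMBOS,
    f_targets=HIGH_DIM_F_TARGETS,
    alpha: float = 0.05,
    n_permutations: int = 30,
    verbose: bool = False,
) -> dict:
    """Run the full benchmarking grid and aggregate across settings.

    Returns a dict with per-method aggregates::

        {"methods": {label: {"auc", "median_sns", "median_spc", "median_j",
                             "per_setting": DataFrame}},
         "settings": DataFrame}
    """
    labels = list(METHOD_LABELS.values()) + ["MVMR", "MVMR_B"]
    per_setting: dict[str, list[ClassificationResult]] = {m: [] for m in labels}
    setting_rows = []
    for si, ((K, B), f_target) in enumerate(
        (c, f) for c in combos for f in f_targets
    ):
        base = high_dim_config(K, B)
        n = sample_size_for_mean_f(base, f_target)
        rep_results: dict[str, list[ClassificationResult]] = {m: [] for m in labels}
        mean_f_obs, mean_cfs_obs = [], []
        for r in range(reps):
            cfg = replace(base, n=n, rng_seed=_derive_seed(seed, si, r))
            ds = simulate_dataset(cfg)
            res = _pipeline_analyses(
                ds.summary,
                ds.outcome_summary,
                ds.truth,
                alpha,
                n_permutations,
                _derive_seed(seed, si, r, 1),
            )
            res.update(
                _mvmr_analyses(ds.summary, ds.outcome_summary, ds.truth, alpha)
            )
            for m in labels:
                rep_results[m].append(res[m])
            if r < 3:  # instrument-strength audit on a few replicates
                st = instrument_strength(ds.summary)
                mean_f_obs.append(float(np.mean(st.mean_f)))
                mean_cfs_obs.append(float(np.mean(st.conditional_f)))
        for m in labels:
            per_setting[m].append(merge_classifications(rep_results[m]))
        setting_rows.append(
            {
                "K": K,
                "B": B,
                "n": n,
                "f_target": f_target,
                "mean_f": float(np.mean(mean_f_obs)),
                "mean_cfs": float(np.mean(mean_cfs_obs)),
            }
        )
        if verbose:
            print(f"setting {si}: K={K} B={B} n={n} done", flush=True)

    methods = {}
    for m in labels:
        summary = summarize(per_setting[m])
        sroc = sroc_auc(per_setting[m])
        methods[m] = {
            "auc": sroc.auc,
            "median_sns": summary.median_sns,
            "median_spc": summary.median_spc,
            "median_j": summary.median_j,
            "summary": summary,
            "sroc": sroc,
        }
    return {"methods": methods, "settings": pd.DataFrame(setting_rows)}


def run_illustrative_study(
    seed: int = 0,
    reps: int = 100,
    n_grid=(600, 2500, 8000, 25000),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-block experiment across a sample-size grid.

    Components are fixed at two a priori; all tests at alpha/2.  Returns a
    per-n table with mean instrument strength (F and conditional F),
    per-exposure power (true-positive rate) and type-I error
    (false-positive rate) for PCA, SCA and joint MVMR.
    """
    rows = []
    for ni, n in enumerate(n_grid):
        counts = {
            m: np.zeros(4) for m in ("PCA", "SCA", "MVMR")
        }  # tp, fp, tn, fn
        f_vals, cfs_vals = [], []
        for r in range(reps):
            cfg = replace(
                illustrative_config(), n=int(n), rng_seed=_derive_seed(seed, ni, r)
            )
            ds = simulate_dataset(cfg)
            res = _pipeline_analyses(
                ds.summary,
                ds.outcome_summary,
                ds.truth,
                alpha,
                n_permutations=1,
                seed=_derive_seed(seed, ni, r, 1),
                methods=("pca", "sca"),
                n_components=2,
                retention="fixed",
            )
            mv = ivw_mvmr(
                ds.summary.gamma, ds.outcome_summary.Gamma, ds.outcome_summary.se
            )
            res["MVMR"] = classify_calls(mv, ds.truth, alpha / 2.0)
            for m in counts:
                c = res[m]
                counts[m] += np.array([c.tp, c.fp, c.tn, c.fn])
            if r < 5:
                st = instrument_strength(ds.summary)
                f_vals.append(float(np.mean(st.mean_f)))
                cfs_vals.append(float(np.mean(st.conditional_f)))
        row = {"n": int(n), "mean_f": np.mean(f_vals), "mean_cfs": np.mean(cfs_vals)}
        for m, (tp, fp, tn, fn) in ((m, c) for m, c in counts.items()):
            row[f"power_{m.lower()}"] = tp / (tp + fn)
            row[f"t1e_{m.lower()}"] = fp / (fp + tn)
        rows.append(row)
    return pd.DataFrame(rows)
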
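"""End-to-end pipeline: simulate -> effluent retention -> size-stratified
retention -> histology -> cross-arm comparison, in one summary document."""
from __future__ import annotations

import numpy as np

from .effluent import analyze_run
from .histology import transmural_gradient, whole_heart_estimate
from .io import RunConfig
from .simulator import (
    default_params,
    expected_first_minute_fraction,
    expected_retention,
    simulate_run,
    simulate_sections,
)
from .sizes import bins_to_frame, per_bin_retention, summarize_sizes

__all__ = ["run_report", "mean_sem"]


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (SD/sqrt(n), ddof=1)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to summarize")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), sem


def _spawn_seeds(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_report(config: RunConfig) -> dict:
    """Run the whole pipeline for one simulated experimental arm.

    Simulates ``n_hearts`` injections, analyses each through the effluent
    pipeline, pools the size histograms for per-bin retention, draws
    histology sections from each heart's ground-truth retained load, and
    compares the effluent and histology retention estimates.  Fully
    deterministic given ``config.seed``.
    """
    try:
        params = config.params or default_params(config.cell_type)
        rngs = _spawn_seeds(config.seed, config.n_hearts)

        runs, truths, results = [], [], []
        for i, rng in enumerate(rngs):
            run, truth = simulate_run(params, int(config.dose), rng=rng)
            res = analyze_run(run, window_minutes=config.window_minutes,
                              clamp=config.clamp)
            runs.append(run)
            truths.append(truth)
            results.append(res)
    except Exception as exc:  # noqa: BLE001 - stage name aids debugging
        raise RuntimeError(f"simulation/effluent stage failed: {exc}") from exc

    retention = [r.retention_pct for r in results]
    first_min = [r.first_minute_pct for r in results]
    ret_mean, ret_sem = mean_sem(retention)
    fm_mean, fm_sem = mean_sem(first_min)

    try:
        pre_pool = runs[0].pre_injection_population.size_histogram
        eff_pool = runs[0].effluent_size_histogram
        for run in runs[1:]:
            pre_pool = pre_pool + run.pre_injection_population.size_histogram
            eff_pool = eff_pool + run.effluent_size_histogram
        # union-aligned addition can widen the range; re-bin onto shared edges
        lo = int(pre_pool.lower_edges[0])
        hi = int(pre_pool.lower_edges[-1])
        eff_pool = eff_pool + type(eff_pool).from_dict({lo: 0.0, hi: 0.0})
        bins = per_bin_retention(pre_pool, eff_pool, clamp=config.clamp)
        pre_median, pre_mean = summarize_sizes(pre_pool)
        eff_median, eff_mean = summarize_sizes(eff_pool)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"size-stratification stage failed: {exc}") from exc

    try:
        rng_hist = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        hist_rows, all_sections = [], []
        for i, truth in enumerate(truths):
            h = simulate_sections(
                params, truth.retained_count, config.dose,
                rng=rng_hist, heart_id=f"H{i + 1}",
            )
            retained_est, pct = whole_heart_estimate(h)
            hist_rows.append(
                {"heart_id": h.heart_id, "retained_cells": retained_est,
                 "retention_pct": pct}
            )
            all_sections.extend(h.sections)
        grad = transmural_gradient(all_sections)
        hist_mean, hist_sem = mean_sem([r["retention_pct"] for r in hist_rows])
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"histology stage failed: {exc}") from exc

    return {
        "cell_type": params.cell_type,
        "dose": config.dose,
        "n_hearts": config.n_hearts,
        "window_minutes": config.window_minutes,
        "seed": config.seed,
        "expected_retention_pct": expected_retention(params) * 100.0,
        "expected_first_minute_pct": expected_first_minute_fraction(params) * 100.0,
        "runs": [
            {
                "run_id": f"H{i + 1}",
                "retention_pct": r.retention_pct,
                "retention_pct_raw": r.retention_pct_raw,
                "first_minute_pct": r.first_minute_pct,
                "total_effluent": r.total_effluent,
                "true_retained_fraction": t.retained_fraction,
            }
            for i, (r, t) in enumerate(zip(results, truths))
        ],
        "retention_pct_mean": ret_mean,
        "retention_pct_sem": ret_sem,
        "first_minute_pct_mean": fm_mean,
        "first_minute_pct_sem": fm_sem,
        "size": {
            "pre_median_um": pre_median,
            "pre_mean_um": pre_mean,
            "effluent_median_um": eff_median,
            "effluent_mean_um": eff_mean,
            "per_bin": bins_to_frame(bins).to_dict(orient="records"),
        },
        "histology": {
            "hearts": hist_rows,
            "retention_pct_mean": hist_mean,
            "retention_pct_sem": hist_sem,
            "layer_densities": grad.layer_densities,
            "endo_epi_ratio": grad.endo_epi_ratio,
        },
        "comparison": {
            "effluent_retention_pct_mean": ret_mean,
            "histology_retention_pct_mean": hist_mean,
            "difference_pct_points": ret_mean - hist_mean,
        },
    }
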
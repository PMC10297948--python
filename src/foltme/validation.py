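"""End-to-end validation experiments.

Each function runs one self-contained benchmark of the pipeline against
synthetic ground truth and returns plain numbers: cohort-table arithmetic,
stain-unmixing round-trip fidelity, registration recovery, compartment
segmentation accuracy, count/ratio bookkeeping, cutpoint recovery, and the
calibration of the statistical machinery (type-I error, CI coverage).
They back both the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are chosen so the full battery runs in a few minutes on one
CPU: 320 px ROIs at 1 um/px for registration, 250 px for segmentation,
300-patient cohorts for cutpoint recovery, 1000 replicates for type-I
calibration and 200 for Cox coverage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cohortsim as cs
from . import epimutation as em
from . import quantify, registration, slidesim, stains
from . import scoring_survival as ss
from .compartments import compartment_masks, segment_follicles

__all__ = [
    "cohort_table_percentages",
    "deconvolution_roundtrip_error",
    "registration_recovery",
    "segmentation_benchmark",
    "counting_consistency",
    "cutpoint_recovery_rate",
    "logrank_type1_rate",
    "mannwhitney_type1_rate",
    "cox_recovery",
    "burden_type1_rate",
    "sem_scan_consistency",
]


def cohort_table_percentages() -> dict[str, float]:
    """Per-level percentages recomputed from the cohort composition counts."""
    out = {}
    for var, levels in cs.DEFAULT_CATEGORY_COUNTS.items():
        total = sum(levels.values())
        for lvl, cnt in levels.items():
            out[f"{var}:{lvl}"] = 100.0 * cnt / total
    return out


def deconvolution_roundtrip_error(seed: int, size: int = 256) -> float:
    """Max concentration error of compose -> 8-bit -> deconvolve.

    The random field spans the renderer's physical regime: hematoxylin
    counterstain uniform in [0, 0.8] OD, chromogen uniform in [0, 1.0].
    """
    rng = np.random.default_rng(seed)
    M = stains.StainMatrix.hax()
    C = np.zeros((size, size, 3))
    C[..., 0] = rng.uniform(0.0, 0.8, (size, size))
    C[..., 1] = rng.uniform(0.0, 1.0, (size, size))
    back = stains.deconvolve(stains.rgb_to_od(stains.compose(C, M)), M)
    return float(np.abs(back.channels - C).max())


def registration_recovery(seed: int, n_seeds: int = 20,
                          roi_size: int = 320) -> dict:
    """Distort rendered rounds by known rigid+elastic maps and re-register.

    Distortions: shift up to 10 px, rotation up to 2 deg, smooth elastic
    field up to 10 px.  Success = mean landmark error below 1.5 px.
    """
    cfg = slidesim.SlideConfig(roi_size=roi_size, pixel_size_um=1.0)
    M = stains.StainMatrix.hax()
    margin = 40
    errors = []
    for k in range(n_seeds):
        truth = slidesim.generate_slide(cfg, seed=seed * 10_000 + k)
        img = slidesim.render_round(truth, 1)
        fixed = stains.deconvolve(stains.rgb_to_od(img),
                                  M).channel("hematoxylin")
        rng = np.random.default_rng(seed * 10_000 + 5000 + k)
        true_t = registration.random_transform(
            fixed.shape, rng, max_shift=10.0, max_rotation_deg=2.0,
            elastic_magnitude=10.0)
        moving = stains.deconvolve(
            stains.rgb_to_od(slidesim.distort_round(img, true_t)),
            M).channel("hematoxylin")
        est = registration.register_rounds(fixed, moving, mode="rigid")
        lms = np.array([c.center for c in truth.cells])
        keep = ((lms[:, 0] > margin) & (lms[:, 0] < roi_size - margin)
                & (lms[:, 1] > margin) & (lms[:, 1] < roi_size - margin))
        errors.append(registration.landmark_error(
            true_t.invert(fixed.shape), est, lms[keep][:60]))
    errors = np.array(errors)
    return {"errors": errors,
            "mean_error_px": float(errors.mean()),
            "success_rate": float((errors < 1.5).mean())}


def segmentation_benchmark(seed: int, n_rois: int = 10,
                           roi_size: int = 250) -> dict:
    """Segment CD21 rounds of synthetic ROIs and score IoU vs truth."""
    cfg = slidesim.SlideConfig(roi_size=roi_size, pixel_size_um=1.0)
    M = stains.StainMatrix.hax()
    ious, fracs, partition_ok = [], [], True
    for k in range(n_rois):
        truth = slidesim.generate_slide(cfg, seed=seed * 10_000 + k)
        img = slidesim.render_round(truth, 0)
        cd21 = stains.deconvolve(stains.rgb_to_od(img), M).channel("AEC")
        if_mask = segment_follicles(cd21, close_radius=6, min_area=300)
        m = compartment_masks(if_mask, roi_id=f"roi{k}")
        tm = truth.follicle_mask
        ious.append((if_mask & tm).sum() / (if_mask | tm).sum())
        fracs.append(m.if_fraction)
        partition_ok &= bool(np.all(m.if_mask ^ m.ef_mask))
    return {"ious": np.array(ious), "min_iou": float(np.min(ious)),
            "mean_iou": float(np.mean(ious)),
            "mean_if_fraction": float(np.mean(fracs)),
            "partition_exact": partition_ok}


def counting_consistency(seed: int) -> dict:
    """Detection counts and ratio scores vs brute-force bookkeeping.

    Renders one ROI, detects cells, and recomputes every per-compartment
    count and per-ROI ratio by explicit loops; also checks that medians of
    the 10 per-ROI integer counts land on the half-integer grid.
    """
    cfg = slidesim.SlideConfig(roi_size=300, pixel_size_um=1.0)
    truth = slidesim.generate_slide(cfg, seed=seed)
    M = stains.StainMatrix.hax()
    masks = compartment_masks(truth.follicle_mask)
    counts_match = True
    dets = {}
    for marker, (rnd, _) in truth.panel.items():
        if marker == "CD21":
            continue
        img = slidesim.render_round(truth, rnd)
        ch = stains.deconvolve(stains.rgb_to_od(img), M).channel("AEC")
        det = quantify.detect_cells(ch, marker, min_scale=2.0, max_scale=7.0,
                                    threshold=0.08, roi_id="roi0")
        det = quantify.assign_compartment(det, masks)
        dets[marker] = det
        for comp in ("IF", "EF"):
            tbl = quantify.counts_per_hpf(det, "P1", marker, comp,
                                          roi_ids=["roi0"])
            brute = sum(1 for _, r in det.iterrows()
                        if r["marker"] == marker
                        and r["compartment"] == comp)
            counts_match &= int(tbl["count"].iloc[0]) == brute

    # ratio + median arithmetic on simulated 10-ROI count tables
    rng = np.random.default_rng(seed + 1)
    rows = []
    for pid in ("P1", "P2", "P3"):
        for i in range(10):
            rows.append((pid, f"r{i}", "CD163", "EF",
                         int(rng.poisson(8.0)) + 1))
            rows.append((pid, f"r{i}", "CD8", "EF",
                         int(rng.poisson(50.0)) + 1))
    tbl = pd.DataFrame(rows, columns=["patient_id", "roi_id", "marker",
                                      "compartment", "count"])
    ratio = ss.marker_ratio(tbl, "CD163", "CD8", "EF")
    ratio_match = True
    for _, row in ratio.iterrows():
        sub = tbl[tbl["patient_id"] == row["patient_id"]]
        per_roi = []
        for roi in sub["roi_id"].unique():
            n = sub[(sub["roi_id"] == roi)
                    & (sub["marker"] == "CD163")]["count"].iloc[0]
            d = sub[(sub["roi_id"] == roi)
                    & (sub["marker"] == "CD8")]["count"].iloc[0]
            per_roi.append(100.0 * n / d)
        ratio_match &= row["value"] == float(np.median(per_roi))

    med = ss.patient_median_score(tbl, "CD8", "EF")
    half_integer = bool(np.all(np.mod(2 * med["value"].to_numpy(), 1) == 0))
    example_median = float(np.median([30, 35]))
    return {"counts_match_bruteforce": counts_match,
            "ratio_match_bruteforce": ratio_match,
            "medians_on_half_integer_grid": half_integer,
            "even_median_example": example_median,
            "n_detections": sum(len(d) for d in dets.values())}


def cutpoint_recovery_rate(seed: int, reps: int = 100, n: int = 300,
                           true_threshold: float = 60.0,
                           hazard_ratio: float = 5.0) -> dict:
    """Maximally selected log-rank recovery of a step-hazard threshold.

    Patient scores are medians of 10 Poisson high-power-field counts (the
    pipeline's own score type, hence a half-integer grid); the hazard
    jumps by ``hazard_ratio`` at the true threshold.  A rep succeeds when
    the found threshold lies within one score-grid interval of the truth.
    """
    hits = 0
    for rep in range(reps):
        rng = np.random.default_rng(seed * 100_000 + rep)
        scores = np.median(rng.poisson(true_threshold, (n, 10)), axis=1)
        lam = 0.01 * np.where(scores >= true_threshold, hazard_ratio, 1.0)
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.exponential(100.0, n)
        times = np.minimum(t_event, t_cens)
        events = (t_event <= t_cens).astype(int)
        try:
            cp = ss.find_cutpoint(scores, times, events)
        except ValueError:
            continue
        uniq = np.unique(scores)
        j = np.searchsorted(uniq, true_threshold)
        lo = uniq[max(j - 2, 0)]
        hi = uniq[min(j + 1, len(uniq) - 1)]
        hits += lo < cp.threshold <= hi
    return {"recovery_rate": hits / reps, "reps": reps}


def logrank_type1_rate(seed: int, reps: int = 1000, n: int = 60) -> float:
    """Rejection rate of the log-rank test between halves of null cohorts."""
    rej = 0
    for rep in range(reps):
        rng = np.random.default_rng(seed * 100_000 + rep)
        t = rng.exponential(50.0, n)
        c = rng.exponential(100.0, n)
        times, events = np.minimum(t, c), (t <= c).astype(int)
        half = n // 2
        _, p = ss.logrank_test(times[:half], events[:half],
                               times[half:], events[half:])
        rej += p < 0.05
    return rej / reps


def mannwhitney_type1_rate(seed: int, reps: int = 1000, n: int = 20) -> float:
    """Rejection rate of Mann-Whitney between two null samples."""
    rej = 0
    for rep in range(reps):
        rng = np.random.default_rng(seed * 100_000 + rep)
        x = rng.normal(0, 1, 2 * n)
        g = np.array(["a"] * n + ["b"] * n)
        rej += ss.group_tests(x, g).p < 0.05
    return rej / reps


def cox_recovery(seed: int, reps: int = 200, n: int = 500,
                 true_hr: float = 0.23) -> dict:
    """Cox fits on cohorts simulated with a known hazard ratio.

    Returns the mean estimated HR and the empirical coverage of the
    nominal 95% Wald interval.
    """
    cover = 0
    hrs = []
    cfg = cs.CohortConfig(n=n, baseline_hazard=0.02, censor_rate=0.004)
    for rep in range(reps):
        rng = np.random.default_rng(seed * 100_000 + rep)
        cov = pd.DataFrame({"grp": rng.integers(0, 2, n)},
                           index=[f"P{i}" for i in range(n)])
        out = cs.simulate_event_times(cov, cfg,
                                      coefs={"grp": np.log(true_hr)},
                                      rng=rng)
        fit = ss.cox_fit(out[["grp"]], out["efs_time"], out["event"])
        hrs.append(fit.hr[0])
        cover += fit.ci_low[0] <= true_hr <= fit.ci_high[0]
    return {"mean_hr": float(np.mean(hrs)), "coverage": cover / reps,
            "reps": reps}


def burden_type1_rate(seed: int, reps: int = 1000,
                      n_per_group: int = 12, rate: float = 20.0) -> float:
    """Type-I error of the Poisson burden regression under equal rates."""
    rej = 0
    group = pd.Series(np.repeat([0, 1], n_per_group))
    for rep in range(reps):
        rng = np.random.default_rng(seed * 100_000 + rep)
        counts = pd.Series(rng.poisson(rate, 2 * n_per_group))
        _, p = em.burden_test(counts, group)
        rej += p < 0.05
    return rej / reps


def sem_scan_consistency(seed: int, n_cpgs: int = 200,
                         window_size: int = 10) -> dict:
    """Hypergeometric window scan vs brute-force enumeration.

    Builds a single synthetic chromosome with injected SEMs, runs the
    scan, and recomputes every window's k and p combinatorially.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    ids = [f"cg{i:04d}" for i in range(n_cpgs)]
    ann = pd.DataFrame({"chromosome": "chr1",
                        "position": np.arange(n_cpgs) * 100 + 1,
                        "gene": [f"G{i // 10}" for i in range(n_cpgs)]},
                       index=ids)
    vals = np.full((n_cpgs, 10), 0.5) + rng.uniform(0, 1e-4, (n_cpgs, 10))
    sem_idx = sorted(rng.choice(n_cpgs, size=8, replace=False))
    for i in sem_idx:
        vals[i, 0] = 0.99
    beta = pd.DataFrame(vals, index=ids,
                        columns=[f"s{j}" for j in range(10)])
    calls = em.call_sems(beta)
    win = em.window_enrichment(calls, ann, window_size=window_size)
    # brute-force enumeration over the called set (index positions)
    called = calls.calls.any(axis=1).to_numpy()
    sem_set = set(np.flatnonzero(called))
    K = len(sem_set)
    match = len(win) == n_cpgs - window_size + 1
    for _, w in win.iterrows():
        k_brute = len(sem_set & set(range(int(w["start_index"]),
                                          int(w["stop_index"]))))
        p_brute = float(sps.hypergeom.sf(k_brute - 1, n_cpgs, K,
                                         window_size))
        match &= (w["k"] == k_brute
                  and np.isclose(w["p"], p_brute, rtol=1e-12))
    return {"scan_matches_bruteforce": bool(match),
            "example_window_p": em.hypergeom_upper_tail(4, 10, 5, 4)}
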
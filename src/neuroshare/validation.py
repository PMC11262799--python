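"""Recovery and calibration experiments on synthetic cohorts.

Every function here generates data with :mod:`neuroshare.synthgen`, runs
the corresponding pipeline stage, and measures how well the known ground
truth is recovered — false-positive calibration of the significance
machinery, taxonomy recovery accuracy, TRF kernel and model recovery, and
closed-form checks of the coherence estimator.  These are the package's
own quality gates; the test suite and the results script both call them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import connectivity as conn
from . import pipeline, preprocess as pre, spectral, stats, synthgen, trf

__all__ = [
    "fwer_calibration",
    "taxonomy_recovery",
    "trf_recovery",
    "model_selection_runs",
    "coherence_closed_form",
    "surrogate_fpr",
    "balanced_accuracy",
]


def _classify_cohort(config: synthgen.CohortConfig, alpha=0.01, n_perm=1000,
                     seed=0) -> pd.DataFrame:
    """Band power + taxonomy for every patient of a cohort (no artifact
    stage; the configs used here inject none)."""
    frames = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(config.n_patients)
    for pi, (pid, recs, truth, _) in enumerate(synthgen.iter_cohort(config)):
        bps = {
            cond: spectral.band_power(pre.epoch(rec, config.epoch_length),
                                      config.band_scheme)
            for cond, rec in recs.items()
        }
        states = children[pi].generate_state(len(config.band_scheme.names))
        for bi, band in enumerate(config.band_scheme.names):
            df = stats.categorize_channels(
                bps["speech"], bps["music"], bps["baseline_tones"],
                band=band, direction="both", alpha=alpha, n_perm=n_perm,
                seed=int(states[bi] % (2**31)),
            )
            df.insert(0, "patient", pid)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def fwer_calibration(
    n_cohorts: int = 200,
    seed: int = 0,
    alpha: float = 0.01,
    n_channels: int = 12,
    duration: float = 80.0,
    n_perm: int = 1000,
) -> dict:
    """Familywise false-positive rate of the tmax taxonomy tests on
    no-effect cohorts.

    Each cohort contributes one test family per band (speech vs baseline);
    a family is a false positive if any channel is significant at
    ``alpha``.  Returns the observed rate, the trial count and the 95%
    binomial (Clopper-Pearson) acceptance interval for the nominal rate.
    """
    root = np.random.SeedSequence(seed)
    fp = 0
    trials = 0
    for rep, child in enumerate(root.spawn(n_cohorts)):
        states = child.generate_state(2)
        cfg = pipeline.null_cohort_config(
            seed=int(states[0] % (2**31)), n_channels=n_channels,
            duration=duration,
        )
        _, recs, _, _ = next(iter(synthgen.iter_cohort(cfg)))
        bps = {
            cond: spectral.band_power(pre.epoch(rec), cfg.band_scheme)
            for cond, rec in recs.items()
        }
        test_states = np.random.SeedSequence(int(states[1] % (2**31))).generate_state(
            len(cfg.band_scheme.names)
        )
        for bi, band in enumerate(cfg.band_scheme.names):
            ls = np.log10(bps["speech"].band(band))
            lb = np.log10(bps["baseline_tones"].band(band))
            res = stats.tmax_permutation_test(
                ls, lb, n_perm=n_perm, seed=int(test_states[bi] % (2**31))
            )
            fp += int((res.p < alpha).any())
            trials += 1
    lo, hi = sps.binom.interval(0.95, trials, alpha)
    return {
        "fwer": fp / trials,
        "false_positives": fp,
        "trials": trials,
        "accept_lo": lo / trials,
        "accept_hi": hi / trials,
        "nominal": alpha,
    }


def balanced_accuracy(truth_labels, predicted_labels) -> float:
    """Mean per-class recall over the classes present in the truth."""
    t = pd.Series(list(map(str, truth_labels)))
    p = pd.Series(list(map(str, predicted_labels)))
    recalls = []
    for cls in sorted(t.unique()):
        sel = t == cls
        recalls.append((p[sel] == cls).mean())
    return float(np.mean(recalls))


def merge_directions(categories: pd.DataFrame) -> pd.DataFrame:
    """One label per patient x channel x band: the non-none direction wins
    (activation arbitrarily on the rare double hit)."""

    def _pick(group):
        nz = group[group["category"].astype(str) != "none"]
        if not len(nz):
            return "none"
        return str(nz.sort_values("direction")["category"].iloc[0])

    return (
        categories.groupby(["patient", "channel", "band"], observed=True)
        .apply(_pick, include_groups=False)
        .reset_index(name="predicted")
    )


def taxonomy_recovery(
    seed: int = 0,
    n_patients: int = 6,
    channels_per_patient: int = 80,
    d: float = 1.5,
    duration: float = 515.0,
    alpha: float = 0.01,
    n_perm: int = 1000,
) -> dict:
    """Classify a random-taxonomy cohort and score it against ground truth.

    Returns the balanced accuracy over the seven-way merged labels
    (inconsistent counts as an error unless true) plus the confusion
    counts.
    """
    cfg = pipeline.taxonomy_cohort_config(
        seed=seed, n_patients=n_patients,
        channels_per_patient=channels_per_patient, d=d, duration=duration,
    )
    cats = _classify_cohort(cfg, alpha=alpha, n_perm=n_perm, seed=seed + 1)
    merged = merge_directions(cats)
    truth = synthgen.make_truth(cfg).category_frame()
    truth = truth.rename(columns={"category": "true"})[
        ["patient", "channel", "band", "true"]
    ]
    joined = merged.merge(truth, on=["patient", "channel", "band"], how="inner")
    acc = balanced_accuracy(joined["true"], joined["predicted"])
    confusion = (
        joined.groupby(["true", "predicted"], observed=True).size().reset_index(name="n")
    )
    return {"balanced_accuracy": acc, "confusion": confusion, "n": len(joined)}


def trf_recovery(seed: int = 0, duration: float = 240.0, snr_db: float = 0.0) -> dict:
    """Kernel and holdout-r recovery for a single injected TRF channel.

    The response is injected at ``snr_db`` against the 1-9 Hz background,
    so the analytic holdout ceiling is ``sqrt(snr / (1 + snr))``.
    """
    kernel = synthgen.default_trf_kernel()
    cfg = synthgen.CohortConfig(
        n_patients=1,
        channels_per_patient=2,
        run_durations={"speech": duration, "music": 20.0, "baseline_tones": 20.0},
        trf_channels={1: synthgen.TRFChannelSpec(kernel=tuple(kernel),
                                                 feature="peakRate",
                                                 snr_db=snr_db)},
        bg_std_spread=0.0,
        rng_seed=seed,
    )
    _, recs, truth, stimuli = next(iter(synthgen.iter_cohort(cfg)))
    rec = recs["speech"]
    stim = stimuli["speech"]
    feat = trf.peak_rate(stim.envelope)
    target = trf.lf_target(rec.data, rec.sample_rate)
    n = min(len(feat.series), target.series.shape[1])
    feat = trf.StimulusFeature(feat.kind, feat.series[:n], feat.rate)
    target = trf.NeuralTarget(target.kind, target.series[:, :n], target.rate)

    n_train = int(round(0.8 * n))
    model = trf.fit_trf(
        trf.StimulusFeature(feat.kind, feat.series[:n_train], feat.rate),
        trf.NeuralTarget(target.kind, target.series[:, :n_train], target.rate),
        lam=100.0,
    )
    lag0 = int(np.argmin(np.abs(model.lags_ms)))
    w = model.weights[lag0 : lag0 + len(kernel), 1]
    kernel_r = float(np.corrcoef(w, kernel)[0, 1])
    scores = trf.score_trf(feat, target, lam=100.0)
    snr = 10.0 ** (snr_db / 10.0)
    ceiling = float(np.sqrt(snr / (1.0 + snr)))
    return {
        "kernel_correlation": kernel_r,
        "holdout_r": float(scores["r"][1]),
        "ceiling": ceiling,
        "ceiling_gap": float(scores["r"][1] - ceiling),
    }


def model_selection_runs(
    n_cohorts: int = 10,
    seed: int = 0,
    lambda_grid=(10.0, 100.0, 1000.0),
    alpha: float = 0.01,
) -> dict:
    """Four-model comparison on cohorts generated under peakRate -> LF.

    Returns how often the generative pairing wins and the per-cohort mean
    percentages.
    """
    winners = []
    means = []
    for c in range(n_cohorts):
        cfg = pipeline.model_comparison_cohort_config(seed=seed + 1000 * c)
        percents = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for pid, recs, truth, stimuli in synthgen.iter_cohort(cfg):
                res = pipeline._trf_patient(
                    recs, stimuli, lambda_grid, alpha, sorted(cfg.trf_channels)
                )
                percents[pid] = res["percent_significant"]
            pct = pd.DataFrame(percents).T
            comp = trf.compare_models(pct)
        winners.append(comp["winner"])
        means.append(comp["means"])
    n_correct = sum(w == "peakRate+LF" for w in winners)
    return {
        "n_cohorts": n_cohorts,
        "n_peakrate_lf_wins": n_correct,
        "winners": winners,
        "mean_percentages": pd.DataFrame(means).mean().to_dict(),
    }


def coherence_closed_form(
    seed: int = 0, rhos=(0.5, 1.0, 3.0), n_epochs: int = 100
) -> dict:
    """Coherence of target = seed + noise at SNR rho vs the rho/(1+rho)
    closed form.  Returns the worst absolute deviation."""
    from .recording import ChannelInfo, EpochSet

    rng = np.random.default_rng(seed)
    errs = {}
    for rho in rhos:
        s = rng.standard_normal((n_epochs, 1, 2500))
        t = s + rng.standard_normal((n_epochs, 1, 2500)) / np.sqrt(rho)
        es = EpochSet(
            data=np.concatenate([s, t], axis=1),
            sample_rate=500.0,
            epoch_length=5.0,
            condition="speech",
            channels=[ChannelInfo(label="a", shaft_id="A"),
                      ChannelInfo(label="b", shaft_id="B")],
        )
        c = conn.band_coherence(es, 0, (5.0, 8.0))
        errs[rho] = float(abs(c[1] - rho / (1 + rho)))
    return {"errors": errs, "max_error": max(errs.values())}


def surrogate_fpr(
    n_reps: int = 30,
    seed: int = 0,
    alpha: float = 0.05,
    n_channels: int = 7,
    n_epochs: int = 40,
    n_surr: int = 200,
) -> dict:
    """False-positive rate of the epoch-shuffle surrogate test on
    independent channels, at level ``alpha`` on the empirical p."""
    from .recording import ChannelInfo, EpochSet

    root = np.random.SeedSequence(seed)
    fp = 0
    trials = 0
    for child in root.spawn(n_reps):
        rng = np.random.default_rng(child)
        data = rng.standard_normal((n_epochs, n_channels, 2500))
        es = EpochSet(
            data=data,
            sample_rate=500.0,
            epoch_length=5.0,
            condition="speech",
            channels=[ChannelInfo(label=f"c{i}", shaft_id=chr(65 + i))
                      for i in range(n_channels)],
        )
        res = conn.surrogate_null(es, 0, (5.0, 8.0), n_surr=n_surr, seed=rng,
                                  alpha=alpha)
        valid = ~np.isnan(res.p)
        fp += int((res.p[valid] < alpha).sum())
        trials += int(valid.sum())
    lo, hi = sps.binom.interval(0.95, trials, alpha)
    return {
        "fpr": fp / trials,
        "false_positives": fp,
        "trials": trials,
        "accept_lo": lo / trials,
        "accept_hi": hi / trials,
        "nominal": alpha,
    }
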
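"""End-to-end orchestration: cohort -> preprocessing -> band power ->
taxonomy -> TRF model comparison -> seed coherence -> aggregation.

Every stochastic stage derives its RNG stream from the single root seed in
:class:`RunConfig` through named ``SeedSequence`` children, so a run is
fully deterministic: the same configuration and seed produce byte-identical
output tables.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings

import numpy as np
import pandas as pd

from . import aggregate as agg
from . import connectivity as conn
from . import preprocess as pre
from . import spectral, stats, synthgen, trf

__all__ = ["RunConfig", "run_all", "demo_cohort_config"]

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunConfig:
    """Configuration for one full synthetic-pipeline run."""

    cohort: synthgen.CohortConfig
    alpha: float = 0.01
    n_perm: int = 1000
    n_surr: int = 1000
    lambda_grid: tuple = trf.DEFAULT_LAMBDA_GRID
    seed: int = 0
    do_spectral: bool = True
    do_trf: bool = True
    do_connectivity: bool = True
    do_aggregate: bool = True
    epoch_length: float = 5.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["cohort"]["band_scheme"] = list(self.cohort.band_scheme.bands)
        d["cohort"]["category_map"] = {
            f"{ch}:{band}": v for (ch, band), v in d["cohort"]["category_map"].items()
        }
        d["cohort"]["coupling_map"] = {
            f"{ch}:{band}": v for (ch, band), v in d["cohort"]["coupling_map"].items()
        }
        d["cohort"]["trf_channels"] = {
            str(k): v for k, v in d["cohort"]["trf_channels"].items()
        }
        d["lambda_grid"] = list(self.lambda_grid)
        return json.dumps(d, indent=1, sort_keys=True, default=str)


def demo_cohort_config(
    seed: int = 0,
    n_patients: int = 2,
    channels_per_patient: int = 24,
    run_durations: dict | None = None,
) -> synthgen.CohortConfig:
    """A small desk-scale cohort exercising every pipeline stage.

    Channels 0-7 carry band-power effects across categories and
    directions, channel 8 encodes the speech/music peakRate (the
    connectivity seed), channels 12-14 are theta-coupled to it (outside
    the seed-neighbor exclusion radius; the three couplings share a band
    so that several channels clear the BH rank floor together), and mild
    channel/epoch artifacts are injected.  Effect strengths are kept
    moderate so genuine responses do not trip the variance-outlier
    artifact rule.
    """
    if run_durations is None:
        run_durations = {"speech": 150.0, "music": 150.0, "baseline_tones": 120.0}
    d = 3.0
    category_map = {
        (0, "delta"): synthgen.CategoryEffect("shared", "activation", d),
        (1, "theta"): synthgen.CategoryEffect("selective_speech", "activation", d),
        (2, "theta"): synthgen.CategoryEffect("selective_music", "activation", d),
        (3, "alpha"): synthgen.CategoryEffect("preferred_speech", "activation", d),
        (4, "beta"): synthgen.CategoryEffect("shared", "deactivation", d),
        (5, "low_gamma"): synthgen.CategoryEffect("selective_speech", "deactivation", d),
        (6, "hfa"): synthgen.CategoryEffect("shared", "activation", d),
        (7, "hfa"): synthgen.CategoryEffect("selective_music", "activation", d),
    }
    kernel = tuple(synthgen.default_trf_kernel())
    trf_channels = {8: synthgen.TRFChannelSpec(kernel=kernel, feature="peakRate",
                                               snr_db=-3.0)}
    coupling_map = {
        (12, "theta"): synthgen.Coupling(seed_channel=8, kappa_speech=0.8,
                                         kappa_music=0.8, power_ratio=3.0),
        (13, "theta"): synthgen.Coupling(seed_channel=8, kappa_speech=0.8,
                                         kappa_music=0.0, power_ratio=3.0),
        (14, "theta"): synthgen.Coupling(seed_channel=8, kappa_speech=0.0,
                                         kappa_music=0.8, power_ratio=3.0),
    }
    regions = [f"region_{i % 4}" for i in range(channels_per_patient)]
    return synthgen.CohortConfig(
        n_patients=n_patients,
        channels_per_patient=channels_per_patient,
        run_durations=run_durations,
        category_map=category_map,
        trf_channels=trf_channels,
        coupling_map=coupling_map,
        artifact_spec=synthgen.ArtifactSpec(channel_fraction=0.08,
                                            epoch_fraction=0.05),
        region_labels=regions,
        rng_seed=seed,
    )


def null_cohort_config(seed: int = 0, n_channels: int = 16,
                       duration: float = 100.0) -> synthgen.CohortConfig:
    """A no-effect cohort: pure 1/f background in every run.  Used for
    false-positive calibration of the significance machinery."""
    return synthgen.CohortConfig(
        n_patients=1,
        channels_per_patient=n_channels,
        run_durations={"speech": duration, "music": duration,
                       "baseline_tones": duration},
        rng_seed=seed,
    )


def taxonomy_cohort_config(
    seed: int = 0,
    n_patients: int = 6,
    channels_per_patient: int = 80,
    d: float = 1.5,
    duration: float = 515.0,
) -> synthgen.CohortConfig:
    """Recovery cohort: random shared/preferred/selective assignments at
    effect size ``d`` across all six bands, >=100 epochs per condition."""
    cat_map = synthgen.random_category_map(
        channels_per_patient, spectral.DEFAULT_BANDS.names, seed=seed + 1, d=d
    )
    return synthgen.CohortConfig(
        n_patients=n_patients,
        channels_per_patient=channels_per_patient,
        run_durations={"speech": duration, "music": duration,
                       "baseline_tones": duration},
        category_map=cat_map,
        rng_seed=seed,
    )


def model_comparison_cohort_config(seed: int = 0) -> synthgen.CohortConfig:
    """Cohort for the four-model TRF comparison: six channels per patient
    carry peakRate-driven LF responses with encoding strengths spanning the
    weak-to-strong range seen in cortex (holdout r roughly 0.1-0.7)."""
    k = tuple(synthgen.default_trf_kernel())
    snrs = {2: -18.0, 3: -15.0, 4: -12.0, 5: -9.0, 6: -5.0, 7: 0.0}
    trf_ch = {
        c: synthgen.TRFChannelSpec(kernel=k, feature="peakRate", snr_db=s)
        for c, s in snrs.items()
    }
    return synthgen.CohortConfig(
        n_patients=6,
        channels_per_patient=12,
        run_durations={"speech": 100.0, "music": 100.0, "baseline_tones": 20.0},
        trf_channels=trf_ch,
        rng_seed=seed,
    )


def _preprocess_patient(recordings: dict, epoch_length: float):
    """Channel mask (intersection over conditions) + per-condition epochs."""
    masks = []
    for rec in recordings.values():
        hfa = pre.hfa_amplitude(rec)
        masks.append(pre.detect_artifact_channels(rec, hfa))
    channel_mask = np.logical_and.reduce(masks)
    epochsets = {}
    for cond, rec in recordings.items():
        es = pre.epoch(rec, epoch_length)
        es.channel_mask &= channel_mask
        es.epoch_mask = pre.detect_artifact_epochs(es)
        epochsets[cond] = es
    return channel_mask, epochsets


def _classify_patient(bandpowers: dict, scheme, alpha, n_perm, seed_seq,
                      channels) -> pd.DataFrame:
    base_key = next(k for k in bandpowers if k.startswith("baseline"))
    frames = []
    children = seed_seq.generate_state(len(scheme.names))
    for i, band in enumerate(scheme.names):
        df = stats.categorize_channels(
            bandpowers["speech"],
            bandpowers["music"],
            bandpowers[base_key],
            band=band,
            direction="both",
            alpha=alpha,
            n_perm=n_perm,
            seed=int(children[i] % (2**31)),
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["region"] = [channels[c].region for c in out["channel"]]
    return out


def _trf_patient(recordings: dict, stimuli: dict, lambda_grid, alpha,
                 auditory_channels) -> dict:
    """Four-model TRF comparison for one patient.

    Returns per-model, per-domain score tables plus the per-model union
    percentage of significantly encoding channels.
    """
    fs = recordings["speech"].sample_rate
    features, targets = {}, {}
    for cond in ("speech", "music"):
        stim = stimuli[cond]
        env = stim.envelope
        features[(cond, "envelope")] = trf.envelope_feature(env, source=cond)
        features[(cond, "peakRate")] = trf.peak_rate(env)
        data = recordings[cond].data
        targets[(cond, "LF")] = trf.lf_target(data, fs)
        targets[(cond, "HFa")] = trf.hfa_target(data, fs)
        n = min(
            len(features[(cond, "envelope")].series),
            targets[(cond, "LF")].series.shape[1],
        )
        for kind in ("envelope", "peakRate"):
            f = features[(cond, kind)]
            features[(cond, kind)] = trf.StimulusFeature(f.kind, f.series[:n], f.rate)
        for kind in ("LF", "HFa"):
            t = targets[(cond, kind)]
            targets[(cond, kind)] = trf.NeuralTarget(t.kind, t.series[:, :n], t.rate)

    scores = {}
    percents = {}
    for feat_kind in ("envelope", "peakRate"):
        for targ_kind in ("LF", "HFa"):
            model_name = f"{feat_kind}+{targ_kind}"
            lam = trf.cross_validate_lambda(
                features[("speech", feat_kind)],
                targets[("speech", targ_kind)],
                channels=auditory_channels,
                lambda_grid=lambda_grid,
            )
            per_domain = {}
            for cond in ("speech", "music"):
                per_domain[cond] = trf.score_trf(
                    features[(cond, feat_kind)], targets[(cond, targ_kind)], lam
                )
            scores[model_name] = per_domain
            percents[model_name] = trf.significant_fraction(
                per_domain["speech"], per_domain["music"], alpha
            )
    return {"scores": scores, "percent_significant": percents}


def _connectivity_patient(epochsets: dict, seed_channel: int, scheme, n_surr,
                          n_perm, alpha, seed_seq, channels) -> pd.DataFrame:
    frames = []
    children = seed_seq.generate_state(len(scheme.names) * 3)
    i = 0
    for band in scheme.names:
        rngs = [np.random.default_rng(int(children[i + k] % (2**31))) for k in range(3)]
        i += 3
        rs = conn.surrogate_null(
            epochsets["speech"], seed_channel, band, n_surr=n_surr, seed=rngs[0],
            alpha=alpha, scheme=scheme,
        )
        rm = conn.surrogate_null(
            epochsets["music"], seed_channel, band, n_surr=n_surr, seed=rngs[1],
            alpha=alpha, scheme=scheme,
        )
        diff = conn.coherence_difference_test(
            epochsets["speech"], epochsets["music"], seed_channel, band,
            n_perm=n_perm, seed=rngs[2], scheme=scheme,
        )
        cats = conn.categorize_connections(rs, rm, diff, alpha=alpha)
        cats.insert(1, "band", band)
        frames.append(cats)
    out = pd.concat(frames, ignore_index=True)
    out["region"] = [channels[c].region for c in out["channel"]]
    return out


def _summary(power_categories: pd.DataFrame, connection_categories: pd.DataFrame | None,
             scheme) -> dict:
    """Per-band percentages of shared/selective/preferred responses among
    significant channels (the pie-chart numbers)."""

    def _pie(df, value_col="category"):
        out = {}
        for band, g in df.groupby("band", observed=True):
            cats = g[value_col].astype(str)
            sig = cats[cats != "none"]
            n_all = len(cats)
            if len(sig) == 0:
                out[band] = {"pct_significant": 0.0}
                continue
            shared = (sig.isin(["shared", "inconsistent"])).mean()
            selective = sig.str.startswith("selective").mean()
            preferred = sig.str.startswith("preferred").mean()
            out[band] = {
                "pct_significant": 100.0 * len(sig) / n_all,
                "pct_shared": 100.0 * shared,
                "pct_selective": 100.0 * selective,
                "pct_preferred": 100.0 * preferred,
            }
        return out

    summary = {"power": _pie(power_categories)}
    if connection_categories is not None and len(connection_categories):
        summary["connectivity"] = _pie(connection_categories)
    return summary


def run_all(config: RunConfig, out_dir=None, auditory_channels=None) -> dict:
    """Execute the full pipeline on a synthetic cohort.

    Returns a bundle of result tables (``power_categories``, ``trf``,
    ``model_comparison``, ``connection_categories``, ``selectivity_traces``,
    ``prevalence``, ``summary``, ``truth``) and, when ``out_dir`` is given,
    writes them as TSV/JSON with fixed float formatting (deterministic
    bytes under a fixed seed).

    ``auditory_channels`` designates the channels used for ridge-parameter
    cross-validation; it defaults to the cohort's ground-truth TRF channels
    (the functional analog of auditory-cortex channels), or all channels if
    none are defined.
    """
    cohort_cfg = dataclasses.replace(config.cohort, rng_seed=config.seed)
    scheme = cohort_cfg.band_scheme
    root = np.random.SeedSequence(config.seed)
    ss_classify, ss_conn = root.spawn(2)
    classify_children = ss_classify.spawn(cohort_cfg.n_patients)
    conn_children = ss_conn.spawn(cohort_cfg.n_patients)

    if auditory_channels is None:
        auditory_channels = sorted(cohort_cfg.trf_channels) or None

    power_frames, conn_frames = [], []
    trf_percents, trf_scores = {}, {}
    truth = None
    patient_channels = {}
    for pi, (pid, recordings, truth, stimuli) in enumerate(
        synthgen.iter_cohort(cohort_cfg)
    ):
        patient_channels[pid] = recordings["speech"].channels
        channel_mask, epochsets = _preprocess_patient(recordings, config.epoch_length)

        if config.do_spectral:
            bandpowers = {
                cond: spectral.band_power(es, scheme) for cond, es in epochsets.items()
            }
            cats = _classify_patient(
                bandpowers, scheme, config.alpha, config.n_perm,
                classify_children[pi], recordings["speech"].channels,
            )
            cats.insert(0, "patient", pid)
            power_frames.append(cats)

        seed_channel = None
        if config.do_trf:
            tr = _trf_patient(recordings, stimuli, config.lambda_grid, config.alpha,
                              auditory_channels)
            trf_percents[pid] = tr["percent_significant"]
            trf_scores[pid] = tr["scores"]

        if config.do_connectivity:
            win = "peakRate+LF"
            if config.do_trf:
                sp = trf_scores[pid][win]["speech"].copy()
                mu = trf_scores[pid][win]["music"].copy()
                keep = channel_mask[sp["channel"].to_numpy()]
                seed_channel = trf.select_seed(sp[keep], mu[keep], config.alpha)
            if seed_channel is None and cohort_cfg.trf_channels:
                cand = sorted(cohort_cfg.trf_channels)[0]
                seed_channel = cand if channel_mask[cand] else None
            if seed_channel is None:
                warnings.warn(
                    f"{pid}: no significant encoding channel; patient excluded "
                    "from connectivity",
                    RuntimeWarning,
                    stacklevel=2,
                )
            else:
                ccats = _connectivity_patient(
                    epochsets, seed_channel, scheme, config.n_surr, config.n_perm,
                    config.alpha, conn_children[pi], recordings["speech"].channels,
                )
                ccats.insert(0, "patient", pid)
                ccats.insert(2, "seed_channel", seed_channel)
                conn_frames.append(ccats)

    bundle: dict = {"truth": truth, "config": config}
    power_categories = (
        pd.concat(power_frames, ignore_index=True) if power_frames else pd.DataFrame()
    )
    connection_categories = (
        pd.concat(conn_frames, ignore_index=True) if conn_frames else None
    )
    bundle["power_categories"] = power_categories
    bundle["connection_categories"] = connection_categories

    if config.do_trf and trf_percents:
        pct = pd.DataFrame(trf_percents).T.sort_index()
        if len(pct) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                comparison = trf.compare_models(pct)
        else:
            comparison = {"winner": None, "decisive": False,
                          "pairwise": pd.DataFrame(), "means": pct.mean()}
        bundle["trf_percent_significant"] = pct
        bundle["model_comparison"] = comparison
        bundle["trf_scores"] = trf_scores

    if config.do_aggregate and len(power_categories):
        traces = []
        for domain in ("speech", "music"):
            for band in scheme.names:
                tr_df = agg.cross_frequency_selectivity(
                    power_categories, domain, band,
                    band_order=agg.default_band_order(band, scheme.names),
                )
                tr_df.insert(0, "domain", domain)
                tr_df.insert(1, "start_band", band)
                traces.append(tr_df)
        bundle["selectivity_traces"] = pd.concat(traces, ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bundle["prevalence"] = agg.population_prevalence(power_categories)

    bundle["summary"] = _summary(power_categories, connection_categories, scheme)

    if out_dir is not None:
        _write_bundle(bundle, out_dir, config)
    return bundle


def _write_bundle(bundle: dict, out_dir, config: RunConfig) -> None:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def _tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format=_FLOAT_FMT,
                  lineterminator="\n")

    _tsv(bundle["power_categories"], "power_categories.tsv")
    if bundle.get("connection_categories") is not None:
        _tsv(bundle["connection_categories"], "connection_categories.tsv")
    if "trf_percent_significant" in bundle:
        pct = bundle["trf_percent_significant"].reset_index(names="patient")
        _tsv(pct, "trf_percent_significant.tsv")
        pw = bundle["model_comparison"].get("pairwise")
        if pw is not None and len(pw):
            _tsv(pw, "model_comparison.tsv")
    if "selectivity_traces" in bundle:
        _tsv(bundle["selectivity_traces"], "selectivity_traces.tsv")
        _tsv(bundle["prevalence"], "prevalence.tsv")
    (out / "summary.json").write_text(
        json.dumps(bundle["summary"], indent=1, sort_keys=True)
    )
    (out / "run_config.json").write_text(config.to_json())
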
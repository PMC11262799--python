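#!/usr/bin/env python
"""Generate the desk-scale demonstration cohort and persist it.

Two synthetic patients, 24 bipolar-like channels each, three runs
(speech, music, tone baseline).  Channels 0-7 carry known band-power
effects, channel 8 encodes the speech/music peakRate, channels 12-14 are
theta-coupled to it, and mild artifacts are injected.  Recordings go to
scratch/ (HDF5 + WAV are binary); the ground-truth manifest is copied to
results/ as JSON.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from neuroshare import pipeline, synthgen  # noqa: E402

SEED = 7
OUT = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "cohort"
RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = pipeline.demo_cohort_config(seed=SEED)
    recordings, truth, stimuli = synthgen.generate_cohort(cfg)
    # regenerate the stimuli with audio for the WAV files
    stimuli_audio = {
        cond: synthgen.generate_stimulus(
            cfg.run_durations[cond], domain=cond, seed=SEED, include_audio=True
        )
        for cond in ("speech", "music")
    }
    synthgen.save_cohort(recordings, truth, OUT, stimuli=stimuli_audio)
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "ground_truth.json").write_text(truth.to_json())

    n_rec = len(recordings)
    durs = {c: r.duration for (p, c), r in recordings.items() if p == "P00"}
    print(f"wrote {n_rec} recordings for {cfg.n_patients} patients to {OUT}")
    print(f"run durations (s): {json.dumps(durs)}")
    print(f"injected effects: {len(cfg.category_map)} band-power, "
          f"{len(cfg.trf_channels)} TRF, {len(cfg.coupling_map)} couplings")
    print(f"artifact channels per patient: {truth.artifact_channels}")


if __name__ == "__main__":
    main()
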
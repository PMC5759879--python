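#!/usr/bin/env python
"""Simulate a trace-level screening cohort and write the raw recordings.

Generates a small test-retest cohort (markers + CoP at 30 Hz, two
occasions, three trials per task) and writes the long-format marker CSV,
the CoP CSV, the subject table and the config under scratch/raw/.
These files are the input to 02_extract_panels.py.
"""

from pathlib import Path

from posturometry import io
from posturometry.synthetic import SimulationConfig, simulate_reliability_dataset

OUT = Path(__file__).resolve().parent.parent / "scratch" / "raw"


def main() -> None:
    cfg = SimulationConfig(n_subjects=6, granularity="trace",
                           marker_noise_sd=0.2, cop_noise_sd=0.05,
                           master_seed=20260924)
    data = simulate_reliability_dataset(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    trials = [t for s in data.sessions for t in s.trials]
    io.write_trials_csv(trials, OUT / "markers.csv", OUT / "cop.csv")
    io.write_config(cfg, OUT / "simulation_config.yaml")
    (OUT / "heights.csv").write_text(
        "subject,height_cm,group\n" + "".join(
            f"{p.subject_id},{p.height:.3f},{p.group}\n" for p in data.cohort))
    print(f"simulated {len(data.cohort)} subjects x 2 occasions x "
          f"{cfg.n_trials} trials/task -> {len(trials)} trials")
    print(f"wrote {OUT}/markers.csv, cop.csv, heights.csv, simulation_config.yaml")


if __name__ == "__main__":
    main()
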
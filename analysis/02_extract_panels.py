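#!/usr/bin/env python
"""Extract the 18 screening endpoints from the simulated raw recordings.

Reads scratch/raw/ (written by 01_simulate_cohort.py), runs the full
kinematic chain — 7 Hz zero-phase Butterworth filtering, single-leg
window detection from the swinging ankle, convex-hull sway area,
95th-percentile sway velocities, posture geometry, side-bend depths —
with the trial-selection rule (third trial preferred, then second, then
first) and writes the tidy panel table to results/panels.csv.
"""

from pathlib import Path

import pandas as pd

from posturometry import io
from posturometry.kinematics import extract_panel

ROOT = Path(__file__).resolve().parent.parent / "results"
RAW = Path(__file__).resolve().parent.parent / "scratch" / "raw"


def main() -> None:
    raw = RAW
    trials = io.read_trials_csv(raw / "markers.csv", raw / "cop.csv")
    heights = pd.read_csv(raw / "heights.csv").set_index("subject")["height_cm"]
    sessions: dict[tuple, list] = {}
    for t in trials:
        sessions.setdefault((t.subject, t.occasion, t.device), []).append(t)
    panels = []
    for (subject, occasion, device), ts in sorted(sessions.items()):
        panel = extract_panel(ts, float(heights[subject]))
        panel.subject, panel.occasion, panel.device = subject, occasion, device
        panels.append(panel)
    io.write_panels_csv(panels, ROOT / "panels.csv")
    n_missing = sum(len(p.missing) for p in panels)
    print(f"extracted {len(panels)} panels "
          f"({len(panels) * 18} endpoints, {n_missing} missing)")
    print(f"wrote {ROOT}/panels.csv")


if __name__ == "__main__":
    main()
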
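#!/usr/bin/env python
"""End-to-end synthetic multi-species experiment.

Emulates a three-colour QD tracking experiment on two dishes of cells —
untreated and cholesterol-depleted — with per-species diffusion mixtures
at the magnitudes seen for membrane species of three anchoring classes
(lipid cluster ~0.013, GPI-anchored ~0.074, transmembrane ~0.038 µm²/s;
depletion lowers and homogenises all three).  Each channel is simulated
with localization noise and QD blinking, then pushed through the full
pipeline: cross-channel duplicate removal → blink-gap re-linking →
per-trajectory MSD fitting (lags 1–5).

Writes per-population fitted-D tables (results/fits_<species>_<cond>.csv)
and a trajectory-and-diffusion summary table
(results/population_summary.csv) with n, <N>, mean ± s.e.m. and MAD.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from qdspt.core import (MICROMETERS, PIXELS, AcquisitionMeta, convert_units)
from qdspt.linking import (RelinkParams, relink_trajectories,
                           remove_cross_channel_duplicates)
from qdspt.msd import fit_trajectory
from qdspt.popstats import summarize_population
from qdspt.simulate import SpeciesSpec, simulate_multispecies

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0
N_PARTICLES = 120
N_FRAMES = 1200

META = AcquisitionMeta(frame_interval=0.040, pixel_size=0.107,
                       localization_precision=0.025)

# (species, condition) -> mixture of (D um^2/s, weight); untreated
# populations are broader two-component mixtures, depletion narrows and
# slows them.
CONDITIONS: dict[str, list[SpeciesSpec]] = {
    "untreated": [
        SpeciesSpec("GM1", ((0.008, 0.5), (0.018, 0.5)),
                    n_particles=N_PARTICLES),
        SpeciesSpec("CD59", ((0.030, 0.5), (0.118, 0.5)),
                    n_particles=N_PARTICLES),
        SpeciesSpec("EGFR", ((0.020, 0.5), (0.056, 0.5)),
                    n_particles=N_PARTICLES),
    ],
    "mbCD": [
        SpeciesSpec("GM1", ((0.006, 0.5), (0.010, 0.5)),
                    n_particles=N_PARTICLES),
        SpeciesSpec("CD59", ((0.024, 0.5), (0.044, 0.5)),
                    n_particles=N_PARTICLES),
        SpeciesSpec("EGFR", ((0.012, 0.5), (0.024, 0.5)),
                    n_particles=N_PARTICLES),
    ],
}


def run_condition(specs, seed: int, condition: str) -> list[dict]:
    tracksets, _ = simulate_multispecies(specs, META, n_frames=N_FRAMES,
                                         seed=seed)
    cleaned = remove_cross_channel_duplicates(
        [convert_units(ts, PIXELS) for ts in tracksets.values()])
    rows = []
    for ts in cleaned:
        name = ts.trajectories[0].channel
        merged = relink_trajectories(ts, RelinkParams())   # >50-step cut
        merged_um = convert_units(merged, MICROMETERS)
        fits, steps = [], []
        for t in merged_um:
            fits.append(fit_trajectory(t, META).D5)
            steps.append(t.n_displacements)
        pd.DataFrame({"trajectory_id": [t.id for t in merged_um],
                      "n_displacements": steps,
                      "D5_um2_s": fits}).to_csv(
            RESULTS / f"fits_{name}_{condition}.csv", index=False)
        s = summarize_population(fits, species=name, condition=condition,
                                 n_steps=steps)
        rows.append({
            "species": name, "condition": condition, "n_traj": s.n_traj,
            "mean_steps": round(s.mean_steps), "mean_D5": s.mean_D,
            "sem_D5": s.sem_D, "mad_D5": s.mad_D,
        })
    return rows


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for i, (condition, specs) in enumerate(CONDITIONS.items()):
        rows += run_condition(specs, SEED + i, condition)
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "population_summary.csv", index=False)
    print("Trajectory and diffusion data (synthetic, per population):\n")
    print(summary.to_string(index=False,
                            float_format=lambda v: f"{v:.4g}"))
    print("\nEach population keeps only re-linked trajectories with more "
          "than 50 displacements; D5 from weighted MSD fits at lags 1-5.")


if __name__ == "__main__":
    main()
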
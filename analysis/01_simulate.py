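"""Generate the synthetic rating experiment.

Builds the default study design (15 materials x 30 segments in 5 sets of 90,
10 attributes, 10 raters per set/attribute cell, 3 repetitions), the
calibrated ground truth, and a full simulated rating table, and writes them
under results/run/.
"""

from pathlib import Path

import matsig as ms
from matsig.io import write_ratings, write_truth

OUT = Path(__file__).resolve().parents[1] / "results" / "run"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = ms.default_design()
    counts = ms.design_counts(design)
    print(f"design: {design.n_materials} materials x {design.segments_per_material} "
          f"segments = {counts.n_stimuli} stimuli in {design.n_sets} sets; "
          f"{counts.n_cells} cells x {design.raters_per_cell} raters x "
          f"{counts.trials_per_task} trials = {counts.total_judgments} judgments")

    truth = ms.default_truth(design)
    intra, inter = ms.expected_consistency(truth, design)
    print(f"calibrated truth: sigma_taste={truth.sigma_taste:.2f}, "
          f"sigma_noise={truth.sigma_noise:.2f}; expected intra r={intra:.3f}, "
          f"inter r={inter:.3f}")

    stimuli = ms.partition_sets(design, SEED)
    records = ms.simulate_ratings(design, truth, SEED + 1, stimuli=stimuli)
    (OUT / "design.json").write_text(design.to_json())
    stimuli.to_csv(OUT / "stimuli.csv", index=False)
    write_ratings(records, OUT / "ratings.csv")
    write_truth(truth, OUT / "truth.json")
    print(f"wrote {len(records)} rating records to {OUT / 'ratings.csv'}")


if __name__ == "__main__":
    main()
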
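"""Generate a synthetic paired app/office cohort under the default
study conditions and write both exports to results/synthetic/.

The default configuration emulates the registry validation setting:
676 families observed for 16 months, with the acute-visit,
app-recording and past-report probabilities that reproduce the
cross-registry episode accounting.
"""

from __future__ import annotations

import sys
from pathlib import Path

from feverdq.io import write_app_data, write_office_data
from feverdq.simulate import GeneratorConfig, generate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    cfg = GeneratorConfig(seed=SEED)
    app, office, truth = generate(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_app_data(app, OUT / "app_profiles.csv", OUT / "app_entries.csv")
    write_office_data(office, OUT / "office_patients.csv", OUT / "office_visits.csv")
    truth.episodes.to_csv(OUT / "ground_truth_episodes.csv", index=False)
    print(f"seed {SEED}: {len(app.profiles)} app profiles, {len(app.entries)} diary entries")
    print(f"  true episodes: {len(truth.episodes)}; app-recorded {truth.n_app_episodes}, "
          f"office-recorded {truth.n_office_episodes}, in both {truth.n_paired}")
    print(f"  wrote exports + ground truth under {OUT}")


if __name__ == "__main__":
    main()
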
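"""Simulate the default cohort and write its dataset tables.

94 children, ~half per condition, 19/94 already-knowers; a 10-trial
disambiguating pretest (no feedback) and a 30-trial learning phase
(9 congruent, then 21 disambiguating trials whose outcomes follow the Size
rule). Pupil change couples to the model-side KL divergence in the
Prediction condition only.

Writes children/trials/responses/pupil CSVs under results/cohort/.
"""

import argparse
from pathlib import Path

from pupilsurprise.io import cohort_to_dataset, write_dataset
from pupilsurprise.stimuli import Congruence, classify_trial_congruence
from pupilsurprise.synthetic import generate_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    cohort = generate_cohort(seed=args.seed)
    write_dataset(cohort_to_dataset(cohort), args.out)

    counts = cohort.children["condition"].value_counts()
    congruent = sum(
        classify_trial_congruence(t) is Congruence.CONGRUENT
        for t in cohort.learning_trials
    )
    print(f"cohort: {len(cohort.children)} children "
          f"({counts['prediction']} prediction / {counts['postdiction']} postdiction)")
    print(f"learning phase: {len(cohort.learning_trials)} trials "
          f"({congruent} congruent, "
          f"{len(cohort.learning_trials) - congruent} disambiguating)")
    print(f"archetypes: {cohort.children['archetype'].value_counts().to_dict()}")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
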
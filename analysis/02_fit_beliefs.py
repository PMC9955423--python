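"""Infer pretest priors and run Bayesian belief trajectories for every child.

Stage 1 infers each child's prior over the four rules (Size, Material, Mass,
Random) from their pretest responses; Stage 2 updates it against the
learning-phase outcomes. Convergence onto the Size rule is declared when its
posterior odds against the strongest competitor reach 10.

Reads results/cohort/, writes beliefs.csv and convergence.csv to results/.
"""

import argparse
from pathlib import Path

from pupilsurprise.io import read_tables, write_table
from pupilsurprise.pipeline import model_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    modeled = model_dataset(read_tables(args.data))
    write_table(modeled.beliefs, args.out / "beliefs.csv", "beliefs")
    write_table(modeled.convergence, args.out / "convergence.csv", "convergence")

    n_learners = len(modeled.partition["learners"])
    n_knowers = len(modeled.partition["already_knowers"])
    conv = modeled.convergence
    learners = conv[~conv["already_knower"]]
    converged = learners[
        (learners["convergence_trial"] >= 1) & (learners["convergence_trial"] <= 19)
    ]
    print(f"pretest split: {n_learners} learners, {n_knowers} already-knowers")
    print(f"learners converged onto Size by trial 19: "
          f"{len(converged)}/{n_learners} ({len(converged) / n_learners:.0%})")
    done = conv[conv["convergence_trial"] >= 1]
    print(f"convergence trial quartiles (all converged children): "
          f"{done['convergence_trial'].quantile([0.25, 0.5, 0.75]).to_dict()}")


if __name__ == "__main__":
    main()
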
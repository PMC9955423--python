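"""Compute trial-by-trial surprise estimates and contrast the two accounts.

Per trial: Shannon information (-log marginal outcome probability under the
pre-update beliefs), KL divergence (posterior vs prior), and the bounded
Jensen-Shannon divergence. Also prints the strong-vs-mixed prior regime
where the two accounts disagree: a near-certain Mass believer gets high SI
but low KLD on a mild conflict trial; a Size/Mass-mixed believer the
reverse.

Reads results/cohort/, writes surprise.csv to results/.
"""

import argparse
from pathlib import Path

import numpy as np
from scipy import stats

from pupilsurprise.belief import BeliefState
from pupilsurprise.io import read_tables, write_table
from pupilsurprise.pipeline import model_dataset
from pupilsurprise.stimuli import Direction, Phase, Sphere, Trial
from pupilsurprise.surprise import kl_divergence, shannon_information


def regime_table() -> str:
    trial = Trial(1, Sphere(1.0, 8.0), Sphere(3.0, 0.25), Phase.LEARNING,
                  Direction.RIGHT)
    lik = np.array([0.9, 0.05, 0.05, 1 / 3])
    lines = ["prior profile       SI (nats)  KLD (nats)"]
    for name, prior in (
        ("mass-dominant", np.array([0.01, 0.01, 0.97, 0.01])),
        ("size/mass mixed", np.array([0.45, 0.05, 0.45, 0.05])),
    ):
        si = shannon_information(BeliefState(prior), trial, Direction.RIGHT, 0.1)
        post = prior * lik / float(prior @ lik)
        kld = kl_divergence(post, prior)
        lines.append(f"{name:<19} {si:9.4f}  {kld:9.4f}")
    return "\n".join(lines)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    modeled = model_dataset(read_tables(args.data))
    write_table(modeled.surprise, args.out / "surprise.csv", "surprise")

    s = modeled.surprise
    print("surprise regime contrast on a mild conflict trial "
          "(likelihoods 0.9 / 0.05 / 0.05 / 1/3):")
    print(regime_table())
    print()
    print(f"cohort surprise: mean SI {s['si'].mean():.4f} nats, "
          f"mean KLD {s['kld'].mean():.4f} nats")
    print(f"trial-level Pearson r(SI, KLD) = "
          f"{stats.pearsonr(s['si'], s['kld']).statistic:.3f}")
    print(f"Spearman rho(JSD, KLD) = "
          f"{stats.spearmanr(s['jsd'], s['kld']).statistic:.4f} "
          "(the bounded divergence tracks KLD almost perfectly)")


if __name__ == "__main__":
    main()
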
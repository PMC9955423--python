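"""Correlate surprise estimates with pupil responses per condition and scope.

The Condition (Prediction, Postdiction) x Estimate (SI, KLD) grid of
trial-level Pearson correlations, tested against the Bonferroni-corrected
alpha 0.05/4 = 0.0125, for four scopes: all trials, learners only,
already-knowers only, and the critical learning trials (10-19). Each grid
carries a Fisher r-to-z comparison of the KLD correlation between
conditions and a Steiger comparison of KLD vs SI within Prediction.

Reads results/cohort/, writes results_grid.csv and comparisons.csv.
"""

import argparse
from pathlib import Path

from pupilsurprise.config import PipelineConfig
from pupilsurprise.io import read_tables, write_table
from pupilsurprise.pipeline import analysis_tables, model_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    modeled = model_dataset(read_tables(args.data))
    grid_df, comp_df, _, grids = analysis_tables(modeled, PipelineConfig())
    write_table(grid_df, args.out / "results_grid.csv", "results_grid")
    write_table(comp_df, args.out / "comparisons.csv", "comparisons")

    for scope, grid in grids.items():
        print(f"scope: {scope} (corrected alpha = {grid.alpha_corrected:g})")
        for (condition, estimate), cell in grid.cells.items():
            if cell is None:
                print(f"  {condition:<12} {estimate:<4} n/a")
                continue
            flag = "  *" if cell.p < grid.alpha_corrected else ""
            print(f"  {condition:<12} {estimate:<4} r({cell.df}) = {cell.r:+.3f}, "
                  f"p = {cell.p:.4g}{flag}")
        for comp in grid.comparisons:
            print(f"  {comp.contrast} ({comp.method}): z = {comp.z:.2f}, "
                  f"p = {comp.p:.4g}")
        print()


if __name__ == "__main__":
    main()
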
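"""CSV table readers/writers and dataset validation.

All tables are plain CSV with one leading comment line declaring the table
name and schema version (``# pupilsurprise table=<name> schema=1``). The
dataset consists of four input tables — children, trials, responses, pupil —
joined on (child_id, trial_index); the pipeline writes further derived
tables (beliefs, surprise, results_grid, comparisons) in the same format.

Externally supplied data (e.g., a reshaped export of the original study's
deposited tables) can be ingested by conforming to these schemas; the pupil
table holds already-baseline-corrected per-trial change scores, never raw
eye-tracker samples.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stimuli import Direction, Phase, Sphere, Trial

__all__ = ["SchemaError", "Dataset", "write_table", "read_table", "read_tables",
           "write_dataset", "cohort_to_dataset", "trials_from_frame"]

SCHEMA_VERSION = 1

#: Required columns per input table.
TABLE_COLUMNS = {
    "children": ["child_id", "condition", "archetype", "eta", "epsilon"],
    "trials": [
        "child_id", "phase", "trial_index",
        "left_size", "left_density", "left_weight",
        "right_size", "right_density", "right_weight", "outcome",
    ],
    "responses": ["child_id", "phase", "trial_index", "response"],
    "pupil": ["child_id", "trial_index", "pupil_change"],
}


class SchemaError(ValueError):
    """An input table violates its declared schema."""


def write_table(df: pd.DataFrame, path: Path | str, name: str) -> Path:
    """Write a table with its schema-version header comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _stdio.StringIO()
    buf.write(f"# pupilsurprise table={name} schema={SCHEMA_VERSION}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table not found: {path}")
    return pd.read_csv(path, comment="#", keep_default_na=False, na_values=[])


@dataclass
class Dataset:
    """Joined per-trial behavioural/pupil dataset.

    ``pupil`` may be None (behaviour-only analyses remain possible).
    """

    children: pd.DataFrame
    trials: pd.DataFrame
    responses: pd.DataFrame
    pupil: pd.DataFrame | None = None

    @property
    def child_ids(self) -> list[str]:
        return list(self.children["child_id"])


def _require_columns(df: pd.DataFrame, name: str, path: str) -> None:
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {name} table lacks columns {missing}")


def _validate_trials(trials: pd.DataFrame, path: str) -> None:
    for row in trials.itertuples():
        line = row.Index + 2  # header + 1-based
        outcome = str(row.outcome).strip()
        if outcome not in ("", "L", "E", "R"):
            raise SchemaError(
                f"{path}, line ~{line}, column 'outcome': value {row.outcome!r} "
                "not in {L, E, R, empty}"
            )
        is_learning = row.phase == "learning"
        if is_learning != bool(outcome):
            raise SchemaError(
                f"{path}, line ~{line}: outcome must be present exactly for "
                f"learning-phase trials (phase={row.phase!r}, outcome={outcome!r})"
            )
    for col in ("left_size", "left_density", "left_weight",
                "right_size", "right_density", "right_weight"):
        bad = trials.index[pd.to_numeric(trials[col], errors="coerce") <= 0]
        if len(bad):
            raise SchemaError(
                f"{path}, line ~{bad[0] + 2}, column {col!r}: values must be "
                "strictly positive"
            )


def read_tables(directory: Path | str, require_pupil: bool = False) -> Dataset:
    """Read and validate the four input tables from a directory.

    Schema violations name the file, approximate line and column; orphan
    pupil or response rows (no matching learning trial) are fatal join
    errors.
    """
    directory = Path(directory)
    frames = {}
    for name in ("children", "trials", "responses"):
        path = directory / f"{name}.csv"
        frames[name] = read_table(path)
        _require_columns(frames[name], name, str(path))
    pupil_path = directory / "pupil.csv"
    pupil = None
    if pupil_path.exists():
        pupil = read_table(pupil_path)
        _require_columns(pupil, "pupil", str(pupil_path))
    elif require_pupil:
        raise FileNotFoundError(f"required table not found: {pupil_path}")

    _validate_trials(frames["trials"], str(directory / "trials.csv"))

    bad = frames["responses"].index[
        ~frames["responses"]["response"].astype(int).isin([1, 2, 3, 4, 5])
    ]
    if len(bad):
        raise SchemaError(
            f"{directory / 'responses.csv'}, line ~{bad[0] + 2}, column "
            "'response': responses must be integers 1..5"
        )

    known_children = set(frames["children"]["child_id"])
    learning_keys = set(
        zip(
            frames["trials"].loc[frames["trials"]["phase"] == "learning", "child_id"],
            frames["trials"].loc[frames["trials"]["phase"] == "learning", "trial_index"].astype(int),
        )
    )
    if pupil is not None:
        for row in pupil.itertuples():
            key = (row.child_id, int(row.trial_index))
            if row.child_id not in known_children or key not in learning_keys:
                raise SchemaError(
                    f"{pupil_path}, line ~{row.Index + 2}: pupil row "
                    f"(child_id={row.child_id!r}, trial_index={row.trial_index}) "
                    "has no matching learning trial"
                )
    resp_children = set(frames["responses"]["child_id"]) - known_children
    if resp_children:
        raise SchemaError(
            f"{directory / 'responses.csv'}: unknown child_id values "
            f"{sorted(resp_children)[:5]}"
        )
    return Dataset(
        children=frames["children"],
        trials=frames["trials"],
        responses=frames["responses"],
        pupil=pupil,
    )


def write_dataset(dataset: Dataset, directory: Path | str) -> dict[str, Path]:
    directory = Path(directory)
    paths = {
        "children": write_table(dataset.children, directory / "children.csv", "children"),
        "trials": write_table(dataset.trials, directory / "trials.csv", "trials"),
        "responses": write_table(dataset.responses, directory / "responses.csv", "responses"),
    }
    if dataset.pupil is not None:
        paths["pupil"] = write_table(dataset.pupil, directory / "pupil.csv", "pupil")
    return paths


def cohort_to_dataset(cohort) -> Dataset:
    """Flatten a simulated cohort into the dataset schemas.

    The cohort shares one trial sequence; the trials table replicates it per
    child so the schema also accommodates per-child trial sets.
    """
    shared = cohort.trials
    per_child = []
    for child_id in cohort.children["child_id"]:
        block = shared.copy()
        block.insert(0, "child_id", child_id)
        per_child.append(block)
    return Dataset(
        children=cohort.children.copy(),
        trials=pd.concat(per_child, ignore_index=True),
        responses=cohort.responses.copy(),
        pupil=cohort.pupil.copy(),
    )


def trials_from_frame(block: pd.DataFrame) -> list[Trial]:
    """Materialize Trial objects from rows of the trials table (one child)."""
    out = []
    for row in block.itertuples():
        outcome = str(row.outcome).strip()
        out.append(
            Trial(
                trial_index=int(row.trial_index),
                left=Sphere(float(row.left_size), float(row.left_density), float(row.left_weight)),
                right=Sphere(float(row.right_size), float(row.right_density), float(row.right_weight)),
                phase=Phase(row.phase),
                outcome=Direction.from_letter(outcome) if outcome else None,
            )
        )
    return out
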
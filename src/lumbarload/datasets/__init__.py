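"""Bundled reference data.

Per-subject summary values from a nine-subject field-validation cohort of
physically active workers (medical disinfection, maintenance and industrial
cleaning jobs): movement-axis agreement between the ANN- and LSM-based
moment estimates on the 6 kg evaluation trials, the corresponding per-axis
RMSE values, and the task-level net-moment descriptives with checklist ranks
and Borg CR-10 ratings. Subject 6's 6 kg trial was unusable, so that column
is missing from the agreement and RMSE tables.

These tables are *inputs* for cohort-level aggregation (the raw recordings
are not redistributable); they are not produced by this package.
"""

from importlib import resources

import pandas as pd

__all__ = ["load_cohort_agreement", "load_cohort_rmse", "load_cohort_tasks"]

_SUBJECT_COLS = [f"s{i}" for i in range(1, 10)]


def _read(name: str, index_cols: list[str]) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh).set_index(index_cols)


def load_cohort_agreement() -> pd.DataFrame:
    """Movement-axis Pearson r / r² per subject (6 kg evaluation trials)."""
    return _read("cohort_agreement.csv", ["movement", "axis", "metric"])


def load_cohort_rmse() -> pd.DataFrame:
    """Per-movement, per-axis RMSE (Nm) between ANN and LSM estimates."""
    return _read("cohort_rmse.csv", ["movement", "axis"])


def load_cohort_tasks() -> pd.DataFrame:
    """Task-level ||M|| descriptives, checklist ranks and Borg ratings."""
    return _read("cohort_tasks.csv", ["task"])


def subject_columns() -> list[str]:
    return list(_SUBJECT_COLS)
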
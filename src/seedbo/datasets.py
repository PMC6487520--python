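"""Published germination-trial tables shipped with the package.

Two small CSVs: the 33 pea conditions (7 set-points each, one repetition,
N = 100 seeds) explored over 11 three-chamber trials, and the 11 radish
temperature schedules (N = 96 seeds, 6 repetitions) with per-schedule mean
and standard deviation of the score.  The pea ``y`` column is the observed
score (N_g + N_wg)/N; counts per run were not published except for the
narrated ones, so the table carries scores only.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_pea_trials", "load_radish_trials", "pea_ledger"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("seedbo.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_pea_trials() -> pd.DataFrame:
    """33 pea conditions with trial index and observed score y."""
    return _read("pea_trials.csv")


def load_radish_trials() -> pd.DataFrame:
    """11 radish temperature schedules with mean and SD of the score.

    Rows 1-4 are the constant-temperature (21-24 degC) initialization trials.
    """
    return _read("radish_trials.csv")


def pea_ledger():
    """The pea table as a standard trial ledger (row 1 is the expert guess)."""
    from .germination_score import append_ledger_row, empty_ledger, noise_floor_for
    from .parameter_space import pea_space

    space = pea_space()
    df = load_pea_trials()
    ledger = empty_ledger(space)
    for _, row in df.iterrows():
        prov = "expert" if row["index"] == 1 else "bo"
        ledger = append_ledger_row(
            ledger, space,
            trial_id=f"t{int(row['trial']):02d}",
            chamber_id=f"v{int(row['index'])}",
            provenance=prov,
            x_physical=[row[n] for n in space.names],
            y=float(row["y"]),
            noise_floor=noise_floor_for(float(row["y"]), 100, "global"),
        )
    return ledger
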
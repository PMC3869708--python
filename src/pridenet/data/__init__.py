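"""Packaged reference fixtures: the published 12-lion pride roster and its
11×11 coefficient-of-relationship matrix (the introduced, unrelated adult
male MI is absent from the published matrix and is filled with zeros by
consumers that need the full roster)."""

from importlib import resources

import pandas as pd

from ..observations import Individual, read_roster


def _path(name: str):
    return resources.files(__package__) / name


def ngamo_roster() -> tuple[Individual, ...]:
    """The 12-lion pride roster: MI + 6 adult females + 5 cubs."""
    with resources.as_file(_path("ngamo_roster.csv")) as p:
        return read_roster(p)


def ngamo_kinship() -> pd.DataFrame:
    """The published 11×11 relatedness matrix (MI absent)."""
    with resources.as_file(_path("ngamo_kinship.csv")) as p:
        df = pd.read_csv(p, index_col=0)
    df.index = [str(i) for i in df.index]
    df.columns = [str(c) for c in df.columns]
    return df.astype(float)
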
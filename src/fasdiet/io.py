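"""CSV/text readers and writers for the documented file dialects.

Conventions (all UTF-8, comma-delimited, headers required):

* predator CSV — first column predator id, remaining columns FA names;
* prey CSV — first column species label, remaining columns FA names;
* FA-set file — one FA name per line;
* CC CSV — columns ``fa_name,value``;
* fat CSV — columns ``species,value``.

FA names are matched order-insensitively but case-sensitively across
files; proportions vs percentages are auto-detected at validation time.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .compositions import InvalidCompositionError, close
from .prey import PreyDatabase

__all__ = [
    "read_predators", "read_prey", "read_faset", "read_cc", "read_fat",
    "write_diets", "write_faset",
]


def read_predators(path) -> pd.DataFrame:
    """Predator signature matrix indexed by predator id."""
    df = pd.read_csv(path)
    if df.shape[1] < 3:
        raise InvalidCompositionError(f"{path}: need an id column plus >= 2 FA columns")
    fa_cols = list(df.columns[1:])
    if len(set(fa_cols)) != len(fa_cols):
        raise InvalidCompositionError(f"{path}: duplicated FA columns")
    out = df.set_index(df.columns[0])
    out = pd.DataFrame(close(out.to_numpy(dtype=float)), index=out.index, columns=fa_cols)
    return out


def read_prey(path, species_col: str | None = None) -> PreyDatabase:
    return PreyDatabase.from_csv(path, species_col=species_col)


def read_faset(path, available=None) -> list[str]:
    """Ordered FA subset, one name per line; blank lines ignored."""
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not names:
        raise InvalidCompositionError(f"{path}: empty FA set")
    if len(set(names)) != len(names):
        raise InvalidCompositionError(f"{path}: duplicate FA names")
    if available is not None:
        unknown = [n for n in names if n not in set(available)]
        if unknown:
            raise InvalidCompositionError(f"{path}: FA name(s) not in the data: {unknown}")
    return names


def read_cc(path, fa_names=None) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise InvalidCompositionError(f"{path}: expected two columns (fa_name,value)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    if (s <= 0).any():
        raise InvalidCompositionError(f"{path}: calibration coefficients must be positive")
    if fa_names is not None:
        missing = [f for f in fa_names if f not in s.index]
        if missing:
            raise InvalidCompositionError(f"{path}: CC missing FA(s): {missing}")
        s = s.loc[list(fa_names)]
    return s


def read_fat(path, species=None) -> pd.Series:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise InvalidCompositionError(f"{path}: expected two columns (species,value)")
    s = pd.Series(df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str))
    if (s <= 0).any():
        raise InvalidCompositionError(f"{path}: fat contents must be positive")
    if species is not None:
        missing = [sp for sp in species if sp not in s.index]
        if missing:
            raise InvalidCompositionError(f"{path}: fat missing species: {missing}")
        s = s.loc[list(species)]
    return s


def write_diets(path, diets: pd.DataFrame, min_distance: pd.Series | None = None) -> None:
    out = diets.copy()
    if min_distance is not None:
        out["min_distance"] = min_distance
    out.index.name = out.index.name or "predator_id"
    out.to_csv(path)


def write_faset(path, names) -> None:
    Path(path).write_text("\n".join(names) + "\n")
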
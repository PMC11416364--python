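"""Dataset container and the documented CSV dialect.

One row per event; columns ``id, time_s, rate_ugps, conc_ugpl, age_y,
wgt_kg, bmi, gender, site``.  Dose rows carry ``rate_ugps`` (and an empty
``conc_ugpl``); observation rows the reverse.  Covariates are repeated on
every row and must be constant within an individual.  Files start with a
``# pksymreg-csv v1`` header comment; reading applies the dose-merge
preprocessing rule (1 s / 0.5 ug/s) unless disabled.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import FormatError
from .pk_model import ConcentrationSeries, DosingProfile
from .symreg_network import NormalizationSpec

__all__ = ["Individual", "Dataset", "read_dataset", "write_dataset", "DIALECT"]

DIALECT = "pksymreg-csv v1"
_COLUMNS = [
    "id", "time_s", "rate_ugps", "conc_ugpl",
    "age_y", "wgt_kg", "bmi", "gender", "site",
]


@dataclass(frozen=True)
class Individual:
    """Covariates, dosing profile and timed observations for one subject."""

    id: str
    age: float  # years
    weight: float  # kg
    bmi: float  # kg/m^2
    gender: str  # M / F
    site: str  # A / V
    dosing: DosingProfile
    observations: ConcentrationSeries

    def covariates(self) -> dict:
        return {
            "age": self.age, "weight": self.weight, "bmi": self.bmi,
            "gender": self.gender, "site": self.site,
        }


@dataclass(frozen=True)
class Dataset:
    individuals: list
    normalization: NormalizationSpec = field(default_factory=NormalizationSpec)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise FormatError("individual ids must be unique")
        for ind in self.individuals:
            if len(ind.dosing.event_times) < 1:
                raise FormatError(f"{ind.id}: needs at least one dose event")
            if len(ind.observations) < 1:
                raise FormatError(f"{ind.id}: needs at least one observation")
            if np.any(ind.observations.values <= 0):
                raise FormatError(
                    f"{ind.id}: observation concentrations must be > 0"
                )

    def __len__(self) -> int:
        return len(self.individuals)

    def subset(self, ids) -> "Dataset":
        keep = set(ids)
        return Dataset(
            individuals=[i for i in self.individuals if i.id in keep],
            normalization=self.normalization,
            provenance=self.provenance,
        )


def read_dataset(
    path, merge_doses: bool = True, spec: NormalizationSpec | None = None
) -> Dataset:
    """Parse a dialect CSV file into a Dataset.

    Dose events closer than 1 s / 0.5 ug/s are merged (the study's
    preprocessing) unless ``merge_doses`` is False.  Rows violating the
    dialect raise :class:`FormatError` naming the offending row.
    """
    from .synthetic_data import merge_close_doses  # deferred: avoids a cycle

    path = Path(path)
    raw = path.read_bytes()
    df = pd.read_csv(io.BytesIO(raw), comment="#", dtype={"id": str})
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")

    individuals = []
    for ind_id, g in df.groupby("id", sort=False):
        g = g.sort_values("time_s", kind="stable")
        for col, label in (("age_y", "age"), ("wgt_kg", "weight"), ("bmi", "bmi"),
                           ("gender", "gender"), ("site", "site")):
            if g[col].nunique() != 1:
                raise FormatError(
                    f"{path}: {label} varies within individual {ind_id} "
                    f"(rows {list(g.index[:5])})"
                )
        first = g.iloc[0]
        if str(first["gender"]) not in ("M", "F"):
            raise FormatError(
                f"{path}: unknown gender {first['gender']!r} for {ind_id}"
            )
        if str(first["site"]) not in ("A", "V"):
            raise FormatError(
                f"{path}: unknown site {first['site']!r} for {ind_id}"
            )
        dose_rows = g[g["rate_ugps"].notna()]
        obs_rows = g[g["conc_ugpl"].notna()]
        bad = obs_rows[obs_rows["conc_ugpl"] <= 0]
        if len(bad):
            raise FormatError(
                f"{path}: non-positive observation for {ind_id} at row "
                f"{int(bad.index[0])}"
            )
        if not len(dose_rows) or not len(obs_rows):
            raise FormatError(
                f"{path}: individual {ind_id} needs >=1 dose and >=1 observation"
            )
        dosing = DosingProfile(
            event_times=dose_rows["time_s"].to_numpy(dtype=float),
            rates=dose_rows["rate_ugps"].to_numpy(dtype=float),
        )
        if merge_doses:
            dosing = merge_close_doses(dosing)
        individuals.append(
            Individual(
                id=str(ind_id),
                age=float(first["age_y"]),
                weight=float(first["wgt_kg"]),
                bmi=float(first["bmi"]),
                gender=str(first["gender"]),
                site=str(first["site"]),
                dosing=dosing,
                observations=ConcentrationSeries(
                    times=obs_rows["time_s"].to_numpy(dtype=float),
                    values=obs_rows["conc_ugpl"].to_numpy(dtype=float),
                ),
            )
        )
    digest = hashlib.sha256(raw).hexdigest()[:16]
    return Dataset(
        individuals=individuals,
        normalization=spec or NormalizationSpec(),
        provenance=f"{path}#sha256:{digest}",
    )


def write_dataset(dataset: Dataset, path) -> None:
    """Write the dialect CSV; deterministic bytes for a fixed dataset."""
    rows = []
    for ind in dataset.individuals:
        base = {
            "id": ind.id, "age_y": ind.age, "wgt_kg": ind.weight,
            "bmi": ind.bmi, "gender": ind.gender, "site": ind.site,
        }
        for t, r in zip(ind.dosing.event_times, ind.dosing.rates):
            rows.append({**base, "time_s": t, "rate_ugps": r, "conc_ugpl": None})
        for t, c in zip(ind.observations.times, ind.observations.values):
            rows.append({**base, "time_s": t, "rate_ugps": None, "conc_ugpl": c})
    df = pd.DataFrame(rows, columns=_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(f"# {DIALECT}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
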
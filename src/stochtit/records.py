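"""Tidy container for per-pH, per-replicate titration data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TitrationRecord"]


@dataclass
class TitrationRecord:
    """Per-pH, per-replicate mean protonation (and charge) per site.

    Backed by a tidy :class:`pandas.DataFrame` with columns
    ``pH, replicate, site, mean_n, se, charge``; ``charge`` is the mean
    site charge (``mean_n`` plus the site's charge offset: -1 for acids,
    0 for bases).
    """

    data: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["pH", "replicate", "site", "mean_n", "se", "charge"]
        )
    )

    COLUMNS = ("pH", "replicate", "site", "mean_n", "se", "charge")

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    @classmethod
    def from_rows(cls, rows) -> "TitrationRecord":
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @property
    def empty(self) -> bool:
        return self.data.empty

    @property
    def ph_values(self) -> np.ndarray:
        return np.array(sorted(self.data["pH"].unique()))

    @property
    def sites(self) -> list[str]:
        return list(dict.fromkeys(self.data["site"]))

    def site_curve(self, site: str):
        """(pH, mean over replicates, per-replicate matrix) for one site."""
        sub = self.data[self.data["site"] == site]
        if sub.empty:
            raise KeyError(site)
        piv = sub.pivot_table(index="replicate", columns="pH", values="mean_n")
        ph = piv.columns.to_numpy(dtype=float)
        reps = piv.to_numpy(dtype=float)
        return ph, reps.mean(axis=0), reps

    def total_charge(self) -> pd.Series:
        """Replicate-averaged total charge per pH."""
        per_rep = self.data.groupby(["pH", "replicate"])["charge"].sum()
        return per_rep.groupby("pH").mean()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TitrationRecord":
        return cls(pd.read_csv(path, sep="\t"))

    def concat(self, other: "TitrationRecord") -> "TitrationRecord":
        return TitrationRecord(
            pd.concat([self.data, other.data], ignore_index=True)
        )
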
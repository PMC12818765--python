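"""Titration analytics: Hill fits, total charge curves, pI, benchmarking.

The per-site titration curve is modelled with the Hill equation in base 10,

    f(pH) = 1 / (1 + 10**(n * (pH - pKa)))

so that ``n = 1`` reduces to Henderson-Hasselbalch.  Standard errors of the
fitted parameters come from a leave-one-out jackknife over replicate
curves.  Benchmarking compares predicted against experimental pKa values,
with a structure-blind null model that assigns every residue its
residue-type reference value measured on alanine-based pentapeptides
(Ala2-X-Ala2) in water.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .records import TitrationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HillFit",
    "BenchmarkResult",
    "PENTAPEPTIDE_PKA",
    "hill_curve",
    "hill_fit",
    "total_titration_curve",
    "isoelectric_point",
    "calibrate_pkmod",
    "benchmark",
    "load_benchmark_table",
    "NoCrossingError",
    "AmbiguousCrossingError",
    "ExtrapolatedFitError",
]

#: Reference pKa values of each residue type in Ala-based pentapeptides in
#: water (NMR measurements on Ala2-X-Ala2 with capped termini); these are
#: the null-model predictions and the calibration targets for pK^mod.
PENTAPEPTIDE_PKA = {
    "Asp": 3.94,
    "Glu": 4.25,
    "His": 6.54,
    "Cys": 8.55,
    "Tyr": 9.84,
    "Lys": 10.40,
    "NTr": 8.00,
    "CTr": 3.67,
}


class NoCrossingError(ValueError):
    """Total charge curve never crosses zero on the grid."""


class AmbiguousCrossingError(ValueError):
    """Total charge curve crosses zero more than once."""


class ExtrapolatedFitError(ValueError):
    """A downstream step refused an extrapolated Hill fit."""


def hill_curve(ph, pka: float, hill_n: float = 1.0):
    """Hill-equation occupancy at the given pH values."""
    ph = np.asarray(ph, dtype=float)
    return 1.0 / (1.0 + 10.0 ** (hill_n * (ph - pka)))


@dataclass(frozen=True)
class HillFit:
    """Result of fitting the Hill equation to a titration curve.

    ``extrapolated`` is set when the curve does not bracket half-occupancy
    inside the fitted pH range (the midpoint is then an extrapolation);
    ``direction`` tags which side of the range the transition lies on
    (``"below_range"`` / ``"above_range"``) when it can be determined.
    """

    pka: float
    hill_n: float
    se_pka: float = math.nan
    se_hill: float = math.nan
    rss: float = math.nan
    extrapolated: bool = False
    direction: str | None = None
    n_replicates: int = 1


def _fit_single(ph, occ, fix_n: bool):
    """Bounded least squares on one mean curve."""
    ph = np.asarray(ph, dtype=float)
    occ = np.asarray(occ, dtype=float)
    p0_pka = float(ph[np.argmin(np.abs(occ - 0.5))])
    span = ph.max() - ph.min()
    lo_pka, hi_pka = ph.min() - 2 * span - 1, ph.max() + 2 * span + 1
    if fix_n:
        res = least_squares(
            lambda p: hill_curve(ph, p[0]) - occ,
            x0=[p0_pka], bounds=([lo_pka], [hi_pka]), xtol=1e-15, ftol=1e-15,
        )
        pka, n = float(res.x[0]), 1.0
    else:
        res = least_squares(
            lambda p: hill_curve(ph, p[0], p[1]) - occ,
            x0=[p0_pka, 1.0],
            bounds=([lo_pka, 0.05], [hi_pka, 20.0]),
            xtol=1e-15, ftol=1e-15,
        )
        pka, n = float(res.x[0]), float(res.x[1])
    rss = float(np.sum(res.fun**2))
    return pka, n, rss


def hill_fit(
    ph,
    mean_occupancy=None,
    replicates=None,
    fix_n: bool = False,
) -> HillFit:
    """Fit the Hill equation; jackknife errors over replicate curves.

    Either ``mean_occupancy`` (one curve) or ``replicates`` (list/array of
    per-replicate curves over the same pH grid; the mean curve is fitted
    and the jackknife refits leave one replicate out at a time) must be
    given.  Curves that stay on one side of half-occupancy are flagged
    ``extrapolated``; fully flat all-0/all-1 curves return a NaN pKa with a
    direction tag.
    """
    ph = np.asarray(ph, dtype=float)
    if replicates is not None:
        reps = np.asarray(replicates, dtype=float)
        if reps.ndim != 2 or reps.shape[1] != len(ph):
            raise ValueError("replicates must be (n_replicates, n_pH)")
        occ = reps.mean(axis=0)
        m = reps.shape[0]
    elif mean_occupancy is not None:
        occ = np.asarray(mean_occupancy, dtype=float)
        reps = None
        m = 1
    else:
        raise ValueError("need mean_occupancy or replicates")
    if len(ph) < 3:
        raise ValueError("need >= 3 pH points")

    spans = occ.min() < 0.5 < occ.max()
    flat_tol = 1e-3
    if occ.max() - occ.min() < flat_tol:  # no titration signal at all
        direction = "below_range" if occ.mean() < 0.5 else "above_range"
        return HillFit(
            math.nan, math.nan, extrapolated=True, direction=direction,
            n_replicates=m,
        )

    pka, n, rss = _fit_single(ph, occ, fix_n)
    extrapolated = (not spans) or not (ph.min() <= pka <= ph.max())
    direction = None
    if extrapolated:
        direction = "above_range" if pka > ph.max() else (
            "below_range" if pka < ph.min() else None
        )

    se_pka = se_n = math.nan
    if reps is not None and m >= 2:
        thetas = []
        for leave in range(m):
            sub = reps[np.arange(m) != leave].mean(axis=0)
            thetas.append(_fit_single(ph, sub, fix_n)[:2])
        thetas = np.asarray(thetas)
        bar = thetas.mean(axis=0)
        var = (m - 1) / m * np.sum((thetas - bar) ** 2, axis=0)
        se_pka, se_n = float(np.sqrt(var[0])), float(np.sqrt(var[1]))
    return HillFit(
        pka=pka, hill_n=n, se_pka=se_pka, se_hill=se_n, rss=rss,
        extrapolated=extrapolated, direction=direction, n_replicates=m,
    )


def total_titration_curve(record: TitrationRecord) -> pd.Series:
    """Replicate-averaged mean total charge per pH."""
    sets = record.data.groupby("pH")["site"].apply(lambda s: frozenset(s))
    if len(set(sets)) > 1:
        raise ValueError("site set differs across pH values")
    return record.total_charge()


def isoelectric_point(ph, charge) -> float:
    """pH of zero mean charge, by linear interpolation on the grid.

    Raises :class:`NoCrossingError` (with the curve's sign) if the charge
    never changes sign, and :class:`AmbiguousCrossingError` (listing all
    crossings) if it changes sign more than once.
    """
    ph = np.asarray(ph, dtype=float)
    q = np.asarray(charge, dtype=float)
    if len(ph) != len(q) or len(ph) < 2:
        raise ValueError("need matching pH/charge arrays with >= 2 points")
    crossings = []
    for k in range(len(q) - 1):
        if q[k] == 0.0:
            crossings.append(float(ph[k]))
        elif q[k] * q[k + 1] < 0:
            frac = q[k] / (q[k] - q[k + 1])
            crossings.append(float(ph[k] + frac * (ph[k + 1] - ph[k])))
    if q[-1] == 0.0:
        crossings.append(float(ph[-1]))
    if not crossings:
        side = "below grid" if q.mean() < 0 else "above grid"
        raise NoCrossingError(
            f"charge is {'all-negative' if q.mean() < 0 else 'all-positive'}; "
            f"pI {side}"
        )
    if len(crossings) > 1:
        raise AmbiguousCrossingError(f"multiple zero crossings at {crossings}")
    return crossings[0]


def calibrate_pkmod(
    fitted_pka: float, experimental_pka: float, current_pkmod: float
) -> float:
    """One calibration step of the model-compound pKa.

    The new pK^mod is shifted by the gap between the experimental pKa and
    the pKa fitted from the simulated model-compound titration:
    ``new = current + (experimental - fitted)``.  Fixed point when the fit
    matches experiment.  Refuses non-finite (extrapolated) fits.
    """
    if not (math.isfinite(fitted_pka) and math.isfinite(experimental_pka)
            and math.isfinite(current_pkmod)):
        raise ExtrapolatedFitError(
            "calibration needs a finite fitted pKa; got "
            f"fitted={fitted_pka}, experimental={experimental_pka}"
        )
    return current_pkmod + (experimental_pka - fitted_pka)


@dataclass(frozen=True)
class BenchmarkResult:
    rmse: float
    rmse_null: float
    mean_error_by_type: dict
    n_used: int
    n_skipped: int

    def report(self) -> str:
        lines = [
            f"n = {self.n_used} (skipped {self.n_skipped})",
            f"RMSE (prediction): {self.rmse:.2f}",
            f"RMSE (null model): {self.rmse_null:.2f}",
            "mean error by residue type:",
        ]
        for t, v in sorted(self.mean_error_by_type.items()):
            lines.append(f"  {t}: {v:+.2f}")
        return "\n".join(lines)


def benchmark(table: pd.DataFrame, exclude_tyr: bool = True) -> BenchmarkResult:
    """RMSE / null RMSE / per-type mean error of pKa predictions.

    ``table`` columns: ``residue, residue_type, pka_pred, pka_exp,
    pka_null`` (``pka_pred`` may be absent or NaN, e.g. when only the null
    model is evaluated).  Rows without an experimental value are skipped
    with a log entry; tyrosines are excluded by default since their pKa is
    typically outside the titrated pH range.
    """
    df = table.copy()
    if "pka_pred" not in df.columns:
        df["pka_pred"] = np.nan
    n0 = len(df)
    missing = df["pka_exp"].isna()
    for r in df.loc[missing, "residue"]:
        logger.info("benchmark: skipping %s (no experimental value)", r)
    df = df[~missing]
    if exclude_tyr:
        df = df[df["residue_type"] != "Tyr"]
    if df.empty:
        raise ValueError("no rows left after exclusions")
    err = df["pka_pred"] - df["pka_exp"]
    err_null = df["pka_null"] - df["pka_exp"]
    rmse = float(np.sqrt(np.nanmean(err**2))) if err.notna().any() else math.nan
    rmse_null = float(np.sqrt(np.mean(err_null**2)))
    by_type = {
        t: float(np.nanmean(e)) if e.notna().any() else math.nan
        for t, e in err.groupby(df["residue_type"])
    }
    return BenchmarkResult(rmse, rmse_null, by_type, len(df), int(missing.sum()))


def load_benchmark_table(protein: str) -> pd.DataFrame:
    """Literature-compiled experimental pKa table for ``hewl`` or ``snase``.

    The null column is filled from :data:`PENTAPEPTIDE_PKA`.  See
    ``docs/methods.md`` for provenance and caveats of these compilations.
    """
    name = protein.lower()
    if name not in {"hewl", "snase"}:
        raise ValueError("protein must be 'hewl' or 'snase'")
    with resources.files("stochtit").joinpath("data", f"{name}_pka.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    df["pka_null"] = df["residue_type"].map(PENTAPEPTIDE_PKA)
    return df
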
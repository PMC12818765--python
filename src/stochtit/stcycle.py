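"""The stochastic-titration loop: dynamics segments alternated with MC.

The method's control flow is: run a short dynamics segment (20 ps by
default), evaluate the protonation energetics of the current conformation,
sample a new protonation state by Monte Carlo, and -- only if the state
changed -- run a brief solvent-relaxation step (0.2 ps) with the solute
frozen before the next segment.  Occupancies are recorded once per segment,
at the MC interruptions.

The loop itself carries no integrator: segment and relaxation lengths are
bookkeeping passed to a pluggable dynamics backend, and the energy backend
maps a conformation to a :class:`~stochtit.sites.SiteSystem`.  With a static
backend the loop must add no bias: its long-run per-site means converge to
the exact enumeration values for the fixed conformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .mc import MCConfig, ProtonationState, run_mc
from .records import TitrationRecord
from .sites import SiteSystem

__all__ = [
    "CycleConfig",
    "CycleTrace",
    "DynamicsBackend",
    "EnergyBackend",
    "StaticDynamics",
    "CyclingDynamics",
    "StaticEnergy",
    "TableEnergy",
    "run_stochastic_titration",
    "cumulative_protonation",
    "BackendError",
]


class BackendError(RuntimeError):
    """A backend failed; carries the segment index."""


class DynamicsBackend(Protocol):
    def advance(self, conformation, length_ps: float, frozen_solute: bool = False):
        """Advance a conformation by ``length_ps``; honour ``frozen_solute``."""


class EnergyBackend(Protocol):
    def __call__(self, conformation) -> SiteSystem:
        """Protonation energetics (sites + couplings) of a conformation."""


@dataclass
class StaticDynamics:
    """Conformation never changes (rigid-structure limit)."""

    conformation: int = 0

    def advance(self, conformation, length_ps, frozen_solute=False):
        return conformation


@dataclass
class CyclingDynamics:
    """Deterministically cycles through ``n_conformations`` mock states.

    Relaxation steps (frozen solute) do not advance the conformation.
    """

    n_conformations: int = 2

    def advance(self, conformation, length_ps, frozen_solute=False):
        if frozen_solute:
            return conformation
        return (conformation + 1) % self.n_conformations


@dataclass
class StaticEnergy:
    system: SiteSystem

    def __call__(self, conformation) -> SiteSystem:
        return self.system


@dataclass
class TableEnergy:
    """Conformation index -> SiteSystem lookup (mock PB step)."""

    systems: Sequence[SiteSystem]

    def __call__(self, conformation) -> SiteSystem:
        return self.systems[int(conformation) % len(self.systems)]


@dataclass(frozen=True)
class CycleConfig:
    """Settings of the stochastic-titration loop.

    ``pb_settings`` carries the electrostatics configuration of the real
    method (solver name, dielectrics, grids, convergence threshold) as
    metadata only; the in-package energy step is whatever backend is
    supplied.
    """

    n_segments: int
    pH: float = 7.0
    segment_length_ps: float = 20.0
    relaxation_length_ps: float = 0.2
    mc: MCConfig = field(default_factory=lambda: MCConfig(n_cycles=2000))
    seed: int | None = None
    pb_settings: tuple[tuple[str, object], ...] = (
        ("solver", "surrogate"),
        ("dielectric_protein", 2.0),
        ("dielectric_solvent", 80.0),
    )

    def __post_init__(self):
        if self.segment_length_ps <= 0 or self.relaxation_length_ps <= 0:
            raise ValueError("segment and relaxation lengths must be > 0")
        if self.n_segments < 0:
            raise ValueError("n_segments must be >= 0")

    @classmethod
    def from_json(cls, path) -> "CycleConfig":
        d = json.loads(Path(path).read_text())
        mc = MCConfig(**d.pop("mc", {}))
        pb = tuple((k, v) for k, v in d.pop("pb_settings", {}).items()) or cls.pb_settings
        return cls(mc=mc, pb_settings=pb, **d)


@dataclass
class CycleTrace:
    """Per-segment record of the loop's decisions."""

    site_ids: list[str]
    states: list[ProtonationState] = field(default_factory=list)
    occupancies: list[np.ndarray] = field(default_factory=list)
    changed: list[bool] = field(default_factory=list)
    relaxed: list[bool] = field(default_factory=list)
    conformations: list = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.states)

    def occupancy_matrix(self) -> np.ndarray:
        if not self.occupancies:
            return np.zeros((0, len(self.site_ids)))
        return np.stack(self.occupancies)

    def to_dataframe(self) -> pd.DataFrame:
        occ = self.occupancy_matrix()
        rows = []
        for t in range(self.n_segments):
            for j, sid in enumerate(self.site_ids):
                rows.append(
                    {
                        "segment": t,
                        "site": sid,
                        "n_prot": occ[t, j],
                        "changed": self.changed[t],
                        "relaxed": self.relaxed[t],
                        "conformation": self.conformations[t],
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["segment", "site", "n_prot", "changed", "relaxed", "conformation"],
        )


def run_stochastic_titration(
    config: CycleConfig,
    dynamics_backend: DynamicsBackend,
    energy_backend: EnergyBackend,
    initial_conformation=0,
    initial_state: ProtonationState | None = None,
) -> tuple[CycleTrace, TitrationRecord]:
    """Alternate dynamics segments with MC protonation updates.

    Each iteration advances the conformation, re-evaluates the site system,
    runs the protonation MC (continuing from the previous state), records
    the sampled state, and triggers the solvent-relaxation hook exactly
    when the state changed.  Backend failures are re-raised with the
    segment index.  Reproducible for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    conf = initial_conformation
    state = initial_state
    trace: CycleTrace | None = None
    for seg in range(config.n_segments):
        try:
            conf = dynamics_backend.advance(conf, config.segment_length_ps)
            system = energy_backend(conf)
        except Exception as exc:  # noqa: BLE001 - contract: annotate segment
            raise BackendError(f"backend failed at segment {seg}: {exc}") from exc
        if trace is None:
            trace = CycleTrace(site_ids=[s.id for s in system.sites])
            if state is None:
                state = ProtonationState.reference(system)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        res = run_mc(
            system,
            replace(config.mc, pH=config.pH, seed=sub_seed),
            initial_state=state,
        )
        new_state = res.final_state
        changed = new_state != state
        if changed:
            try:
                conf = dynamics_backend.advance(
                    conf, config.relaxation_length_ps, frozen_solute=True
                )
            except Exception as exc:  # noqa: BLE001
                raise BackendError(
                    f"relaxation backend failed at segment {seg}: {exc}"
                ) from exc
        trace.states.append(new_state)
        trace.occupancies.append(new_state.n_vector(system).astype(float))
        trace.changed.append(changed)
        trace.relaxed.append(changed)
        trace.conformations.append(conf)
        state = new_state
    if trace is None:
        trace = CycleTrace(site_ids=[])
        return trace, TitrationRecord()
    occ = trace.occupancy_matrix()
    # charge offsets from the last evaluated system (site set is fixed)
    offsets = {s.id: s.charge_offset for s in system.sites}
    rows = [
        (config.pH, 0, sid, float(occ[:, j].mean()),
         float(occ[:, j].std(ddof=1) / np.sqrt(len(occ))) if len(occ) > 1 else 0.0,
         float(occ[:, j].mean() + offsets[sid]))
        for j, sid in enumerate(trace.site_ids)
    ]
    return trace, TitrationRecord.from_rows(rows)


def cumulative_protonation(trace: CycleTrace, site: str) -> np.ndarray:
    """Running mean occupancy of one site over segments 1..t.

    The final element equals the overall mean -- the convergence profile
    used to judge protonation equilibration.
    """
    if trace.n_segments == 0:
        raise ValueError("empty trace")
    try:
        j = trace.site_ids.index(site)
    except ValueError:
        raise KeyError(site) from None
    series = trace.occupancy_matrix()[:, j]
    return np.cumsum(series) / np.arange(1, len(series) + 1)
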
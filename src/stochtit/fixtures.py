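"""Synthetic-data generators that make every module testable offline.

All generators take an explicit seed and embed their generating parameters
in the returned artifact (or alongside it), so tests can assert recovery
against known ground truth.  There is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ffcharges import ResidueBlock
from .sites import make_synthetic_system

__all__ = [
    "FixtureSpec",
    "make_titration_replicates",
    "make_residue_block",
    "make_distance_series",
    "make_angle_series",
    "make_pdb_pair",
    "build_fixture",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic artifact."""

    kind: str  # residue_block | site_system | titration_replicates |
    #            distance_series | angle_series | pdb_pair
    parameters: tuple[tuple[str, object], ...] = ()
    seed: int | None = None

    def params(self) -> dict:
        return dict(self.parameters)


def make_titration_replicates(
    true_pka: float,
    hill_n: float = 1.0,
    n_replicates: int = 3,
    noise_sd: float = 0.02,
    ph_grid=None,
    seed: int | None = None,
):
    """Replicate titration curves from a known Hill curve plus noise.

    Emulates triplicate fixed-pH simulations over an integer pH grid
    (1..12 by default): the exact Hill occupancy plus i.i.d. Gaussian noise
    of standard deviation ``noise_sd``, clipped to [0, 1].  ``noise_sd=0``
    returns the exact curve.  Returns ``(ph_grid, curves)`` with ``curves``
    of shape ``(n_replicates, n_pH)``.
    """
    from .analysis import hill_curve

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if ph_grid is None:
        ph_grid = np.arange(1.0, 13.0)
    ph_grid = np.asarray(ph_grid, dtype=float)
    rng = np.random.default_rng(seed)
    base = hill_curve(ph_grid, true_pka, hill_n)
    curves = base[None, :] + rng.normal(0.0, noise_sd, size=(n_replicates, len(ph_grid)))
    if noise_sd == 0.0:
        curves = np.repeat(base[None, :], n_replicates, axis=0)
    return ph_grid, np.clip(curves, 0.0, 1.0)


def make_residue_block(
    n_side_atoms: int = 3,
    imbalance: float = 0.0,
    seed: int | None = None,
    name: str = "TOY",
    formal_side_chain_charge: int = -1,
    formal_total_charge: int = -1,
) -> ResidueBlock:
    """Toy residue block whose side-chain charge is off-integer by ``imbalance``.

    The side-chain region (C-beta group plus ``n_side_atoms`` side-chain
    atoms) sums to ``formal_side_chain_charge + imbalance`` and the
    backbone region absorbs ``-imbalance``, so the block total stays at its
    integer formal charge and side-chain localization must remove exactly
    ``imbalance``.
    """
    if abs(imbalance) >= 0.5:
        raise ValueError("|imbalance| must be < 0.5")
    if n_side_atoms < 1:
        raise ValueError("need at least one side-chain atom")
    rng = np.random.default_rng(seed)

    def _charges(n, target):
        q = rng.uniform(-0.6, 0.6, size=n)
        q[-1] += target - q.sum()
        return q

    side_names = ["CB", "HB1"] + [f"S{i}" for i in range(1, n_side_atoms)]
    side_q = _charges(len(side_names), formal_side_chain_charge + imbalance)
    main_names = ["N", "H", "CA", "HA", "C", "O"]
    main_target = (formal_total_charge - formal_side_chain_charge) - imbalance
    main_q = _charges(len(main_names), main_target)
    charges = list(zip(main_names, main_q)) + list(zip(side_names, side_q))
    return ResidueBlock.from_charges(
        name,
        charges,
        formal_side_chain_charge=formal_side_chain_charge,
        formal_total_charge=formal_total_charge,
    )


def make_distance_series(
    n: int = 1000,
    mean: float = 0.5,
    sd: float = 0.1,
    seed: int | None = None,
) -> np.ndarray:
    """Positive (truncated-Gaussian) side-chain distance series in nm."""
    rng = np.random.default_rng(seed)
    return np.abs(rng.normal(mean, sd, size=n))


def make_angle_series(
    n: int = 1000,
    modes=((-90.0, 15.0, 0.6), (40.0, 15.0, 0.4)),
    seed: int | None = None,
) -> np.ndarray:
    """Bimodal wrapped-Gaussian angle series in degrees, in (-180, 180]."""
    rng = np.random.default_rng(seed)
    centers, sds, weights = zip(*modes)
    w = np.asarray(weights, dtype=float)
    comp = rng.choice(len(modes), size=n, p=w / w.sum())
    a = rng.normal(np.asarray(centers)[comp], np.asarray(sds)[comp])
    a = np.mod(a + 180.0, 360.0) - 180.0
    a[a == -180.0] = 180.0
    return a


_PDB_ATOM = (
    "ATOM  {serial:5d} {name:^4s}{alt:1s}{res:3s} {chain:1s}{seq:4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
)


def make_pdb_pair(path, distances_nm, seed: int | None = None) -> None:
    """Write a minimal multi-MODEL PDB of two alanine-like residues.

    Each MODEL places the two C-beta atoms (the only side-chain heavy
    atoms) exactly ``distances_nm[m]`` apart, so the minimum side-chain
    distance series read back from the file is known by construction.
    Backbone atoms sit well outside the side-chain separation.
    """
    distances_nm = np.asarray(distances_nm, dtype=float)
    lines = []
    for m, d_nm in enumerate(distances_nm, start=1):
        d = d_nm * 10.0  # angstrom
        lines.append(f"MODEL     {m:4d}\n")
        serial = 1
        for seq, (res, x0, cb_x) in enumerate(
            [("ALA", -10.0, 0.0), ("ALA", 10.0 + d, d)], start=1
        ):
            for nm_, dx, dy in [("N", -1.5, 0.0), ("CA", 0.0, 0.0),
                                ("C", 1.5, 0.0), ("O", 1.5, 1.2)]:
                lines.append(
                    _PDB_ATOM.format(
                        serial=serial, name=nm_, alt=" ", res=res, chain="A",
                        seq=seq, icode=" ", x=x0 + dx, y=dy, z=20.0 * seq,
                        occ=1.0, b=0.0, el=nm_[0],
                    )
                )
                serial += 1
            lines.append(
                _PDB_ATOM.format(
                    serial=serial, name="CB", alt=" ", res=res, chain="A",
                    seq=seq, icode=" ", x=cb_x, y=0.0, z=0.0,
                    occ=1.0, b=0.0, el="C",
                )
            )
            serial += 1
        lines.append("ENDMDL\n")
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def build_fixture(spec: FixtureSpec):
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    p = spec.params()
    if spec.kind == "residue_block":
        return make_residue_block(seed=spec.seed, **p)
    if spec.kind == "site_system":
        return make_synthetic_system(seed=spec.seed, **p)
    if spec.kind == "titration_replicates":
        return make_titration_replicates(seed=spec.seed, **p)
    if spec.kind == "distance_series":
        return make_distance_series(seed=spec.seed, **p)
    if spec.kind == "angle_series":
        return make_angle_series(seed=spec.seed, **p)
    if spec.kind == "pdb_pair":
        return make_pdb_pair(**p)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")
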
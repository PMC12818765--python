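"""Titratable-site systems: states, intrinsic pKa and pairwise couplings.

A :class:`SiteSystem` is the input of the protonation Monte Carlo step: a
list of titratable sites, each with one or more protonation/tautomer states
and an intrinsic pKa, plus a symmetric site-site coupling matrix ``W`` in pK
units (the pairwise free energy of having both sites in their protonated
forms, relative to their reference states).  In the full method the matrix
comes from a finite-difference Poisson-Boltzmann solver; here couplings are
either read from file or produced by a screened-Coulomb surrogate
(:func:`surrogate_couplings`), which preserves the qualitative structure
(symmetry, distance decay, sign from the charge product) at negligible cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .units import COULOMB_PK_NM

__all__ = [
    "SiteState",
    "Site",
    "SiteSystem",
    "FormatError",
    "GeometryError",
    "read_site_system",
    "write_site_system",
    "surrogate_couplings",
    "make_synthetic_system",
    "ACID_TYPES",
    "BASE_TYPES",
]

#: Residue types that are anionic when deprotonated.
ACID_TYPES = ("Asp", "Glu", "Cys", "Tyr", "CTr")
#: Residue types that are cationic when protonated.
BASE_TYPES = ("His", "Lys", "NTr")

_DEFAULT_POLARITY = {**{t: "acid" for t in ACID_TYPES}, **{t: "base" for t in BASE_TYPES}}


class FormatError(ValueError):
    """Malformed site-table / matrix file."""


class GeometryError(ValueError):
    """Invalid site geometry (e.g. coincident points)."""


@dataclass(frozen=True)
class SiteState:
    """One protonation/tautomer state of a site.

    ``n_prot`` counts bound protons relative to the deprotonated reference
    (0 or 1); ``intrinsic_shift`` is a tautomer-specific free-energy offset
    in pK units (0 for the reference state of each protonation count).
    """

    label: str
    n_prot: int
    intrinsic_shift: float = 0.0

    def __post_init__(self):
        if self.n_prot not in (0, 1):
            raise ValueError("n_prot must be 0 or 1")


_DEFAULT_STATES = (SiteState("deprot", 0), SiteState("prot", 1))


@dataclass(frozen=True)
class Site:
    """A titratable site: identity, polarity, intrinsic pKa and states."""

    id: str
    residue_type: str = "Asp"
    polarity: str | None = None  # acid | base; default from residue_type
    pk_int: float = 7.0
    pk_mod: float | None = None
    states: tuple[SiteState, ...] = _DEFAULT_STATES

    def __post_init__(self):
        if self.polarity is None:
            pol = _DEFAULT_POLARITY.get(self.residue_type)
            if pol is None:
                raise ValueError(
                    f"{self.id}: polarity required for residue type "
                    f"{self.residue_type!r}"
                )
            object.__setattr__(self, "polarity", pol)
        if self.polarity not in ("acid", "base"):
            raise ValueError(f"{self.id}: polarity must be acid|base")
        if not np.isfinite(self.pk_int):
            raise ValueError(f"{self.id}: pk_int must be finite")
        object.__setattr__(self, "states", tuple(self.states))
        nvals = {s.n_prot for s in self.states}
        if nvals != {0, 1}:
            raise ValueError(f"{self.id}: need >=1 protonated and >=1 deprotonated state")

    def charge(self, n_prot: int) -> int:
        """Site charge for a protonation count: acid -1/0, base 0/+1."""
        return n_prot - 1 if self.polarity == "acid" else n_prot

    @property
    def charge_offset(self) -> int:
        """Charge at n_prot=0 (so charge = n_prot + offset)."""
        return -1 if self.polarity == "acid" else 0


@dataclass
class SiteSystem:
    """N titratable sites plus their symmetric coupling matrix (pK units)."""

    sites: list[Site]
    W: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        n = len(self.sites)
        if self.W.shape != (n, n):
            raise FormatError(f"coupling matrix shape {self.W.shape} != ({n},{n})")
        if n and not np.allclose(self.W, self.W.T, atol=1e-9, rtol=0.0):
            raise FormatError("coupling matrix is not symmetric")
        if n and np.any(np.abs(np.diag(self.W)) > 0):
            raise FormatError("coupling matrix diagonal must be zero")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_states(self) -> np.ndarray:
        return np.array([len(s.states) for s in self.sites], dtype=np.int64)

    @property
    def state_space_size(self) -> int:
        return int(np.prod([len(s.states) for s in self.sites], dtype=object)) if self.sites else 1

    def site_index(self, site_id: str) -> int:
        for i, s in enumerate(self.sites):
            if s.id == site_id:
                return i
        raise KeyError(site_id)

    # -- padded state tables used by the samplers ----------------------
    def state_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_prot, intrinsic_shift) tables padded to the max state count."""
        n, k = self.n_sites, int(self.n_states.max(initial=1))
        n_prot = np.zeros((n, k), dtype=np.int64)
        shift = np.zeros((n, k), dtype=float)
        for i, s in enumerate(self.sites):
            for j, st in enumerate(s.states):
                n_prot[i, j] = st.n_prot
                shift[i, j] = st.intrinsic_shift
        return n_prot, shift


# ---------------------------------------------------------------------------
# I/O: JSON bundle, or TSV site table + square matrix TSV
# ---------------------------------------------------------------------------


def _site_to_dict(s: Site) -> dict:
    return {
        "id": s.id,
        "residue_type": s.residue_type,
        "polarity": s.polarity,
        "pk_int": s.pk_int,
        "pk_mod": s.pk_mod,
        "states": [
            {"label": st.label, "n_prot": st.n_prot, "intrinsic_shift": st.intrinsic_shift}
            for st in s.states
        ],
    }


def _site_from_dict(d: dict) -> Site:
    return Site(
        id=d["id"],
        residue_type=d.get("residue_type", "Asp"),
        polarity=d.get("polarity"),
        pk_int=float(d["pk_int"]),
        pk_mod=d.get("pk_mod"),
        states=tuple(
            SiteState(s["label"], int(s["n_prot"]), float(s.get("intrinsic_shift", 0.0)))
            for s in d["states"]
        ),
    )


def _encode_states(states) -> str:
    return ";".join(f"{s.label}:{s.n_prot}:{s.intrinsic_shift!r}" for s in states)


def _decode_states(text: str) -> tuple[SiteState, ...]:
    out = []
    for part in text.split(";"):
        label, n, shift = part.split(":")
        out.append(SiteState(label, int(n), float(shift)))
    return tuple(out)


def write_site_system(system: SiteSystem, path, matrix_path=None) -> None:
    """Write a system: single ``.json`` bundle, or site TSV + matrix TSV."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "sites": [_site_to_dict(s) for s in system.sites],
            "W": system.W.tolist(),
            "metadata": system.metadata,
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    if matrix_path is None:
        raise ValueError("matrix_path required for TSV output")
    lines = ["id\tresidue_type\tpolarity\tpk_int\tpk_mod\tstates"]
    for s in system.sites:
        pkm = "" if s.pk_mod is None else repr(s.pk_mod)
        lines.append(
            f"{s.id}\t{s.residue_type}\t{s.polarity}\t{s.pk_int!r}\t{pkm}\t"
            f"{_encode_states(s.states)}"
        )
    path.write_text("\n".join(lines) + "\n")
    ids = "\t".join(s.id for s in system.sites)
    rows = ["\t".join(repr(float(v)) for v in row) for row in system.W]
    Path(matrix_path).write_text(ids + "\n" + "\n".join(rows) + "\n")


def read_site_system(path, matrix_path=None) -> SiteSystem:
    """Read a system written by :func:`write_site_system` (lossless)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return SiteSystem(
            sites=[_site_from_dict(d) for d in payload["sites"]],
            W=np.array(payload["W"], dtype=float).reshape(
                len(payload["sites"]), len(payload["sites"])
            ),
            metadata=payload.get("metadata", {}),
        )
    if matrix_path is None:
        raise ValueError("matrix_path required for TSV input")
    lines = path.read_text().splitlines()
    header = lines[0].split("\t")
    sites = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        rec = dict(zip(header, ln.split("\t")))
        sites.append(
            Site(
                id=rec["id"],
                residue_type=rec["residue_type"],
                polarity=rec["polarity"] or None,
                pk_int=float(rec["pk_int"]),
                pk_mod=float(rec["pk_mod"]) if rec.get("pk_mod") else None,
                states=_decode_states(rec["states"]),
            )
        )
    mlines = [ln for ln in Path(matrix_path).read_text().splitlines() if ln.strip()]
    ids = mlines[0].split("\t")
    if ids != [s.id for s in sites]:
        raise FormatError("matrix header does not match site table")
    W = np.array([[float(v) for v in ln.split("\t")] for ln in mlines[1:]])
    if W.shape != (len(sites), len(sites)):
        raise FormatError(
            f"matrix dimension {W.shape} does not match {len(sites)} sites"
        )
    return SiteSystem(sites=sites, W=W)


# ---------------------------------------------------------------------------
# Screened-Coulomb surrogate couplings
# ---------------------------------------------------------------------------


def surrogate_couplings(
    coords: np.ndarray,
    charges: np.ndarray,
    dielectric: float = 80.0,
    kappa: float = 0.0,
) -> np.ndarray:
    """Screened-Coulomb site-site couplings in pK units.

    ``W[i,j] = q_i q_j * C * exp(-kappa r_ij) / (dielectric * r_ij)`` with
    ``C = COULOMB_PK_NM`` (~24.19 pK nm at 300 K), coordinates in nm and
    ``q`` the charges of the sites' charged states (acid -1, base +1).
    The matrix is symmetric with zero diagonal and decays monotonically
    with distance.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    n = len(coords)
    if charges.shape != (n,):
        raise ValueError("one charge per site required")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] <= 0.0):
        raise GeometryError("coincident site coordinates")
    W = np.zeros((n, n))
    d_safe = np.where(off, d, 1.0)
    W[off] = (
        charges[:, None] * charges[None, :]
        * COULOMB_PK_NM * np.exp(-kappa * d_safe) / (dielectric * d_safe)
    )[off]
    return W


# ---------------------------------------------------------------------------
# Synthetic systems
# ---------------------------------------------------------------------------


def make_synthetic_system(
    n_sites: int,
    pk_range: tuple[float, float] = (2.0, 11.0),
    coupling_scale: float = 1.0,
    seed: int | None = None,
    tautomer_fraction: float = 0.0,
    tautomer_shift_sd: float = 0.5,
) -> SiteSystem:
    """Random coupled-site system with known generation parameters.

    Intrinsic pKa values are uniform over ``pk_range``; couplings are
    symmetric Gaussian with standard deviation ``coupling_scale`` (pK) and
    zero diagonal.  With probability ``tautomer_fraction`` a site gets an
    extra neutral tautomer carrying a Gaussian intrinsic shift.  Generation
    parameters are recorded in ``metadata`` so downstream tests can assert
    recovery against ground truth.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    types = rng.choice(list(ACID_TYPES + BASE_TYPES), size=n_sites)
    pk = rng.uniform(*pk_range, size=n_sites)
    sites = []
    for i in range(n_sites):
        states: tuple[SiteState, ...] = _DEFAULT_STATES
        if rng.random() < tautomer_fraction:
            shift = float(rng.normal(0.0, tautomer_shift_sd))
            states = (
                SiteState("deprot", 0),
                SiteState("prot", 1),
                SiteState("taut2", 1, shift),
            )
        sites.append(
            Site(
                id=f"S{i}",
                residue_type=str(types[i]),
                pk_int=float(pk[i]),
                states=states,
            )
        )
    if coupling_scale > 0.0:
        A = rng.normal(0.0, coupling_scale, size=(n_sites, n_sites))
        W = np.triu(A, k=1)
        W = W + W.T
    else:
        W = np.zeros((n_sites, n_sites))
    return SiteSystem(
        sites=sites,
        W=W,
        metadata={
            "generator": "make_synthetic_system",
            "n_sites": n_sites,
            "pk_range": list(pk_range),
            "coupling_scale": coupling_scale,
            "seed": seed,
            "tautomer_fraction": tautomer_fraction,
        },
    )
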
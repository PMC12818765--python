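"""Convergence and structural diagnostics for titration simulations.

Covers the comparisons used to validate a modified charge set against the
published one: Kullback-Leibler divergence between sampled distributions
(and its cumulative 0-t profile as a convergence diagnostic), side-chain
pseudodihedral computation with the empirical bimodal region
classification, and interaction-time fractions from side-chain distance
series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Histogram",
    "ANGLE1_INTERVALS",
    "ANGLE2_INTERVAL",
    "kl_divergence",
    "cumulative_kl",
    "dihedral",
    "dihedral_series",
    "classify_angle",
    "region_prevalence",
    "interaction_fraction",
    "min_sidechain_distance",
    "HistogramFormatError",
    "CollinearityError",
]


class HistogramFormatError(ValueError):
    """Histograms with incompatible bin edges."""


class CollinearityError(ValueError):
    """Three consecutive points of a torsion are collinear."""


# Empirical bimodal regions of the CB-CA-CA-CB pseudodihedral (degrees):
# angle1 is the union of [-180, -40.5] and [118.5, 180]; angle2 is the
# complementary open interval (-40.5, 118.5).  Together they partition
# (-180, 180].
ANGLE1_INTERVALS = ((-180.0, -40.5), (118.5, 180.0))
ANGLE2_INTERVAL = (-40.5, 118.5)


@dataclass(frozen=True)
class Histogram:
    """Binned counts with explicit edges."""

    edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if len(self.edges) != len(self.counts) + 1:
            raise HistogramFormatError("need len(edges) == len(counts) + 1")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @classmethod
    def from_series(cls, x, edges=None, bins="fd") -> "Histogram":
        x = np.asarray(x, dtype=float)
        if edges is None:
            edges = np.histogram_bin_edges(x, bins=bins)
        counts, edges = np.histogram(x, bins=edges)
        return cls(edges, counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty histogram cannot be normalized")
        return self.counts / self.total


def shared_histograms(a, b, bins="fd") -> tuple[Histogram, Histogram]:
    """Histogram both series on Freedman-Diaconis edges of the pooled data."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    edges = np.histogram_bin_edges(np.concatenate([a, b]), bins=bins)
    return Histogram.from_series(a, edges), Histogram.from_series(b, edges)


def kl_divergence(p: Histogram, q: Histogram, pseudocount: float | None = None) -> float:
    """D_KL(p || q) in nats over shared bins.

    Bins with ``p_k = 0`` contribute nothing.  Empty reference bins where
    ``p_k > 0`` would make the divergence infinite; they are instead given
    a pseudocount (default ``1 / (10 * total q count)``) before
    renormalizing q.  The result is >= 0, and exactly 0 iff the two
    normalized histograms are bitwise equal.
    """
    if not np.array_equal(p.edges, q.edges):
        raise HistogramFormatError("histograms must share bin edges")
    pp = p.probabilities()
    qq = q.probabilities()
    if np.array_equal(pp, qq):
        return 0.0
    if pseudocount is None:
        pseudocount = 1.0 / (10.0 * q.total)
    qc = q.counts.astype(float).copy()
    qc[(qc == 0) & (pp > 0)] = pseudocount
    qq = qc / qc.sum()
    mask = pp > 0
    return float(np.sum(pp[mask] * np.log(pp[mask] / qq[mask])))


def cumulative_kl(series_a, series_b, window_step: int = 1, edges=None, bins="fd"):
    """D_KL between growing prefixes of two series.

    Element ``t`` compares the histograms of ``a[:t]`` and ``b[:t]``;
    prefix lengths run in steps of ``window_step`` and always include the
    full length, so the last value equals the full-series divergence.  Bin
    edges are shared (pooled Freedman-Diaconis over the *full* series
    unless given explicitly) so successive values are comparable.

    Returns ``(lengths, values)``.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("empty series")
    if edges is None:
        edges = np.histogram_bin_edges(np.concatenate([a[:n], b[:n]]), bins=bins)
    lengths = list(range(window_step, n + 1, window_step))
    if not lengths or lengths[-1] != n:
        lengths.append(n)
    vals = [
        kl_divergence(
            Histogram.from_series(a[:t], edges), Histogram.from_series(b[:t], edges)
        )
        for t in lengths
    ]
    return np.asarray(lengths), np.asarray(vals)


def dihedral(p1, p2, p3, p4, collinear_tol: float = 1e-10) -> float:
    """Signed torsion angle of four points, in degrees, in (-180, 180].

    IUPAC sign convention: looking down the p2->p3 bond, the angle is
    positive when the far bond is rotated clockwise from the near bond.
    Invariant under rigid-body motion; raises :class:`CollinearityError`
    when either bonded triple is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < collinear_tol or np.linalg.norm(n2) < collinear_tol:
        raise CollinearityError("collinear points in torsion")
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(y, np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def dihedral_series(points: np.ndarray) -> np.ndarray:
    """Vectorized torsions for an array of shape (T, 4, 3)."""
    p = np.asarray(points, dtype=float)
    b1, b2, b3 = p[:, 1] - p[:, 0], p[:, 2] - p[:, 1], p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.einsum(
        "ij,ij->i", np.cross(n1, n2), b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    )
    ang = np.degrees(np.arctan2(y, np.einsum("ij,ij->i", n1, n2)))
    ang[ang <= -180.0] += 360.0
    return ang


def classify_angle(angle_deg: float) -> str:
    """Region label of a pseudodihedral angle: ``angle1`` or ``angle2``.

    Boundary values (-40.5 and 118.5) belong to angle1, so the two labels
    partition (-180, 180] exactly.
    """
    a = float(angle_deg)
    if not (-180.0 < a <= 180.0) and a != -180.0:
        raise ValueError("angle must lie in (-180, 180]")
    lo, hi = ANGLE2_INTERVAL
    return "angle2" if lo < a < hi else "angle1"


def region_prevalence(series) -> dict[str, float]:
    """Fraction of a series falling in each angle region (sums to 1)."""
    a = np.asarray(series, dtype=float)
    if len(a) == 0:
        raise ValueError("empty series")
    lo, hi = ANGLE2_INTERVAL
    frac2 = float(np.mean((a > lo) & (a < hi)))
    return {"angle1": 1.0 - frac2, "angle2": frac2}


def interaction_fraction(distances, cutoff: float) -> float:
    """Fraction of frames with distance strictly below the cutoff (nm)."""
    d = np.asarray(distances, dtype=float)
    if len(d) == 0:
        raise ValueError("empty distance series")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    return float(np.mean(d < cutoff))


_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def min_sidechain_distance(pdb_path, residue_a: int, residue_b: int) -> np.ndarray:
    """Per-model minimum side-chain heavy-atom distance (nm) from a PDB.

    Reads ATOM records only (Biopython parser), selects non-backbone heavy
    atoms of the two residues identified by residue sequence number, and
    returns one minimum distance per MODEL, converted from angstrom to nm.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("x", str(pdb_path))
    out = []
    for model in structure:
        coords = {residue_a: [], residue_b: []}
        for chain in model:
            for res in chain:
                seq = res.id[1]
                if seq in coords:
                    for atom in res:
                        if atom.get_name() in _BACKBONE or atom.element == "H":
                            continue
                        coords[seq].append(atom.coord)
        a = np.asarray(coords[residue_a], dtype=float)
        b = np.asarray(coords[residue_b], dtype=float)
        if len(a) == 0 or len(b) == 0:
            raise KeyError(f"residue {residue_a} or {residue_b} has no side-chain atoms")
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1).min()
        out.append(d / 10.0)
    return np.asarray(out)
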
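"""Semigrand-canonical Metropolis Monte Carlo over protonation states.

At fixed pH the equilibrium weight of a protonation/tautomer configuration
``s = (s_1 .. s_N)`` is ``10**(-E(s))`` with the configurational energy, in
pK units,

    E(s) = sum_i n_i (pH - pKint_i)                    (pH field)
         + sum_i shift_i(s_i)                          (tautomer offsets)
         + sum_{i<j} W_ij n_i n_j                      (pairwise couplings)

where ``n_i`` is the proton count of state ``s_i`` and ``W`` is the
site-site coupling matrix.  Any isolated site then titrates exactly along
Henderson-Hasselbalch (``<n> = 1/(1 + 10**(pH - pKint))``), which anchors
the sign conventions; acid/base polarity enters only through the charge
map (acid -1/0, base 0/+1), not through the energy.

One MC cycle is a randomized sweep that attempts a state change for every
site and a joint change for every strongly coupled pair (|W_ij| above the
pair-move threshold, 2 pK by default); moves are accepted with probability
``min(1, 10**(-dE))``.  The inner loop is compiled with numba.  For small
systems :func:`enumerate_exact` sums the semigrand partition function
explicitly and serves as the reference the sampler is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .records import TitrationRecord
from .sites import SiteSystem

__all__ = [
    "ProtonationState",
    "MCConfig",
    "MCResult",
    "ExactResult",
    "state_energy",
    "enumerate_exact",
    "run_mc",
    "titration_scan",
    "CapacityError",
]

#: Largest state space enumerate_exact will attempt.
MAX_ENUM_STATES = 2**20


class CapacityError(ValueError):
    """State space too large for exact enumeration."""


@dataclass(frozen=True)
class ProtonationState:
    """One assignment of a state index to every site."""

    state_index: tuple[int, ...]

    @classmethod
    def reference(cls, system: SiteSystem) -> "ProtonationState":
        return cls(tuple(0 for _ in system.sites))

    def n_vector(self, system: SiteSystem) -> np.ndarray:
        return np.array(
            [s.states[i].n_prot for s, i in zip(system.sites, self.state_index)],
            dtype=np.int64,
        )

    def charge_vector(self, system: SiteSystem) -> np.ndarray:
        n = self.n_vector(system)
        off = np.array([s.charge_offset for s in system.sites], dtype=np.int64)
        return n + off


@dataclass(frozen=True)
class MCConfig:
    """Sampler settings for one fixed-pH Monte Carlo run."""

    pH: float = 7.0
    n_cycles: int = 100_000
    pair_threshold: float = 2.0
    burn_in_fraction: float = 0.1
    seed: int | None = None
    n_blocks: int = 20  # block averaging for standard errors

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not (0.0 <= self.burn_in_fraction < 1.0):
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass(frozen=True)
class MCResult:
    """Averages, errors and bookkeeping from one MC run."""

    mean_protonation: np.ndarray
    se: np.ndarray
    mean_total_charge: float
    acceptance_single: float
    acceptance_pair: float
    final_state: ProtonationState
    config: MCConfig
    n_measured_cycles: int


@dataclass(frozen=True)
class ExactResult:
    """Exact semigrand averages from full enumeration."""

    mean_protonation: np.ndarray
    mean_total_charge: float
    log10_Z: float


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------


def _field_tables(system: SiteSystem, pH: float):
    """Per-site per-state non-pairwise energy dg[i,s] (padded)."""
    n_prot, shift = system.state_tables()
    pk = np.array([s.pk_int for s in system.sites], dtype=float)
    dg = n_prot * (pH - pk[:, None]) + shift
    return n_prot, dg


def state_energy(system: SiteSystem, state: ProtonationState, pH: float) -> float:
    """Configurational energy in pK units (see module docstring)."""
    if len(state.state_index) != system.n_sites:
        raise ValueError("state does not match system")
    n_prot, dg = _field_tables(system, pH)
    idx = np.asarray(state.state_index)
    rows = np.arange(system.n_sites)
    n = n_prot[rows, idx].astype(float)
    e_field = float(dg[rows, idx].sum())
    e_pair = 0.5 * float(n @ system.W @ n)
    return e_field + e_pair


# ---------------------------------------------------------------------------
# Exact enumeration (oracle)
# ---------------------------------------------------------------------------


def enumerate_exact(system: SiteSystem, pH: float) -> ExactResult:
    """Exact per-site mean protonation by summing over all configurations.

    For an isolated acid this reduces to Henderson-Hasselbalch,
    ``<n> = 1 / (1 + 10**(pH - pKint))``.
    """
    if system.n_sites == 0:
        return ExactResult(np.zeros(0), 0.0, 0.0)
    size = system.state_space_size
    if size > MAX_ENUM_STATES:
        raise CapacityError(f"state space {size} exceeds {MAX_ENUM_STATES}")
    ks = system.n_states
    n_prot, dg = _field_tables(system, pH)
    # mixed-radix digits: site i's state index for every configuration
    idx = np.arange(size)
    strides = np.concatenate(([1], np.cumprod(ks[:-1])))
    digits = (idx[:, None] // strides[None, :]) % ks[None, :]  # (size, n)
    rows = np.arange(system.n_sites)[None, :]
    N = n_prot[rows, digits].astype(float)
    E = dg[rows, digits].sum(axis=1) + 0.5 * np.einsum("si,ij,sj->s", N, system.W, N)
    logw = -E * np.log(10.0)
    logZ = logsumexp(logw)
    p = np.exp(logw - logZ)
    mean_n = p @ N
    offsets = np.array([s.charge_offset for s in system.sites], dtype=float)
    return ExactResult(mean_n, float(mean_n.sum() + offsets.sum()), float(logZ / np.log(10.0)))


# ---------------------------------------------------------------------------
# Metropolis sampler (numba kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _mc_kernel(
    ks, n_prot, dg, W, pairs, state, n_cycles, burn_in, seed, n_blocks
):  # pragma: no cover - exercised via run_mc
    np.random.seed(seed)
    n_sites = ks.shape[0]
    n_pairs = pairs.shape[0]
    n_moves = n_sites + n_pairs

    n_cur = np.empty(n_sites, dtype=np.float64)
    for i in range(n_sites):
        n_cur[i] = n_prot[i, state[i]]

    sum_n = np.zeros(n_sites)
    measured = n_cycles - burn_in
    block_len = max(measured // n_blocks, 1)
    blocks = np.zeros((n_blocks, n_sites))
    acc_s = 0
    att_s = 0
    acc_p = 0
    att_p = 0
    order = np.arange(n_moves)

    for cycle in range(n_cycles):
        # Fisher-Yates shuffle of the sweep order
        for a in range(n_moves - 1, 0, -1):
            b = np.random.randint(0, a + 1)
            tmp = order[a]
            order[a] = order[b]
            order[b] = tmp
        for m in range(n_moves):
            mv = order[m]
            if mv < n_sites:
                i = mv
                k = ks[i]
                if k < 2:
                    continue
                att_s += 1
                a_st = state[i]
                b_st = np.random.randint(0, k - 1)
                if b_st >= a_st:
                    b_st += 1
                dn = n_prot[i, b_st] - n_prot[i, a_st]
                dE = dg[i, b_st] - dg[i, a_st]
                if dn != 0:
                    coup = 0.0
                    for jj in range(n_sites):
                        coup += W[i, jj] * n_cur[jj]
                    dE += dn * coup
                if dE <= 0.0 or np.random.random() < 10.0 ** (-dE):
                    state[i] = b_st
                    n_cur[i] = n_prot[i, b_st]
                    acc_s += 1
            else:
                p = mv - n_sites
                i = pairs[p, 0]
                j = pairs[p, 1]
                ki = ks[i]
                kj = ks[j]
                tot = ki * kj
                if tot < 2:
                    continue
                att_p += 1
                a_i = state[i]
                a_j = state[j]
                cur = a_i * kj + a_j
                r = np.random.randint(0, tot - 1)
                if r >= cur:
                    r += 1
                b_i = r // kj
                b_j = r % kj
                dni = n_prot[i, b_i] - n_prot[i, a_i]
                dnj = n_prot[j, b_j] - n_prot[j, a_j]
                dE = dg[i, b_i] - dg[i, a_i] + dg[j, b_j] - dg[j, a_j]
                if dni != 0:
                    coup = 0.0
                    for kk in range(n_sites):
                        if kk != j:
                            coup += W[i, kk] * n_cur[kk]
                    dE += dni * coup
                if dnj != 0:
                    coup = 0.0
                    for kk in range(n_sites):
                        if kk != i:
                            coup += W[j, kk] * n_cur[kk]
                    dE += dnj * coup
                dE += W[i, j] * (
                    n_prot[i, b_i] * n_prot[j, b_j] - n_prot[i, a_i] * n_prot[j, a_j]
                )
                if dE <= 0.0 or np.random.random() < 10.0 ** (-dE):
                    state[i] = b_i
                    state[j] = b_j
                    n_cur[i] = n_prot[i, b_i]
                    n_cur[j] = n_prot[j, b_j]
                    acc_p += 1
        if cycle >= burn_in:
            t = cycle - burn_in
            blk = t // block_len
            if blk >= n_blocks:
                blk = n_blocks - 1
            for i in range(n_sites):
                sum_n[i] += n_cur[i]
                blocks[blk, i] += n_cur[i]
    return sum_n, blocks, acc_s, att_s, acc_p, att_p


def interacting_pairs(W: np.ndarray, threshold: float) -> np.ndarray:
    """Index pairs (i<j) with coupling magnitude above the threshold."""
    n = W.shape[0]
    out = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(W[i, j]) > threshold
    ]
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def run_mc(
    system: SiteSystem,
    config: MCConfig,
    initial_state: ProtonationState | None = None,
) -> MCResult:
    """Metropolis MC at fixed pH with single-site and pair moves.

    Each cycle attempts one move per site and one joint move per strongly
    coupled pair, in randomized order.  Averages are taken after the
    burn-in; standard errors come from block averaging over
    ``config.n_blocks`` blocks.  Identical seed and config give bitwise
    identical results.
    """
    if system.n_sites == 0:
        return MCResult(
            np.zeros(0), np.zeros(0), 0.0, 0.0, 0.0,
            ProtonationState(()), config, config.n_cycles,
        )
    n_prot, dg = _field_tables(system, config.pH)
    ks = system.n_states
    pairs = interacting_pairs(system.W, config.pair_threshold)
    if initial_state is None:
        initial_state = ProtonationState.reference(system)
    state = np.array(initial_state.state_index, dtype=np.int64).copy()
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    burn_in = int(config.burn_in_fraction * config.n_cycles)
    measured = config.n_cycles - burn_in
    sum_n, blocks, acc_s, att_s, acc_p, att_p = _mc_kernel(
        ks,
        n_prot,
        dg.astype(np.float64),
        system.W.astype(np.float64),
        pairs,
        state,
        int(config.n_cycles),
        burn_in,
        int(seed) % (2**31),
        int(config.n_blocks),
    )
    mean_n = sum_n / measured
    block_len = max(measured // config.n_blocks, 1)
    # cycles actually contributing to each block (last block absorbs remainder)
    counts = np.full(config.n_blocks, block_len, dtype=float)
    counts[-1] = measured - block_len * (config.n_blocks - 1)
    bm = blocks / counts[:, None]
    se = (
        bm.std(axis=0, ddof=1) / np.sqrt(config.n_blocks)
        if config.n_blocks > 1
        else np.zeros_like(mean_n)
    )
    offsets = np.array([s.charge_offset for s in system.sites], dtype=float)
    return MCResult(
        mean_protonation=mean_n,
        se=se,
        mean_total_charge=float(mean_n.sum() + offsets.sum()),
        acceptance_single=acc_s / att_s if att_s else 0.0,
        acceptance_pair=acc_p / att_p if att_p else 0.0,
        final_state=ProtonationState(tuple(int(s) for s in state)),
        config=replace(config, seed=int(seed)),
        n_measured_cycles=measured,
    )


def titration_scan(
    system: SiteSystem,
    ph_grid,
    config: MCConfig = MCConfig(),
    n_replicates: int = 1,
) -> tuple[TitrationRecord, dict]:
    """Run the sampler over a pH grid (optionally replicated).

    Returns a tidy :class:`TitrationRecord` plus a dict mapping
    ``(pH, replicate)`` to the underlying :class:`MCResult`.  Seeds for the
    individual runs are derived deterministically from ``config.seed``.
    """
    ph_grid = np.atleast_1d(np.asarray(ph_grid, dtype=float))
    rng = np.random.default_rng(config.seed)
    rows = []
    results: dict = {}
    for rep in range(n_replicates):
        for ph in ph_grid:
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = run_mc(system, replace(config, pH=float(ph), seed=sub_seed))
            results[(float(ph), rep)] = res
            for s, m, e in zip(system.sites, res.mean_protonation, res.se):
                rows.append(
                    (float(ph), rep, s.id, float(m), float(e),
                     float(m + s.charge_offset))
                )
    if not rows:
        return TitrationRecord(), results
    return TitrationRecord.from_rows(rows), results
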
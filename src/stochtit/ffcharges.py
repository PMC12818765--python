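"""Charge localization for PB-compatible force-field residue blocks.

Poisson-Boltzmann based protonation sampling requires that the side chain of
every titratable residue carries an integer formal charge, so that switching
protonation states never propagates fractional charge into the backbone.
Additive force fields in the AMBER family do not enforce this: the residual
side-chain charge is absorbed by the backbone during RESP fitting.  The
protocol implemented here restores locality with a minimal edit -- the
residual charge ``delta`` between the side-chain region and its integer
formal charge is transferred between the C-beta group (C-beta and its bound
hydrogens) and the C-alpha group (C-alpha and H-alpha), leaving every other
atom untouched.  Averaged and neutral N-/C-terminus blocks are constructed
the same way.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .units import INTEGER_CHARGE_TOL

__all__ = [
    "AtomCharge",
    "ResidueBlock",
    "ChargeDiff",
    "PartitionReport",
    "StructureError",
    "assign_region",
    "localize_side_chain",
    "average_termini_mainchain",
    "build_neutral_nterminus",
    "build_neutral_cterminus",
    "validate_partition",
    "read_rtp",
    "write_rtp",
]


class StructureError(ValueError):
    """A residue block is missing atoms or is otherwise malformed."""


# ---------------------------------------------------------------------------
# Region templates
# ---------------------------------------------------------------------------

#: Backbone atoms (incl. charged/neutral termini variants).
MAIN_CHAIN_ATOMS = frozenset(
    {
        "N", "H", "HN", "C", "O", "OXT", "OT1", "OT2",
        # N-terminus amine
        "H1", "H2", "H3",
        # neutral C-terminus carboxyl
        "OC1", "OC2", "HC11", "HC12", "HC21", "HC22",
    }
)

#: Default alpha/beta groups; proline re-routes its backbone through C-delta
#: so both C-alpha and C-delta (and their hydrogens) take the backbone-side
#: correction, while the side-chain-side correction spreads over C-beta and
#: C-gamma.
_DEFAULT_ALPHA = frozenset({"CA", "HA", "HA1", "HA2", "HA3"})
_DEFAULT_BETA = frozenset({"CB", "HB", "HB1", "HB2", "HB3"})
_PRO_ALPHA = _DEFAULT_ALPHA | {"CD", "HD1", "HD2", "HD3"}
_PRO_BETA = _DEFAULT_BETA | {"CG", "HG1", "HG2", "HG3"}

_ALPHA_HEAVY = {"default": ("CA",), "PRO": ("CA", "CD")}
_BETA_HEAVY = {"default": ("CB",), "PRO": ("CB", "CG")}


def _is_proline(residue_name: str) -> bool:
    return residue_name.upper().rstrip("0123456789").endswith("PRO")


def assign_region(atom_name: str, residue_name: str = "XXX") -> str:
    """Region of an atom purely from its name and the residue template.

    Returns one of ``main_chain``, ``alpha_group``, ``beta_group`` or
    ``side_chain``.
    """
    name = atom_name.upper()
    alpha = _PRO_ALPHA if _is_proline(residue_name) else _DEFAULT_ALPHA
    beta = _PRO_BETA if _is_proline(residue_name) else _DEFAULT_BETA
    if name in alpha:
        return "alpha_group"
    if name in beta:
        return "beta_group"
    if name in MAIN_CHAIN_ATOMS:
        return "main_chain"
    return "side_chain"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomCharge:
    """One atom of a residue block: name, partial charge and region."""

    name: str
    partial_charge: float
    region: str
    atype: str = "X"  # force-field atom type (round-trip only)
    cgnr: int = 0  # charge-group number (round-trip only)

    def __post_init__(self):
        if self.region not in {"main_chain", "side_chain", "alpha_group", "beta_group"}:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass(frozen=True)
class ResidueBlock:
    """Named residue-topology fragment with an ordered atom/charge list.

    ``formal_side_chain_charge`` / ``formal_total_charge`` are the integer
    charges the represented protonation state should carry; the block's
    partial charges must sum to the total within ``INTEGER_CHARGE_TOL``.
    ``frozen`` marks blocks that the localization protocol must not touch
    (e.g. the charged N-terminal glycine, kept in its published form).
    """

    name: str
    atoms: tuple[AtomCharge, ...]
    formal_side_chain_charge: int
    formal_total_charge: int
    frozen: bool = False
    extra_sections: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        names = [a.name for a in self.atoms]
        if len(set(names)) != len(names):
            raise StructureError(f"{self.name}: duplicate atom names")
        total = sum(a.partial_charge for a in self.atoms)
        if abs(total - self.formal_total_charge) > INTEGER_CHARGE_TOL:
            raise StructureError(
                f"{self.name}: partial charges sum to {total:.6f}, "
                f"expected formal total {self.formal_total_charge}"
            )

    @classmethod
    def from_charges(
        cls,
        name: str,
        charges: Sequence[tuple[str, float]],
        formal_side_chain_charge: int | None = None,
        formal_total_charge: int | None = None,
        frozen: bool = False,
        atypes: Sequence[str] | None = None,
    ) -> "ResidueBlock":
        """Build a block from ``(atom_name, charge)`` pairs.

        Formal charges default to the nearest integer of the corresponding
        region sums, which is the usual situation when reading published
        topology files.
        """
        atoms = tuple(
            AtomCharge(
                n,
                q,
                assign_region(n, name),
                atype=(atypes[i] if atypes is not None else "X"),
                cgnr=i,
            )
            for i, (n, q) in enumerate(charges)
        )
        side = sum(
            a.partial_charge for a in atoms if a.region in ("side_chain", "beta_group")
        )
        total = sum(a.partial_charge for a in atoms)
        if formal_side_chain_charge is None:
            formal_side_chain_charge = round(side)
        if formal_total_charge is None:
            formal_total_charge = round(total)
        return cls(name, atoms, formal_side_chain_charge, formal_total_charge, frozen)

    # -- convenience ---------------------------------------------------
    def charge(self, atom_name: str) -> float:
        for a in self.atoms:
            if a.name == atom_name:
                return a.partial_charge
        raise KeyError(atom_name)

    def region_sum(self, *regions: str) -> float:
        return sum(a.partial_charge for a in self.atoms if a.region in regions)

    @property
    def side_chain_sum(self) -> float:
        """Side-chain region charge (side chain proper plus C-beta group)."""
        return self.region_sum("side_chain", "beta_group")

    @property
    def main_chain_sum(self) -> float:
        """Backbone region charge (main chain proper plus C-alpha group)."""
        return self.region_sum("main_chain", "alpha_group")

    @property
    def total_charge(self) -> float:
        return sum(a.partial_charge for a in self.atoms)

    def with_charges(self, new: dict[str, float]) -> "ResidueBlock":
        atoms = tuple(
            replace(a, partial_charge=new.get(a.name, a.partial_charge))
            for a in self.atoms
        )
        return replace(self, atoms=atoms)


@dataclass(frozen=True)
class ChargeDiff:
    """Per-atom record of what a charge operation changed."""

    residue: str
    entries: tuple[tuple[str, float, float, float], ...]  # name, old, new, delta
    suspicious: bool = False  # |transferred charge| > 0.5 e

    @property
    def max_abs_delta(self) -> float:
        return max((abs(e[3]) for e in self.entries), default=0.0)

    @property
    def changed_atoms(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries if e[3] != 0.0)

    def to_tsv(self) -> str:
        lines = ["atom\told\tnew\tdelta"]
        for name, old, new, delta in self.entries:
            lines.append(f"{name}\t{old:.6f}\t{new:.6f}\t{delta:.6f}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class PartitionReport:
    """Result of checking the integer main/side-chain charge partition."""

    residue: str
    main_chain_sum: float
    side_chain_sum: float
    nearest_main: int
    nearest_side: int
    main_deviation: float
    side_deviation: float
    passed: bool

    def __str__(self) -> str:  # human-readable report
        status = "PASS" if self.passed else "FAIL"
        return (
            f"{self.residue}: main={self.main_chain_sum:+.6f} "
            f"(nearest {self.nearest_main:+d}, dev {self.main_deviation:.2e}) "
            f"side={self.side_chain_sum:+.6f} "
            f"(nearest {self.nearest_side:+d}, dev {self.side_deviation:.2e}) "
            f"[{status}]"
        )


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def _heavy_names(block: ResidueBlock, which: str) -> tuple[str, ...]:
    key = "PRO" if _is_proline(block.name) else "default"
    table = _ALPHA_HEAVY if which == "alpha" else _BETA_HEAVY
    present = tuple(n for n in table[key] if any(a.name == n for a in block.atoms))
    return present


def _distribute(
    block: ResidueBlock, group: str, amount: float, split_policy: str
) -> dict[str, float]:
    """Charge increments that add ``amount`` to the given group."""
    members = [a for a in block.atoms if a.region == group]
    if not members:
        raise StructureError(f"{block.name}: no atoms in {group}")
    if split_policy == "heavy_only":
        heavy = _heavy_names(block, "alpha" if group == "alpha_group" else "beta")
        if not heavy:
            raise StructureError(f"{block.name}: no heavy atom found in {group}")
        return {n: amount / len(heavy) for n in heavy}
    if split_policy == "proportional":
        weights = [abs(a.partial_charge) for a in members]
        wsum = sum(weights)
        if wsum == 0.0:
            weights = [1.0] * len(members)
            wsum = float(len(members))
        return {a.name: amount * w / wsum for a, w in zip(members, weights)}
    raise ValueError(f"unknown split_policy {split_policy!r}")


def localize_side_chain(
    block: ResidueBlock, split_policy: str = "heavy_only"
) -> tuple[ResidueBlock, ChargeDiff]:
    """Make the side-chain region carry its integer formal charge.

    The residual ``delta = side_chain_sum - formal_side_chain_charge`` is
    removed from the C-beta group and added to the C-alpha group, so the
    total block charge is conserved and only those two groups change.
    Blocks flagged ``frozen`` are returned unchanged with an empty diff.
    """
    if block.frozen:
        return block, ChargeDiff(block.name, ())
    if not any(a.region == "alpha_group" for a in block.atoms):
        raise StructureError(f"{block.name}: no C-alpha group")
    if not any(a.region == "beta_group" for a in block.atoms):
        raise StructureError(f"{block.name}: no C-beta group")

    delta = block.side_chain_sum - block.formal_side_chain_charge
    if abs(delta) < 1e-12:  # float dust: keep the map bitwise idempotent
        return block, ChargeDiff(block.name, ())
    incr: dict[str, float] = {}
    for name, d in _distribute(block, "beta_group", -delta, split_policy).items():
        incr[name] = incr.get(name, 0.0) + d
    for name, d in _distribute(block, "alpha_group", +delta, split_policy).items():
        incr[name] = incr.get(name, 0.0) + d

    new = block.with_charges(
        {n: block.charge(n) + d for n, d in incr.items()}
    )
    entries = tuple(
        (a.name, a.partial_charge, new.charge(a.name), incr.get(a.name, 0.0))
        for a in block.atoms
        if a.name in incr
    )
    diff = ChargeDiff(block.name, entries, suspicious=abs(delta) > 0.5)
    return new, diff


def validate_partition(block: ResidueBlock) -> PartitionReport:
    """Report how far the main/side-chain sums are from integer charges."""
    main = block.main_chain_sum
    side = block.side_chain_sum
    nm, ns = round(main), round(side)
    dm, ds = abs(main - nm), abs(side - ns)
    return PartitionReport(
        block.name, main, side, nm, ns, dm, ds,
        passed=(dm < INTEGER_CHARGE_TOL and ds < INTEGER_CHARGE_TOL),
    )


def _mainchain_names(block: ResidueBlock) -> tuple[str, ...]:
    return tuple(a.name for a in block.atoms if a.region == "main_chain")


def average_termini_mainchain(
    blocks: Sequence[ResidueBlock],
    exclude: Iterable[str] = ("PRO", "GLY"),
    split_policy: str = "heavy_only",
) -> ResidueBlock:
    """Average backbone charges over terminus blocks into one template.

    Terminal residue blocks of an additive force field differ slightly in
    their backbone charges.  This averages the main-chain atom charges over
    all given blocks (excluded residue codes dropped first), grafts them
    onto the first remaining block, and re-balances the C-alpha group so the
    template keeps its integer formal charges.
    """
    excl = {c.upper() for c in exclude}
    kept = [
        b for b in blocks
        if not any(b.name.upper().endswith(c) for c in excl)
    ]
    if not kept:
        raise StructureError("no blocks left after exclusion")
    ref_names = _mainchain_names(kept[0])
    for b in kept[1:]:
        if set(_mainchain_names(b)) != set(ref_names):
            raise StructureError(
                f"{b.name}: main-chain atom set differs from {kept[0].name}"
            )
    means = {
        n: sum(b.charge(n) for b in kept) / len(kept) for n in ref_names
    }
    base = kept[0]
    merged_total = base.total_charge + sum(
        means[n] - base.charge(n) for n in ref_names
    )
    # restore the integer total by absorbing the residual into the C-alpha group
    residual = merged_total - base.formal_total_charge
    incr = _distribute(base, "alpha_group", -residual, split_policy)
    updates = dict(means)
    for n, d in incr.items():
        updates[n] = updates.get(n, base.charge(n)) + d
    return base.with_charges(updates)


def _build_neutral_terminus(
    template: ResidueBlock,
    source: ResidueBlock,
    group_atoms: Sequence[str],
    name: str,
    split_policy: str,
) -> ResidueBlock:
    missing = [n for n in group_atoms if not any(a.name == n for a in source.atoms)]
    if missing:
        raise StructureError(f"{source.name}: source lacks atoms {missing}")
    missing_t = [n for n in group_atoms if not any(a.name == n for a in template.atoms)]
    if missing_t:
        raise StructureError(f"{template.name}: template lacks atoms {missing_t}")
    updates = {n: source.charge(n) for n in group_atoms}
    grafted_total = template.total_charge + sum(
        source.charge(n) - template.charge(n) for n in group_atoms
    )
    residual = grafted_total - 0.0  # neutral form target
    incr = _distribute(template, "alpha_group", -residual, split_policy)
    for n, d in incr.items():
        updates[n] = updates.get(n, template.charge(n)) + d
    atoms = tuple(
        replace(a, partial_charge=updates.get(a.name, a.partial_charge))
        for a in template.atoms
    )
    return replace(template, atoms=atoms, name=name, formal_total_charge=0)


def build_neutral_nterminus(
    template: ResidueBlock,
    amine_source: ResidueBlock,
    amine_atoms: Sequence[str] = ("N", "H1", "H2", "H3"),
    name: str | None = None,
    split_policy: str = "heavy_only",
) -> ResidueBlock:
    """Neutral N-terminus: amine charges copied from a neutral-amine donor.

    The published neutral-lysine amine charges are grafted onto the averaged
    terminus template and the C-alpha group absorbs the residual so the
    block is exactly neutral.
    """
    return _build_neutral_terminus(
        template, amine_source, amine_atoms,
        name or f"{template.name}_NEU", split_policy,
    )


def build_neutral_cterminus(
    template: ResidueBlock,
    carboxyl_source: ResidueBlock,
    carboxyl_atoms: Sequence[str] = (
        "C", "OC1", "OC2", "HC11", "HC12", "HC21", "HC22"
    ),
    name: str | None = None,
    split_policy: str = "heavy_only",
) -> ResidueBlock:
    """Neutral C-terminus: carboxyl charges from a protonated-acid donor."""
    present = [n for n in carboxyl_atoms if any(a.name == n for a in carboxyl_source.atoms)]
    if not present:
        raise StructureError(f"{carboxyl_source.name}: no carboxyl atoms found")
    return _build_neutral_terminus(
        template, carboxyl_source, present,
        name or f"{template.name}_NEU", split_policy,
    )


# ---------------------------------------------------------------------------
# rtp-style dialect I/O
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^\s*\[\s*(\S+)\s*\]\s*$")


def read_rtp(text_or_path) -> list[ResidueBlock]:
    """Parse residue blocks from a GROMACS-rtp-style text.

    Only the ``[ atoms ]`` section (name / type / charge / charge-group
    columns) is interpreted; any other section inside a residue entry is
    preserved verbatim and written back unchanged.
    """
    try:
        text = text_or_path.read_text()
    except AttributeError:
        text = text_or_path
    blocks: list[ResidueBlock] = []
    current: str | None = None
    section: str | None = None
    atoms: list[tuple[str, float]] = []
    atypes: list[str] = []
    extras: dict[str, list[str]] = {}

    def flush():
        if current is None:
            return
        if not atoms:
            raise StructureError(f"{current}: no [atoms] section")
        blocks.append(
            replace(
                ResidueBlock.from_charges(current, atoms, atypes=atypes),
                extra_sections=tuple(
                    (k, tuple(v)) for k, v in extras.items()
                ),
            )
        )

    for raw in text.splitlines():
        line = raw.split(";", 1)[0].rstrip()
        if not line.strip():
            continue
        m = _SECTION_RE.match(line)
        if m:
            token = m.group(1)
            if token.lower() in {"atoms", "bonds", "angles", "dihedrals",
                                 "impropers", "exclusions", "cmap"}:
                section = token.lower()
                if section != "atoms":
                    extras.setdefault(section, [])
            else:  # a new residue entry
                flush()
                current = token
                section = None
                atoms, atypes, extras = [], [], {}
            continue
        if current is None:
            continue
        if section == "atoms":
            parts = line.split()
            if len(parts) < 3:
                raise StructureError(f"{current}: bad atom line {line!r}")
            atoms.append((parts[0], float(parts[2])))
            atypes.append(parts[1])
        elif section is not None:
            extras[section].append(line.strip())
    flush()
    return blocks


def write_rtp(blocks: Iterable[ResidueBlock]) -> str:
    """Serialize blocks back to the rtp-style dialect (6-decimal charges)."""
    out: list[str] = []
    for b in blocks:
        out.append(f"[ {b.name} ]")
        out.append(" [ atoms ]")
        for i, a in enumerate(b.atoms):
            out.append(
                f"  {a.name:<6s} {a.atype:<6s} {a.partial_charge:12.6f}  {i}"
            )
        for sec, lines in b.extra_sections:
            out.append(f" [ {sec} ]")
            out.extend(f"  {ln}" for ln in lines)
        out.append("")
    return "\n".join(out)


def group_map_json(block: ResidueBlock) -> str:
    """JSON description of the block's region partition (for reports)."""
    groups: dict[str, list[str]] = {}
    for a in block.atoms:
        groups.setdefault(a.region, []).append(a.name)
    return json.dumps({"residue": block.name, "groups": groups}, indent=2)
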
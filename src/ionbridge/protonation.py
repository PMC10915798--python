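"""Acid-base speciation of polyprotic buffers and integer ion bookkeeping.

Each buffer species is modelled by its two dominant charge states around a
single pKa; minor states are ignored.  Fractions come from the
Henderson-Hasselbalch relation and are apportioned to integer molecule
counts by the largest-remainder rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

AVOGADRO = 6.02214076e23  # 1/mol

__all__ = [
    "ChargeState",
    "ChargeStateSpec",
    "deprotonated_fraction",
    "two_state_composition",
    "ion_count",
    "apportion_states",
]


@dataclass(frozen=True)
class ChargeState:
    charge: float  # elementary-charge units
    fraction: float
    count: int


@dataclass
class ChargeStateSpec:
    """Two-state speciation of one buffer species at a given pH."""

    species: str
    states: tuple[ChargeState, ChargeState]
    pKa: float
    pH: float

    def __post_init__(self) -> None:
        total_fraction = sum(s.fraction for s in self.states)
        if abs(total_fraction - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total_fraction}, expected 1")
        if len(self.states) != 2:
            raise ValueError("exactly two charge states are modelled per species")

    @property
    def total_count(self) -> int:
        return sum(s.count for s in self.states)


def deprotonated_fraction(pH: float, pKa: float) -> float:
    """Fraction of molecules in the more deprotonated (more negative) state.

    ``1 / (1 + 10**(pKa - pH))``; strictly increasing in pH and equal to 0.5
    at pH == pKa.
    """
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def two_state_composition(pH: float, pKa: float) -> tuple[float, float]:
    """(protonated, deprotonated) fractions; their ratio is 10**(pKa - pH)."""
    f = deprotonated_fraction(pH, pKa)
    return (1.0 - f, f)


def ion_count(
    concentration_mM: float, box_length_nm: float, rounding: str = "nearest"
) -> int:
    """Number of molecules of a species at a molar concentration in a cubic box.

    ``N = c * N_A * V`` with V in litres (1 nm^3 = 1e-24 L).  ``rounding`` is
    one of ``nearest`` (default), ``floor``, ``ceil``.
    """
    if concentration_mM < 0:
        raise ValueError(f"concentration must be nonnegative, got {concentration_mM}")
    if box_length_nm <= 0:
        raise ValueError("box length must be positive")
    volume_l = box_length_nm**3 * 1e-24
    exact = concentration_mM * 1e-3 * AVOGADRO * volume_l
    if rounding == "nearest":
        return int(round(exact))
    if rounding == "floor":
        return int(exact // 1)
    if rounding == "ceil":
        return -int(-exact // 1)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def apportion_states(
    total: int,
    fractions: Sequence[float],
    charges: Sequence[float] | None = None,
) -> list[int]:
    """Largest-remainder apportionment of ``total`` molecules over states.

    Counts sum to ``total`` exactly.  Remainder ties are awarded to the state
    with the smaller ``|charge|`` (falling back to state order when charges
    are not given).
    """
    if total < 0:
        raise ValueError("total must be nonnegative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if charges is not None and len(charges) != len(fractions):
        raise ValueError("charges and fractions must have equal length")
    quotas = [f * total for f in fractions]
    counts = [int(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    n_left = total - sum(counts)
    # sort by remainder desc, then smaller |charge|, then state order
    def sort_key(i: int) -> tuple:
        tiebreak = abs(charges[i]) if charges is not None else i
        return (-remainders[i], tiebreak, i)

    for i in sorted(range(len(fractions)), key=sort_key)[:n_left]:
        counts[i] += 1
    return counts


def speciate(
    species: str,
    pH: float,
    pKa: float,
    charges: tuple[float, float],
    total: int,
) -> ChargeStateSpec:
    """Build a full :class:`ChargeStateSpec` for a species.

    ``charges`` is ``(protonated_charge, deprotonated_charge)``.
    """
    fractions = two_state_composition(pH, pKa)
    counts = apportion_states(total, fractions, charges)
    states = tuple(
        ChargeState(charge=q, fraction=f, count=c)
        for q, f, c in zip(charges, fractions, counts)
    )
    return ChargeStateSpec(species=species, states=states, pKa=pKa, pH=pH)
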
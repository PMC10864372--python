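"""Spin-operator algebra for radical-pair Hilbert spaces.

All operators are dense complex matrices in a fixed tensor-product basis:

    electron A  ⊗  electron B  ⊗  nuclei of A (list order)  ⊗  nuclei of B

The spaces in scope are small (≤ a few hundred dimensions), so dense
matrices are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isclose, prod

import numpy as np

__all__ = [
    "SpinSystem",
    "spin_matrices",
    "embed",
    "singlet_projector",
    "electron_spin_ops",
    "nuclear_spin_ops",
]


def _is_half_integer(s: float) -> bool:
    return s >= 0 and isclose(2 * s, round(2 * s), abs_tol=1e-12)


def multiplicity(spins) -> int:
    """Number of nuclear spin configurations, Π(2I+1)."""
    return prod(int(round(2 * s + 1)) for s in spins)


@dataclass(frozen=True)
class SpinSystem:
    """Composite Hilbert-space layout of a two-electron radical pair.

    Parameters
    ----------
    nuclei_A, nuclei_B:
        Spin quantum numbers of the nuclei coupled to electron A / B.
        Each must be a non-negative half-integer.  Spin-0 entries are
        legal; they contribute a trivial one-dimensional factor.
    """

    nuclei_A: tuple = ()
    nuclei_B: tuple = ()
    electron_count: int = field(default=2, init=False)

    def __post_init__(self):
        object.__setattr__(self, "nuclei_A", tuple(float(s) for s in self.nuclei_A))
        object.__setattr__(self, "nuclei_B", tuple(float(s) for s in self.nuclei_B))
        for s in self.nuclei_A + self.nuclei_B:
            if not _is_half_integer(s):
                raise ValueError(f"spin quantum number {s} is not a non-negative half-integer")

    @property
    def M_A(self) -> int:
        return multiplicity(self.nuclei_A)

    @property
    def M_B(self) -> int:
        return multiplicity(self.nuclei_B)

    @property
    def M(self) -> int:
        """Total nuclear multiplicity M = M_A * M_B."""
        return self.M_A * self.M_B

    @property
    def dim(self) -> int:
        return 4 * self.M

    @property
    def factor_spins(self) -> tuple:
        """Spins of every tensor factor, electrons first."""
        return (0.5, 0.5) + self.nuclei_A + self.nuclei_B

    @property
    def factor_dims(self) -> tuple:
        return tuple(int(round(2 * s + 1)) for s in self.factor_spins)

    @property
    def basis_note(self) -> str:
        return (
            "electron A ⊗ electron B ⊗ nuclei_A"
            f"{list(self.nuclei_A)} ⊗ nuclei_B{list(self.nuclei_B)}; "
            "each factor in |s,m⟩ order m = s…−s"
        )


def spin_matrices(s: float):
    """Angular-momentum matrices (Sx, Sy, Sz) for spin quantum number ``s``.

    Returned in the (2s+1)-dimensional |s, m⟩ basis ordered m = s … −s,
    in units of ħ.  Sz is diagonal; Sx, Sy come from the ladder operators
    S± with ⟨m±1|S±|m⟩ = sqrt(s(s+1) − m(m±1)).
    """
    if not _is_half_integer(s):
        raise ValueError(f"spin quantum number must be a non-negative half-integer, got {s}")
    n = int(round(2 * s + 1))
    m = s - np.arange(n)
    sz = np.diag(m).astype(complex)
    # raising operator: connects |m⟩ → |m+1⟩, i.e. entry (i-1, i)
    sp = np.zeros((n, n), dtype=complex)
    for i in range(1, n):
        sp[i - 1, i] = np.sqrt(s * (s + 1) - m[i] * (m[i] + 1))
    sx = (sp + sp.conj().T) / 2
    sy = (sp - sp.conj().T) / 2j
    return sx, sy, sz


def embed(op: np.ndarray, slot: int, system: SpinSystem) -> np.ndarray:
    """Embed a single-factor operator into the full composite space.

    ``slot`` indexes the tensor factor: 0 = electron A, 1 = electron B,
    2… = nuclei of A in list order, then nuclei of B.
    """
    dims = system.factor_dims
    if not 0 <= slot < len(dims):
        raise IndexError(f"slot {slot} out of range for {len(dims)} factors")
    op = np.asarray(op, dtype=complex)
    if op.shape != (dims[slot], dims[slot]):
        raise ValueError(
            f"operator of shape {op.shape} does not fit factor {slot} of dimension {dims[slot]}"
        )
    out = np.eye(1, dtype=complex)
    for i, d in enumerate(dims):
        out = np.kron(out, op if i == slot else np.eye(d, dtype=complex))
    return out


def electron_spin_ops(system: SpinSystem, which: str):
    """Full-space (Sx, Sy, Sz) of electron 'A' (slot 0) or 'B' (slot 1)."""
    slot = {"A": 0, "B": 1}[which]
    return tuple(embed(m, slot, system) for m in spin_matrices(0.5))


def nuclear_spin_ops(system: SpinSystem, which: str, index: int):
    """Full-space (Ix, Iy, Iz) of nucleus ``index`` on radical 'A' or 'B'."""
    if which == "A":
        spins, offset = system.nuclei_A, 2
    elif which == "B":
        spins, offset = system.nuclei_B, 2 + len(system.nuclei_A)
    else:
        raise ValueError("radical must be 'A' or 'B'")
    return tuple(embed(m, offset + index, system) for m in spin_matrices(spins[index]))


def singlet_projector(system: SpinSystem) -> np.ndarray:
    """Projector onto the two-electron singlet, identity on the nuclei.

    P_S = ¼·I − Ŝ_A·Ŝ_B.  Its trace is M: one singlet state per nuclear
    configuration.
    """
    SA = electron_spin_ops(system, "A")
    SB = electron_spin_ops(system, "B")
    dot = sum(SA[i] @ SB[i] for i in range(3))
    return 0.25 * np.eye(system.dim, dtype=complex) - dot
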
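"""Sequence-dependent mechanical coefficients of the coupled-pendulum DNA model.

Each nitrogenous base is treated as a rigid pendulum rotating about the
sugar-phosphate backbone.  Per base type the model needs five constants:

=========  =========================================  ==========
symbol     meaning                                    SI unit
=========  =========================================  ==========
``I``      moment of inertia of the base              kg·m²
``R``      distance base centre of mass to backbone   m
``K``      torsional stiffness of the backbone link   J
``k12``    hydrogen-bond stiffness of the base pair   N/m
``beta``   solvent dissipation coefficient            J·s
=========  =========================================  ==========

The pair stiffness ``k12`` is a property of the Watson-Crick pair, so the
A and T entries coincide, as do the G and C entries.  The dissipation
coefficient is scaled at run time by the dimensionless solvent-viscosity
factor ``lambda``.

All values are stored in SI units; the published table lists them in
10⁻⁴⁴ kg·m², Å, 10⁻¹⁸ J, 10⁻² N/m and 10⁻³⁴ J·s, and the conversion is
done once, here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "BaseParameters",
    "ChainSystem",
    "DEFAULT_PARAMETERS",
    "map_base_parameters",
    "complement_sequence",
    "build_system",
]

#: Watson-Crick complement map (upper case only; input is normalised first).
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class BaseParameters:
    """Mechanical constants of a single base type, in SI units."""

    base: str
    inertia: float  # kg·m²
    lever: float  # m
    backbone_stiffness: float  # J
    pair_stiffness: float  # N/m
    dissipation: float  # J·s

    def __post_init__(self) -> None:
        if self.base not in COMPLEMENT:
            raise ValueError(f"unsupported base symbol {self.base!r}")
        for name in (
            "inertia",
            "lever",
            "backbone_stiffness",
            "pair_stiffness",
            "dissipation",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


# Published per-base coefficients, written directly as SI decimal literals
# (published units were 1e-44 kg·m², Å, 1e-18 J, 1e-2 N/m, 1e-34 J·s; the
# conversion is folded into the exponents once, here, so the stored values
# are bit-exact decimal representations).
_SI_TABLE: dict[str, tuple[float, float, float, float, float]] = {
    #        I         R        K         k12      beta
    "A": (7.61e-44, 5.80e-10, 2.35e-18, 6.20e-2, 4.25e-34),
    "T": (4.86e-44, 4.80e-10, 1.61e-18, 6.20e-2, 2.91e-34),
    "G": (8.22e-44, 5.70e-10, 2.27e-18, 9.60e-2, 4.10e-34),
    "C": (4.11e-44, 4.70e-10, 1.54e-18, 9.60e-2, 2.79e-34),
}

DEFAULT_PARAMETERS: dict[str, BaseParameters] = {
    base: BaseParameters(
        base=base,
        inertia=i,
        lever=r,
        backbone_stiffness=k,
        pair_stiffness=k12,
        dissipation=b,
    )
    for base, (i, r, k, k12, b) in _SI_TABLE.items()
}


def map_base_parameters(
    base: str, table: Mapping[str, BaseParameters] | None = None
) -> BaseParameters:
    """Return the mechanical constants for one base symbol.

    Parameters
    ----------
    base
        One of ``A``, ``C``, ``G``, ``T`` (case-insensitive).
    table
        Optional override table (e.g. for sensitivity studies); defaults to
        the published constants.

    Raises
    ------
    ValueError
        For any other symbol, including IUPAC ambiguity codes such as ``N``.
    """
    table = DEFAULT_PARAMETERS if table is None else table
    key = str(base).upper()
    if key not in table:
        raise ValueError(
            f"unsupported base symbol {base!r}: parameters exist only for A, C, G, T"
        )
    return table[key]


def _validate_sequence(seq: str) -> str:
    seq = str(seq).upper()
    if len(seq) == 0:
        raise ValueError("sequence must be non-empty")
    for pos, sym in enumerate(seq):
        if sym not in COMPLEMENT:
            raise ValueError(
                f"unsupported base symbol {sym!r} at position {pos} "
                "(only A, C, G, T are allowed)"
            )
    return seq


def complement_sequence(seq: str) -> str:
    """Position-wise Watson-Crick complement, same orientation (no reversal).

    Site ``i`` of the result pairs with site ``i`` of the input: the two
    strands of the model index base *pairs*, not 5'->3' reading direction.
    """
    seq = _validate_sequence(seq)
    return "".join(COMPLEMENT[s] for s in seq)


@dataclass
class ChainSystem:
    """Assembled per-site coefficient arrays for both strands of a duplex.

    ``strand1`` is the input sequence, ``strand2`` its position-wise
    complement.  All arrays have length ``n`` and SI units.  The effective
    dissipation used in the equations of motion is ``lambda * beta`` per
    site and strand.
    """

    strand1: str
    strand2: str
    I1: np.ndarray
    I2: np.ndarray
    R1: np.ndarray
    R2: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    k12: np.ndarray
    lam: float = 1.0
    sign_convention: str = "printed"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("viscosity scale lambda must be > 0")
        if self.sign_convention not in ("printed", "symmetrized"):
            raise ValueError(
                "sign_convention must be 'printed' or 'symmetrized', "
                f"got {self.sign_convention!r}"
            )
        n = len(self.strand1)
        if n < 2:
            raise ValueError(
                f"need at least 2 base pairs (got {n}): the chain boundary "
                "equations require a first and a last site"
            )
        for name in ("I1", "I2", "R1", "R2", "K1", "K2", "beta1", "beta2", "k12"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"coefficient array {name} must have shape ({n},)")
            setattr(self, name, arr)

    @property
    def n(self) -> int:
        """Number of base pairs."""
        return len(self.strand1)

    @property
    def effective_beta1(self) -> np.ndarray:
        """Strand-1 dissipation actually used in the equations: lambda*beta."""
        return self.lam * self.beta1

    @property
    def effective_beta2(self) -> np.ndarray:
        """Strand-2 dissipation actually used in the equations: lambda*beta."""
        return self.lam * self.beta2

    def with_lambda(self, lam: float) -> "ChainSystem":
        """Copy of this system at a different viscosity scale."""
        return ChainSystem(
            strand1=self.strand1,
            strand2=self.strand2,
            I1=self.I1,
            I2=self.I2,
            R1=self.R1,
            R2=self.R2,
            K1=self.K1,
            K2=self.K2,
            beta1=self.beta1,
            beta2=self.beta2,
            k12=self.k12,
            lam=lam,
            sign_convention=self.sign_convention,
        )


def build_system(
    seq: str,
    lam: float = 1.0,
    table: Mapping[str, BaseParameters] | None = None,
    sign_convention: str = "printed",
) -> ChainSystem:
    """Map a nucleotide sequence to the full per-site coefficient arrays.

    Parameters
    ----------
    seq
        Strand-1 sequence (A/C/G/T, case-insensitive), length >= 2.
    lam
        Dimensionless solvent-viscosity scale (the model's lambda) applied to both strands'
        dissipation coefficients.
    table
        Optional per-base parameter override; defaults to the published
        constants.
    sign_convention
        ``"printed"`` keeps the published strand-2 sign structure
        (non-symmetric); ``"symmetrized"`` mirrors strand 1 (diagnostic
        variant, non-default).
    """
    seq = _validate_sequence(seq)
    if len(seq) < 2:
        raise ValueError(
            f"need at least 2 base pairs (got {len(seq)}): the chain boundary "
            "equations require a first and a last site"
        )
    comp = complement_sequence(seq)
    p1 = [map_base_parameters(s, table) for s in seq]
    p2 = [map_base_parameters(s, table) for s in comp]
    k12_1 = np.array([p.pair_stiffness for p in p1])
    k12_2 = np.array([p.pair_stiffness for p in p2])
    # cannot disagree for the default table (pair members share k12); guards
    # override tables that break the pair-equality invariant
    if not np.allclose(k12_1, k12_2, rtol=0, atol=0):
        raise ValueError("pair stiffness k12 differs between pair members")
    return ChainSystem(
        strand1=seq,
        strand2=comp,
        I1=np.array([p.inertia for p in p1]),
        I2=np.array([p.inertia for p in p2]),
        R1=np.array([p.lever for p in p1]),
        R2=np.array([p.lever for p in p2]),
        K1=np.array([p.backbone_stiffness for p in p1]),
        K2=np.array([p.backbone_stiffness for p in p2]),
        beta1=np.array([p.dissipation for p in p1]),
        beta2=np.array([p.dissipation for p in p2]),
        k12=k12_1,
        lam=float(lam),
        sign_convention=sign_convention,
    )
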
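"""Super-coarse-grained 4-block model of a cooperative homodimer.

Each monomer is reduced to two blocks (ligand-binding domain and DNA-binding
domain), each carrying one internal breathing amplitude b_i; three
inter-block relative displacements u12 (across the dimer interface) and
u13, u24 (within each monomer) complete a 7-degree-of-freedom harmonic
model with stiffness

    E = 1/2 sum_i k_i b_i^2 + 1/2 k12 u12^2 + 1/2 k13 u13^2 + 1/2 k24 u24^2
      - c [ j12 u12 (b1+b2) + j13 u13 (b1+b3) + j24 u24 (b2+b4) ]

where the geometric cross-couplings j_e are set once by the apo stiffnesses
(j_e = k_e of the unbound state) and c is a dimensionless coupling
coefficient. Ligand binding multiplies the diagonal stiffnesses only:
k1 (then k2) by beta, the interface coupling k12 by alpha per event, and
the intra-monomer coupling of the bound side (k13 then k24) by gamma; the
cross-couplings are geometric and stay fixed. A note on this choice: if the
cross terms were completed squares (each displacement relaxing freely
against its own spring), the determinant would factorize over the tree of
block contacts and all cooperativity would vanish identically; and if the
cross-couplings scaled with the binding factors, the 0/1/2-ligand
determinant combination is provably never anti-cooperative. Fixed geometric
coupling is the minimal structure that leaves the wild-type parameter sets
on the anti-cooperative side.

Free energies follow from (R*T/2) ln det of the stiffness matrix, and the
+1/-2/+1 combination over 0/1/2 bound ligands gives the allosteric free
energy. With c = 0 the matrix is diagonal and the binding factors cancel
exactly (ddG = 0); the 7x7 dimension is the same in all states, so a global
stiffness rescale also cancels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, R_CAL

__all__ = [
    "BlockParams",
    "BlockStiffness",
    "CAP_PARAMS",
    "GLXR_PARAMS",
    "block_stiffness",
    "block_free_energy",
    "block_cooperativity",
    "cooperativity_landscape",
]

COORDS = ("b1", "b2", "b3", "b4", "u12", "u13", "u24")


@dataclass(frozen=True)
class BlockParams:
    """Stiffnesses (kcal mol^-1 A^-2), binding factors and geometry.

    k1, k2 : internal breathing stiffness of the two ligand-binding blocks
    k3, k4 : internal stiffness of the two DNA-binding blocks
    k12    : inter-monomer (interface) coupling
    k13, k24 : intra-monomer couplings between the two domains of a monomer
    alpha, beta, gamma : multiplicative binding factors on k12, k1/k2, k13/k24
    c      : breathing-displacement geometric coupling coefficient
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k12: float
    k13: float
    k24: float
    alpha: float
    beta: float
    gamma: float
    c: float = 0.15
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4", "k12", "k13", "k24",
                     "alpha", "beta", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @staticmethod
    def symmetric(k1, k3, k12, k13, alpha, beta, gamma, c=0.15,
                  temperature=DEFAULT_TEMPERATURE) -> "BlockParams":
        """Homodimer-symmetric constructor (k1 = k2, k3 = k4, k13 = k24)."""
        return BlockParams(k1, k1, k3, k3, k12, k13, k13,
                           alpha, beta, gamma, c, temperature)


#: Wild-type parameter sets calibrated on the full CAP and GlxR proteins.
CAP_PARAMS = BlockParams.symmetric(
    k1=13.70, k3=3.98, k12=27.08, k13=5.19, alpha=1.30, beta=0.560, gamma=0.901
)
GLXR_PARAMS = BlockParams.symmetric(
    k1=12.85, k3=3.98, k12=24.67, k13=4.21, alpha=1.40, beta=0.71, gamma=0.99
)


@dataclass(frozen=True)
class BlockStiffness:
    """7x7 symmetric stiffness matrix over (b1, b2, b3, b4, u12, u13, u24)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, float)
        if M.shape != (7, 7) or not np.allclose(M, M.T):
            raise ValueError("block stiffness must be a symmetric 7x7 matrix")
        object.__setattr__(self, "matrix", M)


def _bound_params(p: BlockParams, bound: int) -> dict:
    k = dict(k1=p.k1, k2=p.k2, k3=p.k3, k4=p.k4,
             k12=p.k12, k13=p.k13, k24=p.k24)
    if bound >= 1:
        k["k1"] *= p.beta
        k["k12"] *= p.alpha
        k["k13"] *= p.gamma
    if bound == 2:
        k["k2"] *= p.beta
        k["k12"] *= p.alpha
        k["k24"] *= p.gamma
    return k


def block_stiffness(p: BlockParams, bound: int) -> BlockStiffness:
    """Hessian of the block energy with 0, 1 or 2 ligands bound.

    Diagonal stiffnesses carry the binding factors; the breathing to
    displacement cross-couplings are geometric (c times the apo stiffness
    of that contact) and identical in all three states.
    """
    if bound not in (0, 1, 2):
        raise ValueError("bound must be 0, 1 or 2")
    k = _bound_params(p, bound)
    j = _bound_params(p, 0)  # geometric couplings from the apo state
    K = np.zeros((7, 7))
    for i, name in enumerate(("k1", "k2", "k3", "k4")):
        K[i, i] = k[name]
    couplings = (
        ("k12", 4, (0, 1)),  # u12 with b1 + b2
        ("k13", 5, (0, 2)),  # u13 with b1 + b3
        ("k24", 6, (1, 3)),  # u24 with b2 + b4
    )
    for name, ui, (ba, bb) in couplings:
        K[ui, ui] = k[name]
        for b in (ba, bb):
            K[ui, b] -= p.c * j[name]
            K[b, ui] -= p.c * j[name]
    vals = np.linalg.eigvalsh(K)
    if vals[0] <= 0:
        raise ValueError(f"block stiffness not positive definite (min eig {vals[0]:.3g})")
    return BlockStiffness(K)


def block_free_energy(K: BlockStiffness, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """(R*T/2) ln det K, cal mol^-1, up to a state-independent constant."""
    sign, logdet = np.linalg.slogdet(K.matrix)
    if sign <= 0:
        raise ValueError("block stiffness matrix is singular or indefinite")
    return 0.5 * R_CAL * temperature * logdet


def block_cooperativity(p: BlockParams) -> tuple:
    """(ddG in cal mol^-1, K2/K1) from the three ligation-state determinants."""
    g = [block_free_energy(block_stiffness(p, b), p.temperature) for b in (0, 1, 2)]
    ddg = g[2] + g[0] - 2.0 * g[1]
    return ddg, float(np.exp(ddg / (R_CAL * p.temperature)))


def cooperativity_landscape(
    p: BlockParams, k1_grid, k12_grid
) -> pd.DataFrame:
    """ddG surface over (k1 = k2, k12) with other parameters at wild type.

    Cells whose three ligation states are not all positive definite are
    marked invalid (NaN) rather than fatal. The sign of ddG locates the
    boundary between negative (ddG > 0) and positive cooperativity.
    """
    rows = []
    for k1 in k1_grid:
        for k12 in k12_grid:
            try:
                q = replace(p, k1=float(k1), k2=float(k1), k12=float(k12))
                ddg, ratio = block_cooperativity(q)
            except ValueError:
                ddg, ratio = float("nan"), float("nan")
            rows.append((float(k1), float(k12), ddg, ratio))
    return pd.DataFrame(rows, columns=["k1", "k12", "ddG", "K2_over_K1"])
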
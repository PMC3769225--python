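"""Sequential-site analysis of isothermal titration calorimetry data.

A homodimer with s sequential binding steps is described by stepwise
dissociation constants K_i and stepwise molar enthalpies dH_i. At free
ligand concentration [L] the fraction of protein with i ligands bound is

    F_i = (prod_{j<=i} [L]/K_j) / sum_{i'} (prod_{j<=i'} [L]/K_j),

the cell heat content is Q = V0 * P_tot * sum_i F_i * (sum_{l<=i} dH_l),
and each injection's heat is the change in Q corrected for the volume
displaced from the (overfilled, constant-volume) cell. CAP is fitted with
s = 3 (two major cAMP sites plus one minor site); GlxR with s = 2.

The cooperativity ratio K2/K1 of the two major sites is reported either
raw or statistically corrected (divided by 4, the ratio expected for two
identical independent sites on a symmetric dimer), so that 1 means
non-cooperative and values above 1 mean negative cooperativity on the same
scale as the elastic-network prediction exp(ddG/RT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "TitrationSeries",
    "SequentialBindingModel",
    "SequentialBindingFit",
    "free_ligand",
    "bound_fractions",
    "cumulative_heat",
    "injection_heats",
    "fit_sequential",
    "cooperativity_from_fit",
    "read_titration_csv",
    "write_titration_csv",
]


@dataclass(frozen=True)
class SequentialBindingModel:
    """Stepwise dissociation constants (M) and enthalpies (cal mol^-1)."""

    K: tuple
    dH: tuple

    def __post_init__(self) -> None:
        if len(self.K) != len(self.dH):
            raise ValueError("K and dH must have equal length")
        if any(k <= 0 for k in self.K):
            raise ValueError("dissociation constants must be > 0")

    @property
    def n_sites(self) -> int:
        return len(self.K)


@dataclass(frozen=True)
class TitrationSeries:
    """One ITC experiment: geometry, concentrations and per-injection heats.

    cell_volume_uL   : active cell volume V0
    cell_protein_M   : initial protein concentration in the cell (dimer basis)
    syringe_ligand_M : ligand concentration in the syringe
    injection_volumes_uL / heats_ucal : parallel per-injection arrays
    """

    cell_volume_uL: float
    cell_protein_M: float
    syringe_ligand_M: float
    injection_volumes_uL: np.ndarray
    heats_ucal: np.ndarray
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "injection_volumes_uL",
            np.asarray(self.injection_volumes_uL, float))
        object.__setattr__(self, "heats_ucal", np.asarray(self.heats_ucal, float))
        if self.cell_volume_uL <= 0:
            raise ValueError("cell volume must be > 0")
        if self.cell_protein_M < 0 or self.syringe_ligand_M < 0:
            raise ValueError("concentrations must be >= 0")
        if len(self.injection_volumes_uL) != len(self.heats_ucal):
            raise ValueError("volumes and heats must be parallel")
        if len(self.heats_ucal) < 3:
            raise ValueError("a titration needs at least 3 injections")


@dataclass(frozen=True)
class SequentialBindingFit:
    """Result of a least-squares sequential-site fit."""

    model: SequentialBindingModel
    rss: float
    n_obs: int
    converged: bool
    message: str = ""
    n_starts: int = 1


def bound_fractions(L: float, model: SequentialBindingModel) -> np.ndarray:
    """Fractions F_0..F_s of protein with 0..s ligands bound at free [L]."""
    if L < 0:
        raise ValueError("free ligand concentration must be >= 0")
    terms = np.ones(model.n_sites + 1)
    for i, K in enumerate(model.K):
        terms[i + 1] = terms[i] * (L / K)
    return terms / terms.sum()


def free_ligand(L_tot: float, P_tot: float, model: SequentialBindingModel) -> float:
    """Free ligand concentration from the mass balance, by bracketed root finding.

    Solves L_tot = [L] + P_tot * sum_i i * F_i([L]); the root is unique and
    bracketed in [0, L_tot].
    """
    if L_tot < 0 or P_tot < 0:
        raise ValueError("total concentrations must be >= 0")
    if L_tot == 0:
        return 0.0
    if P_tot == 0:
        return L_tot

    def residual(L):
        F = bound_fractions(L, model)
        return L + P_tot * float(np.dot(np.arange(len(F)), F)) - L_tot

    tol = 1e-12 * max(L_tot, 1e-12)
    if residual(L_tot) <= 0:  # numerically saturated
        return L_tot
    return brentq(residual, 0.0, L_tot, xtol=tol, maxiter=200)


def cumulative_heat(
    model: SequentialBindingModel, L: float, P_tot: float, V0_uL: float
) -> float:
    """Cell heat content Q in ucal at free ligand [L].

    Q = V0 * P_tot * sum_i F_i * (cumulative dH up to i); V0 in uL, P_tot in
    M and dH in cal/mol give 1e-6 cal * 1e6 = ucal directly.
    """
    F = bound_fractions(L, model)
    cum_dH = np.concatenate([[0.0], np.cumsum(model.dH)])
    return float(V0_uL * P_tot * np.dot(F, cum_dH))


def injection_heats(
    series: TitrationSeries, model: SequentialBindingModel
) -> np.ndarray:
    """Forward-model the per-injection heats (ucal) for a titration.

    Standard perfusion-cell bookkeeping: each injection of dV displaces dV
    of cell contents, so cell species dilute by (1 - dV/V0) before the
    injected ligand is added; the measured heat is the change in cell heat
    content plus the average heat carried out with the displaced volume:
    q_j = Q_j - Q_{j-1} + (dV_j/V0) * (Q_j + Q_{j-1}) / 2.
    """
    V0 = series.cell_volume_uL
    P = series.cell_protein_M
    L = 0.0
    if series.injection_volumes_uL.sum() > V0:
        warnings.warn("cumulative injected volume exceeds the cell volume")
    q = np.empty(len(series.injection_volumes_uL))
    Q_prev = 0.0
    for j, dV in enumerate(series.injection_volumes_uL):
        f = dV / V0
        P *= (1.0 - f)
        L = L * (1.0 - f) + series.syringe_ligand_M * f
        Lfree = free_ligand(L, P, model)
        Q = cumulative_heat(model, Lfree, P, V0)
        q[j] = Q - Q_prev + f * (Q + Q_prev) / 2.0
        Q_prev = Q
    return q


def _pack(model: SequentialBindingModel) -> np.ndarray:
    return np.concatenate([np.log(model.K), np.asarray(model.dH, float)])


def _unpack(theta: np.ndarray, s: int) -> SequentialBindingModel:
    logK = np.clip(theta[:s], -80.0, 20.0)
    return SequentialBindingModel(tuple(np.exp(logK)), tuple(theta[s:]))


def fit_sequential(
    series: TitrationSeries,
    s: int,
    init: SequentialBindingModel | None = None,
    discard_first: bool = True,
    n_starts: int = 6,
) -> SequentialBindingFit:
    """Least-squares fit of a sequential s-site model to a titration.

    Dissociation constants are parameterized on a log scale; a deterministic
    multistart grid around the initial guess guards against local minima.
    The first injection is excluded by default (syringe diffusion artefact).
    """
    if s < 1:
        raise ValueError("s must be >= 1")
    obs = series.heats_ucal
    weight = np.ones(len(obs), bool)
    if discard_first:
        weight[0] = False

    def residuals(theta):
        m = _unpack(theta, s)
        return injection_heats(series, m)[weight] - obs[weight]

    if init is None:
        # crude scale guesses from the experiment geometry
        P0 = max(series.cell_protein_M, 1e-9)
        total_heat = obs[weight].sum()
        dh0 = total_heat / (series.cell_volume_uL * P0 * s)
        init = SequentialBindingModel(
            tuple(P0 * (4.0 ** i) for i in range(s)), tuple([dh0] * s)
        )

    theta0 = _pack(init)
    best = None
    offsets = [np.zeros_like(theta0)]
    for i in range(n_starts - 1):
        off = np.zeros_like(theta0)
        off[: s] = ((-1) ** i) * (1.0 + i // 2) * np.log(10.0) / 2.0
        offsets.append(off)
    rss_floor = 1e-12 * float(np.sum(obs[weight] ** 2))
    for off in offsets:
        try:
            sol = least_squares(residuals, theta0 + off, method="lm", xtol=1e-14,
                                ftol=1e-14, max_nfev=20000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
        if rss < rss_floor:  # essentially exact; later starts cannot improve
            break
    if best is None:
        raise RuntimeError("sequential fit failed from every start")
    rss, sol = best
    return SequentialBindingFit(
        model=_unpack(sol.x, s),
        rss=rss,
        n_obs=int(weight.sum()),
        converged=sol.status > 0,
        message=sol.message,
        n_starts=len(offsets),
    )


def cooperativity_from_fit(
    fit: SequentialBindingFit, convention: str = "statistical"
) -> float:
    """K2/K1 of the two major sites from a fitted sequential model.

    "raw" is the stepwise dissociation-constant ratio; "statistical"
    divides by 4 to remove the ratio expected for two identical independent
    sites, putting the value on the intrinsic scale of exp(ddG/RT).
    """
    if fit.model.n_sites < 2:
        raise ValueError("cooperativity needs at least two sites")
    raw = fit.model.K[1] / fit.model.K[0]
    if convention == "raw":
        return float(raw)
    if convention == "statistical":
        return float(raw / 4.0)
    raise ValueError("convention must be 'raw' or 'statistical'")


# ---------------------------------------------------------------------------
# CSV round trip


def write_titration_csv(series: TitrationSeries, path) -> None:
    """Header block (# key,value) + injection table."""
    with open(path, "w") as fh:
        fh.write(f"# cell_volume_uL,{series.cell_volume_uL}\n")
        fh.write(f"# cell_protein_M,{series.cell_protein_M}\n")
        fh.write(f"# syringe_ligand_M,{series.syringe_ligand_M}\n")
        fh.write(f"# temperature_K,{series.temperature}\n")
        fh.write("injection_index,volume_uL,heat_ucal\n")
        for j, (v, q) in enumerate(
            zip(series.injection_volumes_uL, series.heats_ucal), start=1
        ):
            fh.write(f"{j},{v:.6g},{q:.8g}\n")


def read_titration_csv(path) -> TitrationSeries:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, val = line[1:].split(",", 1)
                meta[key.strip()] = float(val)
            elif line and not line.startswith("injection_index"):
                _idx, v, q = line.split(",")
                rows.append((float(v), float(q)))
    vols, heats = zip(*rows)
    return TitrationSeries(
        cell_volume_uL=meta["cell_volume_uL"],
        cell_protein_M=meta["cell_protein_M"],
        syringe_ligand_M=meta["syringe_ligand_M"],
        injection_volumes_uL=np.array(vols),
        heats_ucal=np.array(heats),
        temperature=meta.get("temperature_K", 298.15),
    )
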
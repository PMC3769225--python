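"""Allosteric free energy and cooperativity from elastic-network modes.

Binding is modelled purely through its effect on the vibrational spectrum:
apo, singly bound (holo1) and doubly bound (holo2) networks differ only by
ligand pseudo-nodes. The allosteric free energy

    ddG = (dG_holo2 - dG_holo1) - (dG_holo1 - dG_apo)
        = (R*T/2) * [S_holo2 + S_apo - 2*S_holo1],

with S the sum of log-eigenvalues over nonzero modes, measures how much
harder the second binding event is than the first; K2/K1 = exp(ddG/RT) > 1
is negative cooperativity. With the full mode sums the +1/-2/+1 combination
is balanced (nonzero-mode counts 3N, 3N-3, 3N-6 cancel), so unit and mass
constants drop out.

In-silico mutagenesis rescales the springs of one residue (k_R/k) in all
three states and re-evaluates K2/K1; scanning this over the sequence yields
the allosteric control map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE, R_CAL
from .nma import ModeSpectrum, bfactor_profile, eigenmodes, hessian
from .structure import (
    BuildConfig,
    ElasticNetwork,
    LigationState,
    SpringEdit,
    StructureModel,
    apply_spring_edit,
    build_network,
)

__all__ = [
    "AllosteryResult",
    "EnsembleSummary",
    "FlexibilityDelta",
    "log_mode_sum",
    "allosteric_free_energy",
    "cooperativity_ratio",
    "convergence_profile",
    "ligation_spectra",
    "structure_cooperativity",
    "ensemble_cooperativity",
    "scan_mutagenesis",
    "pair_interaction_scan",
    "flexibility_change",
    "site_fluctuation_change",
]


@dataclass(frozen=True)
class AllosteryResult:
    """Mode sums, allosteric free energy and cooperativity for one structure."""

    S_apo: float
    S_holo1: float
    S_holo2: float
    n_modes: object  # int or "full"
    ddG: float  # cal mol^-1
    K2_over_K1: float
    temperature: float

    def __post_init__(self) -> None:
        expected = float(np.exp(self.ddG / (R_CAL * self.temperature)))
        if not np.isclose(self.K2_over_K1, expected, rtol=1e-12, atol=0):
            raise ValueError("K2/K1 inconsistent with ddG at this temperature")


@dataclass(frozen=True)
class EnsembleSummary:
    """Per-structure values with their unweighted mean and standard error."""

    values: np.ndarray
    source_ids: tuple

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        if self.n < 2:
            return float("nan")
        return float(np.std(self.values, ddof=1) / np.sqrt(self.n))


@dataclass(frozen=True)
class FlexibilityDelta:
    """Per-residue percentage change in calculated B-factor vs wild type."""

    percent: np.ndarray
    labels: tuple


def log_mode_sum(spec: ModeSpectrum, n="full") -> float:
    """Sum of log-eigenvalues over the lowest n nonzero modes (ascending)."""
    lam = spec.nonzero_eigenvalues
    if n == "full":
        return float(np.sum(np.log(lam)))
    n = int(n)
    if n < 0 or n > lam.size:
        raise ValueError(f"n={n} exceeds available nonzero modes ({lam.size})")
    return float(np.sum(np.log(lam[:n])))


def cooperativity_ratio(ddg: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """K2/K1 = exp(ddG / (R*T)), ddG in cal mol^-1."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return float(np.exp(ddg / (R_CAL * temperature)))


def allosteric_free_energy(
    apo: ModeSpectrum,
    holo1: ModeSpectrum,
    holo2: ModeSpectrum,
    n="full",
    temperature: float = DEFAULT_TEMPERATURE,
) -> AllosteryResult:
    """Allosteric free energy (cal mol^-1) from the three ligation spectra.

    The three spectra must come from the same structure: holo1 has one node
    more than apo and one fewer than holo2.
    """
    if not (holo2.n_nonzero - holo1.n_nonzero == 3 == holo1.n_nonzero - apo.n_nonzero):
        raise ValueError(
            "spectra do not differ by one ligand node each "
            f"(nonzero counts {apo.n_nonzero}, {holo1.n_nonzero}, {holo2.n_nonzero})"
        )
    s0 = log_mode_sum(apo, n)
    s1 = log_mode_sum(holo1, n)
    s2 = log_mode_sum(holo2, n)
    ddg = 0.5 * R_CAL * temperature * (s2 + s0 - 2.0 * s1)
    return AllosteryResult(
        s0, s1, s2, n, ddg, cooperativity_ratio(ddg, temperature), temperature
    )


def convergence_profile(
    apo: ModeSpectrum,
    holo1: ModeSpectrum,
    holo2: ModeSpectrum,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-4,
    lag: int = 10,
    sustain: int = 50,
) -> tuple:
    """K2/K1 as a function of the number of summed modes.

    Returns (DataFrame with columns n, ddG, K2_over_K1; converged_n or None).
    Convergence: |K(n) - K(n - lag)| < tol sustained for ``sustain``
    consecutive n; if never reached the full-sum value stands, flagged by
    converged_n = None.
    """
    nmax = min(apo.n_nonzero, holo1.n_nonzero, holo2.n_nonzero)
    rows = []
    for n in range(1, nmax + 1):
        res = allosteric_free_energy(apo, holo1, holo2, n, temperature)
        rows.append((n, res.ddG, res.K2_over_K1))
    df = pd.DataFrame(rows, columns=["n", "ddG", "K2_over_K1"])
    k = df["K2_over_K1"].to_numpy()
    converged_n = None
    run = 0
    for n in range(lag, nmax):
        if abs(k[n] - k[n - lag]) < tol:
            run += 1
            if run >= sustain:
                converged_n = n + 1 - sustain + 1
                break
        else:
            run = 0
    return df, converged_n


# ---------------------------------------------------------------------------
# structure-level pipeline


def ligation_spectra(
    model: StructureModel,
    config: BuildConfig | None = None,
    edits: tuple = (),
    vectors: bool = False,
) -> dict:
    """Build and decompose apo, holo1 (every site) and holo2 networks.

    Returns {"apo": spectrum, "holo1": {site: spectrum, ...}, "holo2": spectrum}.
    Spring edits are applied identically to all states.
    """
    config = config or BuildConfig()
    sites = model.ligand_instances
    if len(sites) < 2:
        raise ValueError(
            f"{model.source_id}: doubly bound state needs >= 2 ligand "
            f"instances, found {len(sites)}"
        )

    def spec_for(state):
        net = build_network(model, config, state)
        for e in edits:
            net = apply_spring_edit(net, e)
        return eigenmodes(hessian(net)) if vectors else _eigvals_spectrum(net)

    return {
        "apo": spec_for(LigationState.apo()),
        "holo1": {s: spec_for(LigationState.holo1(s)) for s in sites},
        "holo2": spec_for(LigationState.holo2()),
    }


def _eigvals_spectrum(net: ElasticNetwork) -> ModeSpectrum:
    """Eigenvalues-only decomposition (no vectors; faster for scans)."""
    import scipy.linalg

    from .nma import expected_rigid_modes

    H = hessian(net)
    vals = scipy.linalg.eigvalsh(H.matrix)
    scale = max(abs(vals[-1]), 1.0)
    expected = expected_rigid_modes(H.coords)
    n_small = int(np.sum(np.abs(vals) < 1e-9 * scale))
    if n_small != expected:
        raise ValueError(
            f"expected {expected} rigid-body modes, found {n_small}"
        )
    return ModeSpectrum(vals, None, expected, H.labels)


def structure_cooperativity(
    model: StructureModel,
    config: BuildConfig | None = None,
    edits: tuple = (),
    n="full",
    temperature: float | None = None,
) -> AllosteryResult:
    """Allostery for one structure, averaging the singly bound state over sites.

    Real crystal dimers are only approximately C2-symmetric, so the two
    choices of which cAMP to retain in holo1 differ slightly; their
    log-eigenvalue sums are averaged before forming ddG.
    """
    config = config or BuildConfig()
    T = temperature if temperature is not None else config.temperature
    specs = ligation_spectra(model, config, edits)
    s0 = log_mode_sum(specs["apo"], n)
    s1 = float(np.mean([log_mode_sum(sp, n) for sp in specs["holo1"].values()]))
    s2 = log_mode_sum(specs["holo2"], n)
    ddg = 0.5 * R_CAL * T * (s2 + s0 - 2.0 * s1)
    return AllosteryResult(s0, s1, s2, n, ddg, cooperativity_ratio(ddg, T), T)


def ensemble_cooperativity(
    models,
    config: BuildConfig | None = None,
    edits: tuple = (),
    n="full",
    temperature: float | None = None,
) -> EnsembleSummary:
    """Unweighted per-structure K2/K1 over an ensemble of crystal structures."""
    vals, ids = [], []
    for m in models:
        res = structure_cooperativity(m, config, edits, n, temperature)
        vals.append(res.K2_over_K1)
        ids.append(m.source_id)
    return EnsembleSummary(np.array(vals), tuple(ids))


def scan_mutagenesis(
    models,
    residues,
    scales=(0.25, 0.5, 1.0, 2.0, 4.0),
    config: BuildConfig | None = None,
    temperature: float | None = None,
    extra_edits: tuple = (),
) -> pd.DataFrame:
    """Spring-constant mutagenesis map over (residue, scale) cells.

    Each cell rescales every spring of that residue (both chains) by the
    scale factor in all three ligation states of every structure and
    reports the ensemble mean K2/K1 with its standard error. ``extra_edits``
    are applied on top of every cell (e.g. a second-site rearrangement such
    as the V140A-induced C179 contact, modelled as k_C179/k = 4).
    """
    rows = []
    for resnum, scale in itertools.product(residues, scales):
        edits = tuple(extra_edits)
        if scale != 1.0:
            edits = (SpringEdit(scale=scale, residue=resnum),) + edits
        summ = ensemble_cooperativity(models, config, edits, "full", temperature)
        rows.append(
            (resnum, scale, summ.mean, summ.sem, summ.n, tuple(summ.values))
        )
    return pd.DataFrame(
        rows,
        columns=["residue", "scale", "K2_over_K1_mean", "sem", "n", "values"],
    )


def pair_interaction_scan(
    model: StructureModel,
    residue: int,
    scale: float,
    config: BuildConfig | None = None,
    chain: str | None = None,
    temperature: float | None = None,
) -> pd.DataFrame:
    """Per-contact contribution of one residue's springs to cooperativity.

    Each spring joining (chain, residue) to a partner residue is rescaled on
    its own and the resulting change in K2/K1 relative to wild type is
    reported, split into same-monomer and cross-monomer partners.
    """
    config = config or BuildConfig()
    wt = structure_cooperativity(model, config, (), "full", temperature)
    net = build_network(model, config, LigationState.holo2())
    if chain is None:
        chain = net.labels[0].chain
    idx = net.index_of(chain, residue)
    rows = []
    for (i, j) in net.incident(idx):
        other = net.labels[j if i == idx else i]
        if other.kind != "calpha":
            continue
        edit = SpringEdit(
            scale=scale, pair=((chain, residue), (other.chain, other.resnum))
        )
        res = structure_cooperativity(model, config, (edit,), "full", temperature)
        rows.append(
            (other.chain, other.resnum, other.chain == chain,
             res.K2_over_K1 - wt.K2_over_K1)
        )
    return pd.DataFrame(
        rows, columns=["partner_chain", "partner_resnum", "same_monomer",
                       "delta_K2_over_K1"]
    ).sort_values(["same_monomer", "partner_chain", "partner_resnum"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# flexibility reports


def flexibility_change(wild: ModeSpectrum, mutant: ModeSpectrum) -> FlexibilityDelta:
    """Per-node percentage change in calculated B-factor, mutant vs wild type."""
    if wild.labels != mutant.labels:
        raise ValueError("wild-type and mutant spectra have different node maps")
    bw = bfactor_profile(wild).bfactor
    bm = bfactor_profile(mutant).bfactor
    return FlexibilityDelta(100.0 * (bm - bw) / bw, wild.labels)


def site_fluctuation_change(
    wild: ModeSpectrum, mutant: ModeSpectrum, site_residues
) -> float:
    """Percentage change of RMS fluctuation aggregated over a residue set.

    Per-residue mean-square fluctuations are averaged over the named
    residues (all chains), square-rooted to an RMS amplitude, and compared
    mutant vs wild type. For cAMP-site residues this tracks how a mutation
    re-tunes motion at the binding site itself.
    """
    if wild.labels != mutant.labels:
        raise ValueError("wild-type and mutant spectra have different node maps")
    site = set(site_residues)
    mask = np.array(
        [lab.kind == "calpha" and lab.resnum in site for lab in wild.labels]
    )
    if not mask.any():
        raise ValueError("no site residues present in the node map")
    rw = np.sqrt(bfactor_profile(wild).msf[mask].mean())
    rm = np.sqrt(bfactor_profile(mutant).msf[mask].mean())
    return float(100.0 * (rm - rw) / rw)
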
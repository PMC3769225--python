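"""Synthetic fixtures with the statistical structure of each pipeline stage.

Three generators, all pure functions of (config, seed):

* a two-domain homodimer bead network with ligand sites and a tunable
  interface, emulating the topology of a CRP/FNR-type dimer at toy scale;
* sequential-site titrations with Gaussian heat noise;
* aligned sequence families whose per-position mutation counts follow the
  linked beta-binomial model, built on a mutation path so that the
  nearest-neighbour parsimony count recovers exactly twice each generated
  event (each adjacent pair on the path is counted once from either side).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conservation import MutationProfile, SequenceFamily, mutation_rate_link
from .itc import SequentialBindingModel, TitrationSeries, injection_heats
from .structure import StructureModel

__all__ = [
    "ToyDimerConfig",
    "SynthItcConfig",
    "SynthFamilyConfig",
    "toy_dimer",
    "toy_monomer",
    "synth_titration",
    "synth_family",
    "write_model_pdb",
]

AMINO = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# toy dimer


@dataclass(frozen=True)
class ToyDimerConfig:
    """Two compact domains per monomer, C2-related monomers, one ligand each.

    beads_per_domain : beads in each of the four domain clusters
    domain_radius    : cluster radius, Angstrom
    separation       : half-distance between the monomer centers, Angstrom
    symmetric        : exact C2 symmetry (monomer B is the rotated copy of A)
    seed             : base RNG seed (resampled +1 on a disconnected draw)
    """

    beads_per_domain: int = 12
    domain_radius: float = 3.5
    separation: float = 4.5
    symmetric: bool = True
    seed: int = 0


def _monomer_coords(cfg: ToyDimerConfig, rng) -> np.ndarray:
    """One monomer: ligand-binding domain near the interface, DNA domain above."""
    centers = np.array(
        [[-cfg.separation, 0.0, 0.0],          # ligand-binding domain
         [-cfg.separation - 2.0, 0.0, 9.0]]    # DNA-binding domain
    )
    pts = []
    for c in centers:
        # rejection-sample points in a ball, min spacing to avoid duplicates
        got = []
        while len(got) < cfg.beads_per_domain:
            p = rng.uniform(-1, 1, 3)
            if np.dot(p, p) <= 1.0:
                q = c + cfg.domain_radius * p
                if all(np.linalg.norm(q - g) > 1.5 for g in got):
                    got.append(q)
        pts.extend(got)
    return np.array(pts)


def toy_dimer(cfg: ToyDimerConfig) -> StructureModel:
    """Synthetic homodimer StructureModel with one ligand instance per monomer.

    Monomer B is the C2 rotation (about z) of monomer A when symmetric;
    otherwise an independent draw. Each ligand is three pseudo-atoms of
    unequal mass near the first bead of the ligand-binding domain, so the
    mass-weighted placement is exercised. Draws whose doubly bound network
    would be disconnected at the default 8 A cutoff are resampled with the
    seed incremented (warned).
    """
    for attempt in range(20):
        seed = cfg.seed + attempt
        rng = np.random.default_rng(seed)
        a = _monomer_coords(cfg, rng)
        if cfg.symmetric:
            b = a * np.array([-1.0, -1.0, 1.0])  # C2 about the z axis
        else:
            b = _monomer_coords(cfg, rng) * np.array([-1.0, -1.0, 1.0])
        nodes = []
        for chain, coords in (("A", a), ("B", b)):
            for i, xyz in enumerate(coords, start=1):
                nodes.append((chain, i, "GLY", xyz))
        ligs = []
        for chain, coords in (("A", a), ("B", b)):
            site = coords[0]
            toward = np.array([0.0, 0.0, 0.0]) - site
            u = toward / np.linalg.norm(toward)
            for k, (el, mass) in enumerate((("C", 12.011), ("N", 14.007),
                                            ("O", 15.999))):
                ligs.append(
                    (f"{chain}:LIG:1", el, mass, site + (1.0 + 0.5 * k) * u)
                )
        model = StructureModel(tuple(nodes), tuple(ligs), f"toy-dimer-{seed}")
        if _connected_at_cutoff(model):
            if attempt:
                warnings.warn(
                    f"toy dimer draw resampled {attempt}x (disconnected); "
                    f"final seed {seed}"
                )
            return model
    raise RuntimeError("could not draw a connected toy dimer in 20 attempts")


def toy_monomer(cfg: ToyDimerConfig, chain: str = "A") -> StructureModel:
    """One monomer of the toy dimer (same draw), with its single ligand."""
    full = toy_dimer(cfg)
    nodes = tuple(n for n in full.nodes if n[0] == chain)
    ligs = tuple(l for l in full.ligand_atoms if l[0].startswith(chain))
    return StructureModel(nodes, ligs, full.source_id + f"-{chain}")


def _connected_at_cutoff(model: StructureModel, cutoff: float = 8.0) -> bool:
    from .structure import BuildConfig, LigationState, build_network

    try:
        build_network(model, BuildConfig(cutoff=cutoff), LigationState.holo2())
        return True
    except ValueError:
        return False


def write_model_pdb(model: StructureModel, path) -> None:
    """Write a StructureModel as a minimal PDB file (CA + ligand HETATM)."""
    with open(path, "w") as fh:
        serial = 1
        for chain, resnum, resname, xyz in model.nodes:
            fh.write(
                f"ATOM  {serial:5d}  CA  {resname:<3s} {chain}{resnum:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00\n"
            )
            serial += 1
        for inst, el, _mass, xyz in model.ligand_atoms:
            chain, resname, resnum = inst.split(":")
            fh.write(
                f"HETATM{serial:5d} {el:>2s}   {resname:<3s} {chain}{int(resnum):4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
                f"{el:>2s}\n"
            )
            serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# synthetic titrations


@dataclass(frozen=True)
class SynthItcConfig:
    """Ground-truth model plus instrument geometry and heat noise.

    Defaults mirror a typical small-cell titration: 40 x 1 uL injections of
    5 mM ligand into 202 uL of 200 uM protein (dimer basis).
    """

    model: SequentialBindingModel = field(
        default_factory=lambda: SequentialBindingModel(
            K=(2.5e-5, 1.68e-4, 1.0e-3),
            dH=(-8000.0, -5000.0, -2000.0),
        )
    )
    n_injections: int = 40
    injection_volume_uL: float = 1.0
    cell_volume_uL: float = 202.0
    cell_protein_M: float = 2.0e-4
    syringe_ligand_M: float = 5.0e-3
    noise_sd_ucal: float = 0.4
    temperature: float = 298.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd_ucal < 0:
            raise ValueError("noise sd must be >= 0")


def synth_titration(cfg: SynthItcConfig) -> TitrationSeries:
    """Forward-model heats plus i.i.d. Gaussian noise."""
    vols = np.full(cfg.n_injections, cfg.injection_volume_uL)
    clean = TitrationSeries(
        cell_volume_uL=cfg.cell_volume_uL,
        cell_protein_M=cfg.cell_protein_M,
        syringe_ligand_M=cfg.syringe_ligand_M,
        injection_volumes_uL=vols,
        heats_ucal=np.zeros(cfg.n_injections),
        temperature=cfg.temperature,
    )
    q = injection_heats(clean, cfg.model)
    rng = np.random.default_rng(cfg.seed)
    noisy = q + rng.normal(0.0, cfg.noise_sd_ucal, size=q.shape)
    return TitrationSeries(
        cell_volume_uL=cfg.cell_volume_uL,
        cell_protein_M=cfg.cell_protein_M,
        syringe_ligand_M=cfg.syringe_ligand_M,
        injection_volumes_uL=vols,
        heats_ucal=noisy,
        temperature=cfg.temperature,
    )


# ---------------------------------------------------------------------------
# synthetic sequence families


@dataclass(frozen=True)
class SynthFamilyConfig:
    """Linked beta-binomial ground truth for a sequence family.

    n_events is the total number of mutation events N used as the
    beta-binomial trial count; scores x must have length L. Default theta
    puts the mean per-position rate near 1/L with a strongly negative
    allostery coefficient; phi = 0.005 roughly triples the binomial count
    variance at N = 500 (overdispersion factor 1 + (N-1)*phi/(1+phi)).
    """

    length: int = 210
    n_events: int = 500
    beta0: float = -5.3
    beta1: float = -2.4
    beta2: float = 0.0
    phi: float = 0.005
    scores: np.ndarray | None = None
    seed: int = 0


def default_scores(length: int, seed: int = 12345) -> np.ndarray:
    """Allostery-score surrogate: mostly near zero, a tail of strong sites."""
    rng = np.random.default_rng(seed)
    x = rng.exponential(0.08, size=length)
    x[rng.random(length) < 0.4] = 0.0
    return x


def synth_counts(cfg: SynthFamilyConfig):
    """Per-position mutation counts from the linked beta-binomial model.

    Pure count-level draws (no sequence realization, no truncation):
    p_i ~ Beta(mu_i/phi, (1-mu_i)/phi), n_i ~ Binomial(N, p_i). Returns
    (MutationProfile, scores).
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.asarray(cfg.scores, float) if cfg.scores is not None else \
        default_scores(cfg.length)
    if len(x) != cfg.length:
        raise ValueError("scores length must match sequence length")
    mu = mutation_rate_link(x, cfg.beta0, cfg.beta1, cfg.beta2)
    if cfg.phi > 0:
        p = rng.beta(mu / cfg.phi, (1.0 - mu) / cfg.phi)
    else:
        p = mu
    return MutationProfile(rng.binomial(cfg.n_events, p)), x


def synth_family(cfg: SynthFamilyConfig):
    """Draw per-position counts and realize them as a mutation path.

    Returns (SequenceFamily, MutationProfile of the drawn event counts,
    scores). The family is an ancestor plus one sequence per event, each
    differing from its predecessor at exactly one position; events at the
    same position are interleaved with other positions so that
    nearest-neighbour parsimony recovers exactly two counts per event
    (each adjacent pair is found once from each side).

    A position can host at most 19 events (distinct substitute letters), so
    the realized counts follow a tail-truncated beta-binomial: any
    per-position draw above the cap is redrawn. Count-level statistical
    studies that need the untruncated model should use :func:`synth_counts`.
    """
    rng = np.random.default_rng(cfg.seed)
    x = np.asarray(cfg.scores, float) if cfg.scores is not None else \
        default_scores(cfg.length)
    if len(x) != cfg.length:
        raise ValueError("scores length must match sequence length")
    mu = mutation_rate_link(x, cfg.beta0, cfg.beta1, cfg.beta2)
    cap = len(AMINO) - 1
    counts = np.empty(cfg.length, int)
    for i in range(cfg.length):
        for _attempt in range(100):
            p = rng.beta(mu[i] / cfg.phi, (1.0 - mu[i]) / cfg.phi) \
                if cfg.phi > 0 else mu[i]
            n_i = rng.binomial(cfg.n_events, p)
            if n_i <= cap:
                counts[i] = n_i
                break
        else:
            raise ValueError(
                f"position {i} cannot be realized with {len(AMINO)} letters"
            )
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no mutation events drawn; increase n_events")
    if counts.max() > total - counts.max() + 1:
        raise ValueError("counts too concentrated to interleave positions")

    # greedy scheduling so same-position events are never adjacent: always
    # emit the position with the most remaining events, avoiding the last one
    remaining = counts.copy()
    order: list = []
    while remaining.sum() > 0:
        ranked = np.argsort(-remaining, kind="stable")
        pick = None
        for pos in ranked:
            if remaining[pos] > 0 and (not order or order[-1] != pos):
                pick = int(pos)
                break
        if pick is None:
            raise ValueError("counts too concentrated to interleave positions")
        order.append(pick)
        remaining[pick] -= 1

    anc = rng.integers(0, len(AMINO), size=cfg.length)
    cur = anc.copy()
    seqs = ["".join(AMINO[i] for i in anc)]
    used = {i: {int(anc[i])} for i in range(cfg.length)}
    for pos in order:
        choices = [c for c in range(len(AMINO)) if c not in used[pos]]
        cur = cur.copy()
        cur[pos] = choices[0]
        used[pos].add(choices[0])
        seqs.append("".join(AMINO[i] for i in cur))
    ids = tuple(f"seq{i:04d}" for i in range(len(seqs)))
    return SequenceFamily(tuple(seqs), ids), MutationProfile(counts), x
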
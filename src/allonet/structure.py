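"""Structure parsing and elastic-network construction.

A protein (here a homodimeric transcription factor such as CAP or GlxR) is
reduced to one bead per residue at the C-alpha position. Each bound ligand
(cAMP) is represented by a single pseudo-node at the mass-weighted mean of
its atoms. Beads closer than a distance cutoff are joined by identical
Hookean springs; mutations are emulated by rescaling every spring incident
to a residue.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .constants import DEFAULT_TEMPERATURE, R_CAL

__all__ = [
    "StructureModel",
    "BuildConfig",
    "ElasticNetwork",
    "LigationState",
    "SpringEdit",
    "NodeLabel",
    "read_structure",
    "place_ligand_nodes",
    "build_network",
    "apply_spring_edit",
]


@dataclass(frozen=True)
class BuildConfig:
    """Elastic-network construction parameters.

    spring_constant : uniform spring stiffness, kcal mol^-1 A^-2
    cutoff          : inclusive contact distance Rc, Angstrom
    temperature     : K
    gas_constant    : cal mol^-1 K^-1
    """

    spring_constant: float = 1.0
    cutoff: float = 8.0
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = R_CAL

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    @staticmethod
    def from_file(path) -> tuple:
        """Read a YAML config file.

        Recognized keys: spring_constant, cutoff, temperature, ligand_names.
        Returns (BuildConfig, ligand_names).
        """
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        ligands = tuple(data.pop("ligand_names", ["CMP"]))
        known = {"spring_constant", "cutoff", "temperature"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return BuildConfig(**data), ligands


@dataclass(frozen=True)
class StructureModel:
    """One bead per residue plus grouped ligand atoms.

    nodes        : sequence of (chain_id, residue_number, residue_name, xyz)
    ligand_atoms : sequence of (instance_id, element, mass_da, xyz)
    source_id    : provenance label (PDB id or file stem)
    """

    nodes: tuple
    ligand_atoms: tuple
    source_id: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for chain, resnum, _name, xyz in self.nodes:
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"non-finite coordinate at {chain}{resnum}")
            key = (chain, resnum)
            if key in seen:
                raise ValueError(f"duplicate residue {chain}{resnum}")
            seen.add(key)

    @property
    def ligand_instances(self) -> tuple:
        out = []
        for inst, *_ in self.ligand_atoms:
            if inst not in out:
                out.append(inst)
        return tuple(out)


class Ligation(enum.Enum):
    APO = "apo"
    HOLO1 = "holo1"
    HOLO2 = "holo2"


@dataclass(frozen=True)
class LigationState:
    """Which ligand pseudo-nodes are retained in the network.

    holo1 names exactly one ligand instance; holo2 retains all instances;
    apo retains none.
    """

    kind: Ligation
    site: object | None = None

    def __post_init__(self) -> None:
        if self.kind is Ligation.HOLO1 and self.site is None:
            raise ValueError("holo1 requires the retained ligand instance id")
        if self.kind is not Ligation.HOLO1 and self.site is not None:
            raise ValueError("site is only meaningful for holo1")

    @staticmethod
    def apo() -> "LigationState":
        return LigationState(Ligation.APO)

    @staticmethod
    def holo1(site) -> "LigationState":
        return LigationState(Ligation.HOLO1, site)

    @staticmethod
    def holo2() -> "LigationState":
        return LigationState(Ligation.HOLO2)


@dataclass(frozen=True)
class NodeLabel:
    chain: str
    resnum: int
    kind: str = "calpha"  # "calpha" | "ligand"
    instance: object | None = None


@dataclass(frozen=True)
class SpringEdit:
    """Multiply springs incident to a residue (or one explicit pair) by scale.

    residue : residue number; applied in the listed chains, or all chains
              when ``chains`` is None.
    pair    : explicit ((chain, resnum), (chain, resnum)) spring; mutually
              exclusive with ``residue``.
    """

    scale: float
    residue: int | None = None
    chains: tuple | None = None
    pair: tuple | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("spring scale factor must be > 0")
        if (self.residue is None) == (self.pair is None):
            raise ValueError("specify exactly one of residue or pair")


@dataclass(frozen=True)
class ElasticNetwork:
    """Bead-spring network for one ligation state.

    coords  : (n, 3) float array, Angstrom
    labels  : tuple of NodeLabel, parallel to coords
    springs : mapping {(i, j): stiffness} with i < j
    config  : BuildConfig used at construction
    """

    coords: np.ndarray
    labels: tuple
    springs: Mapping
    config: BuildConfig
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        for (i, j), k in self.springs.items():
            if i == j:
                raise ValueError("self-spring")
            if i > j:
                raise ValueError("spring pairs must be ordered i < j")
            if k <= 0:
                raise ValueError("spring stiffness must be > 0")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def index_of(self, chain: str, resnum: int) -> int:
        for i, lab in enumerate(self.labels):
            if lab.kind == "calpha" and lab.chain == chain and lab.resnum == resnum:
                return i
        raise KeyError(f"no C-alpha node {chain}{resnum}")

    def incident(self, node: int) -> list:
        return [p for p in self.springs if node in p]

    def to_edge_csv(self, path) -> None:
        """Audit dump: node_i,node_j,stiffness edge list."""
        with open(path, "w") as fh:
            fh.write("node_i,node_j,stiffness\n")
            for (i, j), k in sorted(self.springs.items()):
                fh.write(f"{i},{j},{k:.10g}\n")


# ---------------------------------------------------------------------------
# structure input


def read_structure(
    path,
    chains: Sequence[str] | None = None,
    ligand_names: Iterable[str] = ("CMP",),
) -> StructureModel:
    """Read a PDB (or mmCIF) file into a StructureModel.

    One node per residue bearing a C-alpha atom (altloc resolved to highest
    occupancy); HETATM residues whose name is in ``ligand_names`` are
    collected atom-by-atom, grouped per residue instance. Residues lacking a
    C-alpha raise a warning and are skipped. Requesting ligands when none
    match is an error.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    ligand_names = set(ligand_names)
    model = st[0]
    wanted = set(chains) if chains is not None else None
    if wanted is not None:
        have = {ch.name for ch in model}
        missing = wanted - have
        if missing:
            raise ValueError(f"chains {sorted(missing)} not in {path}")

    nodes = []
    ligand_atoms = []
    for ch in model:
        if wanted is not None and ch.name not in wanted:
            continue
        for res in ch:
            if res.name in ligand_names:
                inst = f"{ch.name}:{res.name}:{res.seqid.num}"
                for atom in res:
                    if atom.is_hydrogen():
                        continue
                    ligand_atoms.append(
                        (inst, atom.element.name, atom.element.weight,
                         np.array([atom.pos.x, atom.pos.y, atom.pos.z]))
                    )
                continue
            if not gemmi.find_tabulated_residue(res.name) or not (
                gemmi.find_tabulated_residue(res.name).is_amino_acid()
            ):
                continue
            ca = _best_altloc(res, "CA")
            if ca is None:
                warnings.warn(
                    f"residue {ch.name}{res.seqid.num} ({res.name}) has no "
                    "C-alpha; skipped"
                )
                continue
            nodes.append(
                (ch.name, res.seqid.num, res.name,
                 np.array([ca.pos.x, ca.pos.y, ca.pos.z]))
            )
    if ligand_names and not ligand_atoms:
        raise ValueError(
            f"no ligand instances matching {sorted(ligand_names)} in {path}"
        )
    return StructureModel(tuple(nodes), tuple(ligand_atoms), Path(str(path)).stem)


def _best_altloc(res, name):
    best, occ = None, -1.0
    for atom in res:
        if atom.name == name and atom.occ > occ:
            best, occ = atom, atom.occ
    return best


# ---------------------------------------------------------------------------
# network construction


def place_ligand_nodes(model: StructureModel) -> list:
    """One pseudo-node per ligand instance at the mass-weighted mean coordinate."""
    if not model.ligand_atoms:
        raise ValueError("structure has no ligand atoms")
    out = []
    for inst in model.ligand_instances:
        atoms = [a for a in model.ligand_atoms if a[0] == inst]
        masses = np.array([a[2] for a in atoms], float)
        coords = np.array([a[3] for a in atoms], float)
        total = masses.sum()
        if total <= 0:
            raise ValueError(f"ligand instance {inst} has zero total mass")
        out.append((inst, (masses[:, None] * coords).sum(axis=0) / total))
    return out


def build_network(
    model: StructureModel,
    config: BuildConfig,
    state: LigationState,
) -> ElasticNetwork:
    """Construct the uniform-cutoff elastic network for one ligation state.

    Nodes are all C-alpha beads plus the state's ligand pseudo-nodes; springs
    of stiffness ``config.spring_constant`` join every node pair at distance
    <= cutoff (inclusive). Apo/holo1 differ from holo2 only by omitted
    ligand nodes. The network must be a single connected component.
    """
    coords = [n[3] for n in model.nodes]
    labels = [NodeLabel(n[0], n[1]) for n in model.nodes]

    if state.kind is not Ligation.APO:
        placed = place_ligand_nodes(model)
        if state.kind is Ligation.HOLO1:
            keep = [p for p in placed if p[0] == state.site]
            if len(keep) != 1:
                raise ValueError(
                    f"holo1 site {state.site!r} does not name exactly one of "
                    f"{[p[0] for p in placed]}"
                )
            placed = keep
        for inst, xyz in placed:
            coords.append(xyz)
            labels.append(NodeLabel("*", -1, "ligand", inst))

    coords = np.asarray(coords, float)
    n = len(coords)
    d = squareform(pdist(coords))
    if np.any(d[np.triu_indices(n, 1)] < 1e-6):
        ii, jj = np.where((d < 1e-6) & ~np.eye(n, dtype=bool))
        raise ValueError(f"duplicate node positions, e.g. nodes {ii[0]} and {jj[0]}")
    mask = np.triu(d <= config.cutoff, 1)
    pairs = np.argwhere(mask)
    springs = {(int(i), int(j)): config.spring_constant for i, j in pairs}

    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    ncomp, comp = connected_components(adj, directed=False)
    if ncomp != 1:
        sizes = np.bincount(comp)
        raise ValueError(
            f"network is disconnected: {ncomp} components with sizes "
            f"{sizes.tolist()} (cutoff {config.cutoff} A)"
        )
    return ElasticNetwork(coords, tuple(labels), springs, config, model.source_id)


def apply_spring_edit(net: ElasticNetwork, edit: SpringEdit) -> ElasticNetwork:
    """Rescale springs incident to a residue (all chains by default) or one pair.

    Topology is unchanged; editing by a then b equals editing by a*b.
    """
    springs = dict(net.springs)
    if edit.pair is not None:
        (c1, r1), (c2, r2) = edit.pair
        i, j = net.index_of(c1, r1), net.index_of(c2, r2)
        key = (min(i, j), max(i, j))
        if key not in springs:
            raise ValueError(f"no spring between {c1}{r1} and {c2}{r2}")
        springs[key] = springs[key] * edit.scale
        return replace(net, springs=springs)

    targets = {
        i for i, lab in enumerate(net.labels)
        if lab.kind == "calpha" and lab.resnum == edit.residue
        and (edit.chains is None or lab.chain in edit.chains)
    }
    touched = [p for p in springs if targets & set(p)]
    if not touched:
        raise ValueError(f"residue {edit.residue} resolves to no springs")
    for p in touched:
        springs[p] = springs[p] * edit.scale
    return replace(net, springs=springs)
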
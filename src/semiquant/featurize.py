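"""SMILES featurization for graph and descriptor-based regression.

Two representations are produced:

* :class:`MolGraph` — the heavy-atom molecular graph (bond types deliberately
  discarded; only connectivity is kept) with a 16-column per-node feature
  matrix: 12 local atomic descriptors followed by 4 global shape descriptors
  (volume, width, length, height of a 3D conformer) copied onto every node.
* :class:`DescriptorTable` — a molecule × descriptor real matrix for the
  non-graph regressors, either imported from a PaDEL-export CSV or derived
  from simple heavy-atom counts.

The 12 local columns, in fixed order:

==  =================================  =========================
 #  feature                            encoding
==  =================================  =========================
 0  atomic number                      integer as float
 1  number of (implicit) hydrogens     count
 2  number of valence electrons        outer-shell electron count
 3  number of radical electrons        count
 4  formal charge                      signed integer
 5  hybridization                      code, see HYBRIDIZATION_CODES
 6  heavy-atom degree                  count
 7  member of any ring                 0/1
 8  aromatic                           0/1
 9  van der Waals radius               scaled by VDW_RADIUS_SCALE
10  atomic mass                        scaled by ATOMIC_MASS_SCALE
11  covalent radius                    scaled by COVALENT_RADIUS_SCALE
==  =================================  =========================

The scale constants are the maxima of the tabulated values over the elements
H–Rn, so every scaled column lies in (0, 1].
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit import RDLogger

from .errors import FeaturizationError, SchemaError, SmilesParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

N_NODE_FEATURES = 16
N_LOCAL_FEATURES = 12

_PT = Chem.GetPeriodicTable()

# maxima over H(1)..Rn(86); written out in docs/methods.md
VDW_RADIUS_SCALE = max(_PT.GetRvdw(z) for z in range(1, 87))
ATOMIC_MASS_SCALE = max(_PT.GetAtomicWeight(z) for z in range(1, 87))
COVALENT_RADIUS_SCALE = max(_PT.GetRcovalent(z) for z in range(1, 87))

HYBRIDIZATION_CODES = {
    Chem.HybridizationType.UNSPECIFIED: 0,
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
    Chem.HybridizationType.SP3D: 4,
    Chem.HybridizationType.SP3D2: 5,
}
_HYBRIDIZATION_OTHER = 6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GlobalShape:
    """3D extent descriptors of one conformer.

    ``length >= width >= height`` are the coordinate ranges of the heavy-atom
    centers along the principal axes of the conformer, in Å; ``volume`` is the
    overlap-corrected union volume of the heavy-atom van der Waals spheres,
    in Å³. All four are invariant under rigid rotation and translation.
    """

    volume: float
    length: float
    width: float
    height: float

    def __post_init__(self):
        if not (self.length >= self.width >= self.height >= 0.0):
            raise FeaturizationError(
                f"shape extents must satisfy length >= width >= height >= 0, "
                f"got ({self.length}, {self.width}, {self.height})"
            )
        if self.volume <= 0:
            raise FeaturizationError("molecular volume must be positive")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.volume, self.width, self.length, self.height)


@dataclass
class MolGraph:
    """Heavy-atom molecular graph with an optional node-feature matrix.

    ``edges`` holds each undirected bond once as an ``(i, j)`` pair with
    ``i < j``; bond order and aromaticity are not encoded. ``node_order``
    maps SMILES chain positions to node indices (identity for graphs built
    directly from a SMILES parse) and is what the positional readout modes
    of the GNN consume.
    """

    molecule_id: str
    n_nodes: int
    edges: list[tuple[int, int]]
    node_features: np.ndarray | None = None
    node_order: list[int] = field(default_factory=list)
    smiles: str = ""
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.n_nodes < 1:
            raise FeaturizationError("a molecular graph needs at least one node")
        seen = set()
        for i, j in self.edges:
            if i == j:
                raise FeaturizationError("self-loops are not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise FeaturizationError("edge index out of range")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise FeaturizationError("duplicate edge")
            seen.add(key)
        if not self.node_order:
            self.node_order = list(range(self.n_nodes))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    # -- JSON caching -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "molecule_id": self.molecule_id,
            "n_nodes": self.n_nodes,
            "edges": [list(e) for e in self.edges],
            "node_order": list(self.node_order),
            "smiles": self.smiles,
            "node_features": None
            if self.node_features is None
            else [float(x) for x in np.asarray(self.node_features).ravel()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MolGraph":
        feats = d.get("node_features")
        if feats is not None:
            feats = np.asarray(feats, dtype=float).reshape(d["n_nodes"], -1)
        return cls(
            molecule_id=d["molecule_id"],
            n_nodes=int(d["n_nodes"]),
            edges=[tuple(e) for e in d["edges"]],
            node_features=feats,
            node_order=list(d.get("node_order") or []),
            smiles=d.get("smiles", ""),
        )


@dataclass
class DescriptorTable:
    """Molecule × named-descriptor matrix for the non-graph models."""

    molecule_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    imputed_cells: list[tuple[str, str]] = field(default_factory=list)
    constant_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.molecule_ids), len(self.descriptor_names)):
            raise SchemaError(
                f"descriptor matrix shape {self.values.shape} does not match "
                f"{len(self.molecule_ids)} molecules x {len(self.descriptor_names)} descriptors"
            )
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            raise SchemaError("duplicate molecule ids in descriptor table")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    def subset_rows(self, indices) -> "DescriptorTable":
        idx = list(indices)
        return DescriptorTable(
            [self.molecule_ids[i] for i in idx],
            list(self.descriptor_names),
            self.values[idx],
        )

    def subset_columns(self, names: list[str]) -> "DescriptorTable":
        missing = [n for n in names if n not in self.descriptor_names]
        if missing:
            raise SchemaError(f"descriptors not in table: {missing}")
        cols = [self.descriptor_names.index(n) for n in names]
        return DescriptorTable(list(self.molecule_ids), list(names), self.values[:, cols])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.descriptor_names)
        df.insert(0, "Name", self.molecule_ids)
        return df

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update("\x1f".join(self.molecule_ids).encode())
        h.update("\x1f".join(self.descriptor_names).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles, "empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        # salts / mixtures: keep the largest fragment by heavy-atom count
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        logger.info("disconnected SMILES %r: kept largest fragment of %d", smiles, len(frags))
    mol = Chem.RemoveHs(mol)  # explicit-H inputs normalized to the heavy-atom graph
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError(smiles, "no heavy atoms")
    return mol


def smiles_to_graph(smiles: str, molecule_id: str = "") -> MolGraph:
    """Parse a SMILES into a bond-type-free heavy-atom graph (features unset).

    Node indices follow the toolkit's SMILES atom order, so ``node_order`` is
    the identity and positional readouts refer to positions in the SMILES
    chain.
    """
    mol = _mol_from_smiles(smiles)
    edges = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()), max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    return MolGraph(
        molecule_id=molecule_id or smiles,
        n_nodes=mol.GetNumAtoms(),
        edges=edges,
        smiles=smiles,
        mol=mol,
    )


def atom_features(graph: MolGraph) -> MolGraph:
    """Fill the 12 local atomic feature columns of ``graph`` in place."""
    mol = graph.mol
    if mol is None:
        mol = _mol_from_smiles(graph.smiles)
        graph.mol = mol
    n = graph.n_nodes
    feats = (
        graph.node_features
        if graph.node_features is not None and graph.node_features.shape == (n, N_NODE_FEATURES)
        else np.zeros((n, N_NODE_FEATURES))
    )
    for idx, atom in enumerate(mol.GetAtoms()):
        z = atom.GetAtomicNum()
        rvdw = _PT.GetRvdw(z)
        rcov = _PT.GetRcovalent(z)
        if rvdw <= 0 or rcov <= 0:
            raise FeaturizationError(
                f"no tabulated radius for element {atom.GetSymbol()} (Z={z})"
            )
        feats[idx, 0] = z
        feats[idx, 1] = atom.GetTotalNumHs()
        feats[idx, 2] = _PT.GetNOuterElecs(z)
        feats[idx, 3] = atom.GetNumRadicalElectrons()
        feats[idx, 4] = atom.GetFormalCharge()
        feats[idx, 5] = HYBRIDIZATION_CODES.get(atom.GetHybridization(), _HYBRIDIZATION_OTHER)
        feats[idx, 6] = atom.GetDegree()
        feats[idx, 7] = float(atom.IsInRing())
        feats[idx, 8] = float(atom.GetIsAromatic())
        feats[idx, 9] = rvdw / VDW_RADIUS_SCALE
        feats[idx, 10] = atom.GetMass() / ATOMIC_MASS_SCALE
        feats[idx, 11] = rcov / COVALENT_RADIUS_SCALE
    graph.node_features = feats
    return graph


# ---------------------------------------------------------------------------
# 3D shape
# ---------------------------------------------------------------------------


def _sphere_volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


def _lens_volume(d: float, r1: float, r2: float) -> float:
    """Volume of the intersection of two spheres at center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return _sphere_volume(min(r1, r2))
    return (
        math.pi
        * (r1 + r2 - d) ** 2
        * (d**2 + 2 * d * (r1 + r2) - 3 * (r1 - r2) ** 2)
        / (12 * d)
    )


def _union_volume(coords: np.ndarray, radii: np.ndarray) -> float:
    """Union volume of van der Waals spheres, pairwise-overlap corrected.

    Inclusion–exclusion is truncated at pair terms; triple overlaps of heavy
    atoms are small at bonding distances. Depends only on interatomic
    distances, hence exactly invariant under rigid motion.
    """
    vol = float(sum(_sphere_volume(r) for r in radii))
    n = len(radii)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            vol -= _lens_volume(d, radii[i], radii[j])
    return vol


def shape_from_coords(coords: np.ndarray, radii: np.ndarray) -> GlobalShape:
    """Shape descriptors from heavy-atom centers and their vdW radii.

    Extents are coordinate ranges along the principal axes of the centered
    coordinate cloud (eigenvectors of its 3x3 covariance), sorted descending.
    Invariant under rigid rotation/translation whenever the covariance
    spectrum is non-degenerate (for exactly symmetric tops the in-plane axes
    are arbitrary).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) == 1:
        extents = np.zeros(3)
    else:
        centered = coords - coords.mean(axis=0)
        cov = centered.T @ centered / len(coords)
        _, axes = np.linalg.eigh(cov)  # columns = principal axes
        proj = centered @ axes
        extents = np.sort(proj.max(axis=0) - proj.min(axis=0))[::-1]
    return GlobalShape(
        volume=_union_volume(coords, np.asarray(radii, dtype=float)),
        length=float(extents[0]),
        width=float(extents[1]),
        height=float(extents[2]),
    )


def global_shape(smiles: str, conformer_seed: int = 17, max_attempts: int = 5) -> GlobalShape:
    """Embed one 3D conformer and measure its global shape descriptors.

    Extents are coordinate ranges of the heavy-atom centers along the three
    principal axes of the (hydrogen-augmented, force-field relaxed) conformer,
    sorted descending into length/width/height. Deterministic for a fixed
    seed.
    """
    mol = _mol_from_smiles(smiles)
    molh = Chem.AddHs(mol)
    base_seed = int(conformer_seed) % (2**31 - 1)
    if base_seed <= 0:
        base_seed = 1
    params = AllChem.ETKDGv3()
    conf_id = -1
    for attempt in range(max_attempts):
        params.randomSeed = base_seed + attempt
        params.useRandomCoords = attempt > 1
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id >= 0:
            break
    if conf_id < 0:
        raise FeaturizationError(f"3D embedding failed for {smiles!r} after {max_attempts} attempts")
    try:
        if AllChem.MMFFHasAllMoleculeParams(molh):
            AllChem.MMFFOptimizeMolecule(molh, confId=conf_id)
        else:
            AllChem.UFFOptimizeMolecule(molh, confId=conf_id)
    except Exception:  # noqa: BLE001 - relaxation is best-effort, geometry stays usable
        logger.warning("force-field relaxation failed for %r; using raw embedding", smiles)
    conf = molh.GetConformer(conf_id)
    heavy_idx = [a.GetIdx() for a in molh.GetAtoms() if a.GetAtomicNum() > 1]
    coords = np.array([list(conf.GetAtomPosition(i)) for i in heavy_idx], dtype=float)
    radii = np.array([_PT.GetRvdw(molh.GetAtomWithIdx(i).GetAtomicNum()) for i in heavy_idx])
    return shape_from_coords(coords, radii)


def assemble_node_matrix(graph: MolGraph, shape: GlobalShape) -> MolGraph:
    """Copy the 4 global shape values onto columns 12..15 of every node."""
    if graph.node_features is None:
        raise FeaturizationError("local atomic features must be filled first")
    graph.node_features[:, N_LOCAL_FEATURES:] = np.array(shape.as_tuple())
    return graph


def featurize_smiles(smiles: str, molecule_id: str = "", conformer_seed: int = 17) -> MolGraph:
    """Full pipeline: SMILES -> graph with all 16 node-feature columns."""
    graph = smiles_to_graph(smiles, molecule_id=molecule_id)
    atom_features(graph)
    shape = global_shape(smiles, conformer_seed=conformer_seed)
    return assemble_node_matrix(graph, shape)


# ---------------------------------------------------------------------------
# descriptor tables
# ---------------------------------------------------------------------------


def load_descriptor_table(path) -> DescriptorTable:
    """Read a PaDEL-export-style CSV: id column ``Name`` then descriptor columns.

    Empty/NA cells are imputed with the column median and flagged; cells that
    are present but non-numeric raise :class:`SchemaError` naming the row and
    column. Constant-valued columns are retained but flagged.
    """
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise SchemaError("descriptor table needs an id column plus >=1 descriptor column")
    id_col = df.columns[0]
    ids = df[id_col].astype(str).tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"duplicate molecule ids: {dupes}")
    names = [str(c) for c in df.columns[1:]]
    na_tokens = {"", "na", "nan", "n/a", "null", "inf", "-inf", "infinity", "-infinity"}
    values = np.empty((len(ids), len(names)))
    imputed: list[tuple[str, str]] = []
    for j, name in enumerate(names):
        col = df[name].astype(str).str.strip()
        for i, cell in enumerate(col):
            if cell.lower() in na_tokens:
                values[i, j] = np.nan
                imputed.append((ids[i], name))
                continue
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise SchemaError(
                    f"non-numeric cell at row {i} (molecule {ids[i]!r}), column {name!r}: {cell!r}"
                ) from exc
        if np.isnan(values[:, j]).any():
            med = np.nanmedian(values[:, j])
            if np.isnan(med):
                med = 0.0
            values[np.isnan(values[:, j]), j] = med
    constant = [names[j] for j in range(len(names)) if np.ptp(values[:, j]) == 0.0]
    return DescriptorTable(ids, names, values, imputed_cells=imputed, constant_columns=constant)


def write_descriptor_table(table: DescriptorTable, path) -> None:
    table.to_dataframe().to_csv(path, index=False)


_COUNT_DESCRIPTORS = [
    "n_heavy",
    "n_carbon",
    "n_nitrogen",
    "n_oxygen",
    "n_halogen",
    "n_aromatic",
    "n_rings",
    "n_hetero",
    "n_bonds",
    "n_hydrogens",
]


def count_descriptor_table(smiles_list: list[str], molecule_ids: list[str] | None = None) -> DescriptorTable:
    """Simple graph-derived count descriptors (self-contained baseline input)."""
    if molecule_ids is None:
        molecule_ids = list(smiles_list)
    rows = []
    halogens = {9, 17, 35, 53}
    for smi in smiles_list:
        mol = _mol_from_smiles(smi)
        zs = [a.GetAtomicNum() for a in mol.GetAtoms()]
        rows.append(
            [
                mol.GetNumHeavyAtoms(),
                sum(z == 6 for z in zs),
                sum(z == 7 for z in zs),
                sum(z == 8 for z in zs),
                sum(z in halogens for z in zs),
                sum(a.GetIsAromatic() for a in mol.GetAtoms()),
                mol.GetRingInfo().NumRings(),
                sum(z not in (1, 6) for z in zs),
                mol.GetNumBonds(),
                sum(a.GetTotalNumHs() for a in mol.GetAtoms()),
            ]
        )
    return DescriptorTable(list(molecule_ids), list(_COUNT_DESCRIPTORS), np.array(rows, dtype=float))


def select_main_features(
    table: DescriptorTable, targets, k: int = 11, seed: int = 0
) -> list[str]:
    """Rank descriptors by Random-Forest mean impurity decrease, return top k.

    Uses the same forest configuration as the baseline models (500 trees,
    depth 4). Ties are broken by descriptor name order; deterministic for a
    fixed seed.
    """
    from .baselines import make_estimator, BaselineConfig  # local import avoids a cycle

    if k > len(table.descriptor_names):
        raise ValueError(
            f"k={k} exceeds the {len(table.descriptor_names)} available descriptors"
        )
    y = np.asarray(targets, dtype=float)
    if len(y) != table.n_molecules:
        raise ValueError("targets are not aligned with the descriptor table rows")
    forest = make_estimator(BaselineConfig(model="random_forest", seed=seed))
    forest.fit(table.values, y)
    importances = forest.feature_importances_
    order = sorted(
        range(len(importances)), key=lambda j: (-importances[j], table.descriptor_names[j])
    )
    return [table.descriptor_names[j] for j in order[:k]]


def graphs_to_json(graphs: list[MolGraph], path) -> None:
    with open(path, "w") as fh:
        json.dump([g.to_dict() for g in graphs], fh)


def graphs_from_json(path) -> list[MolGraph]:
    with open(path) as fh:
        return [MolGraph.from_dict(d) for d in json.load(fh)]
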
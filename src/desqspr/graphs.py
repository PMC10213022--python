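"""Hydrogen-depleted molecular graphs and edge-adjacency spectral descriptors.

The descriptors implemented here (the ``EEig`` eigenvalue family and the
``ESpm`` spectral-moment family) are derived from the edge-adjacency matrix
``EA(G)`` of a hydrogen-depleted molecular graph: a square matrix over the
molecule's bonds whose entry (i, j) is 1 when bonds i and j share an atom,
and 0 otherwise (zero diagonal).  Heteroatom information enters through bond
dipole-moment weights.  Three weighting conventions are supported:

``diagonal``
    Off-diagonal entries stay 0/1; the diagonal entry (i, i) is the dipole
    moment of bond i.  This is Estrada's weighted edge-adjacency matrix and
    the calibrated default: with the shipped bond-dipole table it reproduces
    the packaged EEig02d reference values for the text-consistent donors.
``symmetric``
    Entry (i, j) = sqrt(w_i * w_j) for adjacent bonds, zero diagonal.
``literal``
    Entry (i, j) = w_j for adjacent bonds (generally asymmetric).

``EEig0k(d)`` is the k-th largest eigenvalue of this matrix; ``ESpm0k(d)``
is the trace of its k-th power, reported on a log scale as ln(1 + trace).
"""

from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import DescriptorError, StructureParseError

RDLogger.DisableLog("rdApp.*")

BOND_CLASSES = ("single", "double", "triple", "aromatic")

_RDKIT_BOND_CLASS = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}

CONVENTIONS = ("literal", "symmetric", "diagonal")

#: Suffix Dragon-style descriptor names use for dipole-moment weighting.
DIPOLE_SUFFIX = "d"


@dataclass(frozen=True)
class Bond:
    """One bond of a hydrogen-depleted graph; endpoints satisfy i < j."""

    i: int
    j: int
    bond_class: str

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError(f"self-loop on atom {self.i}")
        if self.bond_class not in BOND_CLASSES:
            raise ValueError(f"unknown bond class {self.bond_class!r}")
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)


@dataclass
class MolecularGraph:
    """Hydrogen-depleted atom/bond graph of one hydrogen-bond donor.

    ``atoms`` is a list of (element symbol, formal charge); ``bonds`` holds
    the canonical bond list, sorted by (min endpoint, max endpoint).
    """

    atoms: list[tuple[str, int]]
    bonds: list[Bond]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError(f"bond ({b.i},{b.j}) has an invalid atom index")
            if (b.i, b.j) in seen:
                raise ValueError(f"duplicate bond ({b.i},{b.j})")
            seen.add((b.i, b.j))
        self.bonds = sorted(self.bonds, key=lambda b: (b.i, b.j))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Relabel atoms by ``perm`` (atom k becomes perm[k]); descriptors
        must be invariant under this."""
        inv_atoms: list[tuple[str, int]] = [("", 0)] * len(self.atoms)
        for k, a in enumerate(self.atoms):
            inv_atoms[perm[k]] = a
        bonds = [Bond(min(perm[b.i], perm[b.j]), max(perm[b.i], perm[b.j]), b.bond_class)
                 for b in self.bonds]
        return MolecularGraph(inv_atoms, bonds, self.name)


def _locate_bad_token(smiles: str) -> str:
    """Best-effort pointer at the first position where parsing breaks."""
    for end in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:end], sanitize=False) is None:
            return f"near position {end} ({smiles[max(0, end - 3):end]!r})"
    return "structure-level failure (valence or ring perception)"


def parse_structure(smiles: str, name: str = "") -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-depleted molecular graph.

    Atoms are renumbered by RDKit's canonical ranking so that the bond list
    (and hence every edge matrix) is reproducible regardless of how the
    input SMILES was written.  Multi-fragment inputs are rejected.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(
            f"cannot parse SMILES {smiles!r} for {name or 'unnamed molecule'}: "
            + _locate_bad_token(smiles)
        )
    if len(Chem.GetMolFrags(mol)) > 1:
        raise StructureParseError(
            f"{smiles!r} contains multiple disconnected fragments; "
            "one molecule per record is required"
        )
    ranks = list(Chem.CanonicalRankAtoms(mol))
    atoms: list[tuple[str, int]] = [("", 0)] * mol.GetNumAtoms()
    for atom in mol.GetAtoms():
        atoms[ranks[atom.GetIdx()]] = (atom.GetSymbol(), atom.GetFormalCharge())
    bonds = []
    for bond in mol.GetBonds():
        cls = _RDKIT_BOND_CLASS.get(bond.GetBondType())
        if cls is None:
            raise StructureParseError(
                f"unsupported bond type {bond.GetBondType()} in {smiles!r}"
            )
        i, j = ranks[bond.GetBeginAtomIdx()], ranks[bond.GetEndAtomIdx()]
        bonds.append(Bond(min(i, j), max(i, j), cls))
    return MolecularGraph(atoms, bonds, name or smiles)


def read_smiles_file(path) -> list[MolecularGraph]:
    """Read molecules from a one-record-per-line SMILES file.

    Each line is ``SMILES[<tab or spaces>name]``; the name may contain
    spaces only when tab-delimited.  Blank lines and ``#`` comments skip.
    """
    graphs = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                smiles, _, name = line.partition("\t")
            else:
                parts = line.split(None, 1)
                smiles = parts[0]
                name = parts[1] if len(parts) > 1 else ""
            try:
                graphs.append(parse_structure(smiles.strip(), name.strip()))
            except StructureParseError as exc:
                raise StructureParseError(f"line {lineno}: {exc}") from exc
    return graphs


class BondDipoleTable:
    """Map (unordered element pair, bond class) -> dipole weight in Debye.

    Unlisted keys weigh 0 (carbon-carbon bonds in particular).  The table is
    calibration data: it ships as an editable CSV and only relative
    magnitudes matter, so the Debye values are used as-is.
    """

    def __init__(self, entries: Mapping[tuple[tuple[str, str], str], float]):
        self._entries: dict[tuple[tuple[str, str], str], float] = {}
        for (pair, cls), w in entries.items():
            if cls not in BOND_CLASSES:
                raise ValueError(f"unknown bond class {cls!r}")
            if w < 0:
                raise ValueError(f"negative weight for {pair} {cls}")
            self._entries[(tuple(sorted(pair)), cls)] = float(w)

    def lookup(self, elem_a: str, elem_b: str, bond_class: str) -> float:
        return self._entries.get((tuple(sorted((elem_a, elem_b))), bond_class), 0.0)

    def weight(self, g: MolecularGraph, bond: Bond) -> float:
        return self.lookup(g.atoms[bond.i][0], g.atoms[bond.j][0], bond.bond_class)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"element_a": a, "element_b": b, "bond_class": cls, "weight_debye": w}
            for ((a, b), cls), w in sorted(self._entries.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BondDipoleTable":
        required = {"element_a", "element_b", "bond_class", "weight_debye"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"bond-dipole table missing columns: {sorted(missing)}")
        return cls(
            {
                ((str(r.element_a), str(r.element_b)), str(r.bond_class)): float(r.weight_debye)
                for r in df.itertuples()
            }
        )

    @classmethod
    def from_csv(cls, path) -> "BondDipoleTable":
        return cls.from_frame(pd.read_csv(path, comment="#"))

    @classmethod
    def default(cls) -> "BondDipoleTable":
        text = resources.files("desqspr").joinpath("data/bond_dipoles.csv").read_text()
        return cls.from_frame(pd.read_csv(io.StringIO(text), comment="#"))


@dataclass
class EdgeMatrix:
    """Edge-adjacency matrix of one molecule under one weighting convention."""

    values: np.ndarray
    convention: str
    weighted: bool
    bonds: list[Bond] = field(default_factory=list)
    molecule: str = ""

    @property
    def dim(self) -> int:
        return self.values.shape[0]


def _bond_adjacency(bonds: Sequence[Bond]) -> np.ndarray:
    m = len(bonds)
    adj = np.zeros((m, m))
    for i in range(m):
        ei = {bonds[i].i, bonds[i].j}
        for j in range(i + 1, m):
            if ei & {bonds[j].i, bonds[j].j}:
                adj[i, j] = adj[j, i] = 1.0
    return adj


def edge_adjacency(g: MolecularGraph) -> EdgeMatrix:
    """Unweighted edge-adjacency matrix: (i,j)=1 iff bonds i, j share an atom."""
    if g.n_bonds == 0:
        raise DescriptorError(f"{g.name or 'molecule'} has no edges")
    return EdgeMatrix(_bond_adjacency(g.bonds), "symmetric", False, list(g.bonds), g.name)


def weighted_edge_adjacency(
    g: MolecularGraph,
    weights: BondDipoleTable,
    convention: str = "diagonal",
) -> EdgeMatrix:
    """Dipole-weighted edge-adjacency matrix under the chosen convention."""
    if convention not in CONVENTIONS:
        raise DescriptorError(
            f"unknown convention {convention!r}; choose one of {CONVENTIONS}"
        )
    if g.n_bonds == 0:
        raise DescriptorError(f"{g.name or 'molecule'} has no edges")
    w = np.array([weights.weight(g, b) for b in g.bonds])
    adj = _bond_adjacency(g.bonds)
    if convention == "diagonal":
        m = adj + np.diag(w)
    elif convention == "symmetric":
        m = adj * np.sqrt(np.outer(w, w))
    else:  # literal: entry (i, j) carries the weight of bond j
        m = adj * w[np.newaxis, :]
    return EdgeMatrix(m, convention, True, list(g.bonds), g.name)


@dataclass(frozen=True)
class DescriptorValue:
    name: str
    value: float
    molecule: str
    convention: str


def _eigvals_desc(m: EdgeMatrix) -> np.ndarray:
    if np.allclose(m.values, m.values.T):
        ev = np.linalg.eigvalsh(m.values).astype(complex)
    else:
        ev = np.linalg.eigvals(m.values)
    order = np.argsort(-ev.real, kind="stable")
    return ev[order]


def eigen_descriptor(m: EdgeMatrix, k: int = 2) -> DescriptorValue:
    """k-th largest eigenvalue (by algebraic value) of the edge matrix.

    The name renders as ``EEig0{k}`` plus the dipole suffix for weighted
    matrices.  Complex eigenvalues (possible under the literal convention)
    are rejected beyond a 1e-8 imaginary tolerance.
    """
    if k < 1:
        raise DescriptorError("eigenvalue order k must be >= 1")
    if k > m.dim:
        raise DescriptorError(
            f"EEig{k:02d} undefined for this molecule size "
            f"({m.molecule or 'molecule'} has only {m.dim} bond(s))"
        )
    ev = _eigvals_desc(m)[k - 1]
    if abs(ev.imag) > 1e-8:
        raise DescriptorError(
            f"eigenvalue {k} of {m.molecule} is complex ({ev:.3g}) under the "
            f"{m.convention} convention"
        )
    suffix = DIPOLE_SUFFIX if m.weighted else ""
    return DescriptorValue(f"EEig{k:02d}{suffix}", float(ev.real), m.molecule, m.convention)


#: Floor applied to 1 + trace before the log transform (degenerate traces).
SPECTRAL_LOG_FLOOR = 1e-12


def spectral_moment(m: EdgeMatrix, k: int = 2, log_scale: bool = True) -> DescriptorValue:
    """Spectral moment of order k: trace of the k-th matrix power.

    On the log scale the value is ln(1 + trace) — the transform that matches
    the packaged ESpm02d reference values; 1 + trace is floored at
    ``SPECTRAL_LOG_FLOOR`` for the (odd-order, weighted) cases where it
    could be non-positive.
    """
    if k < 1:
        raise DescriptorError("spectral moment order k must be >= 1")
    trace = float(np.trace(np.linalg.matrix_power(m.values, k)))
    value = math.log(max(1.0 + trace, SPECTRAL_LOG_FLOOR)) if log_scale else trace
    suffix = DIPOLE_SUFFIX if m.weighted else ""
    return DescriptorValue(f"ESpm{k:02d}{suffix}", value, m.molecule, m.convention)


@dataclass
class DescriptorConfig:
    """How descriptor tables are computed: convention + dipole table."""

    convention: str = "diagonal"
    dipole_table: BondDipoleTable | None = None
    log_scale_moments: bool = True

    def table(self) -> BondDipoleTable:
        return self.dipole_table if self.dipole_table is not None else BondDipoleTable.default()


_NAME_RE = re.compile(r"^(EEig|ESpm)(\d{2})(d?)$")


def _parse_descriptor_name(name: str) -> tuple[str, int, bool]:
    m = _NAME_RE.match(name)
    if not m:
        raise DescriptorError(
            f"unsupported descriptor {name!r}; supported names match "
            "EEig0k / EEig0kd / ESpm0k / ESpm0kd (e.g. EEig02d)"
        )
    return m.group(1), int(m.group(2)), m.group(3) == DIPOLE_SUFFIX


def compute_descriptor_table(
    molecules: Iterable[MolecularGraph],
    names: Sequence[str],
    config: DescriptorConfig | None = None,
) -> pd.DataFrame:
    """One row per (molecule, descriptor): columns molecule, descriptor,
    value, convention.  Deterministic given the config."""
    config = config or DescriptorConfig()
    for name in names:
        _parse_descriptor_name(name)
    table = config.table()
    rows = []
    for g in molecules:
        unweighted = None
        weighted = None
        for name in names:
            family, k, dipole = _parse_descriptor_name(name)
            if dipole:
                if weighted is None:
                    weighted = weighted_edge_adjacency(g, table, config.convention)
                mat = weighted
            else:
                if unweighted is None:
                    unweighted = edge_adjacency(g)
                mat = unweighted
            if family == "EEig":
                dv = eigen_descriptor(mat, k)
            else:
                dv = spectral_moment(mat, k, log_scale=config.log_scale_moments)
            rows.append(
                {"molecule": g.name, "descriptor": dv.name, "value": dv.value,
                 "convention": dv.convention}
            )
    return pd.DataFrame(rows, columns=["molecule", "descriptor", "value", "convention"])


@dataclass
class CalibrationResult:
    convention: str
    max_abs_deviation: dict[str, float]
    report: pd.DataFrame


def calibrate_convention(
    molecules: Sequence[MolecularGraph],
    reference: Mapping[str, float],
    dipole_table: BondDipoleTable | None = None,
) -> CalibrationResult:
    """Pick the weighting convention that best reproduces reference EEig02d.

    Evaluates all three conventions on every molecule present in
    ``reference`` and returns the one minimising the maximum absolute
    deviation, together with a per-molecule deviation report.  Ties are
    broken in favour of symmetric, then diagonal: the literal matrix
    A*diag(w) is similar to the symmetric diag(w)^1/2 * A * diag(w)^1/2,
    so those two always tie and the one with a guaranteed-real spectrum
    wins.
    """
    table = dipole_table if dipole_table is not None else BondDipoleTable.default()
    named = {g.name: g for g in molecules}
    missing = sorted(set(reference) - set(named))
    if missing:
        raise DescriptorError(f"no structure supplied for reference molecule(s) {missing}")
    if len(reference) < 3:
        raise DescriptorError(
            f"convention calibration needs at least 3 reference molecules, got {len(reference)}"
        )
    rows = []
    max_dev: dict[str, float] = {}
    for conv in CONVENTIONS:
        worst = 0.0
        for name, ref in reference.items():
            try:
                val = eigen_descriptor(
                    weighted_edge_adjacency(named[name], table, conv), 2
                ).value
                dev = abs(val - ref)
            except DescriptorError:
                val, dev = float("nan"), float("inf")
            worst = max(worst, dev)
            rows.append(
                {"molecule": name, "convention": conv, "computed": val,
                 "reference": ref, "abs_deviation": dev}
            )
        max_dev[conv] = worst
    best = min(("symmetric", "diagonal", "literal"), key=lambda c: max_dev[c])
    return CalibrationResult(best, max_dev, pd.DataFrame(rows))


def load_default_structures() -> dict[str, MolecularGraph]:
    """The packaged hydrogen-bond-donor structures, keyed by name."""
    text = resources.files("desqspr").joinpath("data/hbd_structures.smi").read_text()
    graphs: dict[str, MolecularGraph] = {}
    for line in text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        smiles, _, name = line.partition("\t")
        g = parse_structure(smiles.strip(), name.strip())
        graphs[g.name] = g
    return graphs
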
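"""Mining a vocabulary of recurrent ligand substructures ("protogroups").

A protogroup is a small compound (four or more heavy atoms) that both acts
as a standalone protein ligand and recurs as a substructure of larger
ligands.  Candidates are ranked by the number of library ligands they match
as an element-labeled subgraph (bond order and charge ignored, hydrogens
stripped); the vocabulary is selected in two passes — first the most
frequent candidates with >= 5 atoms, then additional candidates with >= 4
atoms — mirroring how the reference 87-member vocabulary was assembled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

import networkx as nx
import pandas as pd
from networkx.algorithms import isomorphism

logger = logging.getLogger(__name__)

FIRST_PASS_MIN_ATOMS = 5
SECOND_PASS_MIN_ATOMS = 4
FIRST_PASS_SIZE = 61
TOTAL_VOCAB_SIZE = 87


@dataclass(frozen=True)
class MolecularGraph:
    """A connected, hydrogen-free, element-labeled molecular graph."""

    component_id: str
    atoms: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(
            self, "bonds", tuple(tuple(sorted(b)) for b in self.bonds)
        )
        n = len(self.atoms)
        for a, b in self.bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise ValueError(f"invalid bond ({a}, {b}) in {self.component_id!r}")
        if any(atom == "H" for atom in self.atoms):
            raise ValueError(f"{self.component_id!r} contains explicit hydrogens")

    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, element in enumerate(self.atoms):
            g.add_node(i, element=element)
        g.add_edges_from(self.bonds)
        return g

    def is_connected(self) -> bool:
        return self.atom_count > 0 and nx.is_connected(self.to_networkx())

    def formula(self) -> str:
        """Hill-order heavy-atom formula (C first, then alphabetical)."""
        from collections import Counter

        counts = Counter(self.atoms)
        parts = []
        for element in (["C"] if "C" in counts else []) + sorted(
            e for e in counts if e != "C"
        ):
            n = counts[element]
            parts.append(element + (str(n) if n > 1 else ""))
        return "".join(parts)


@dataclass(frozen=True)
class Protogroup:
    """A vocabulary member: substructure graph plus its mining statistics."""

    graph: MolecularGraph
    rank: int
    match_frequency: int
    vocab_index: int

    def __post_init__(self) -> None:
        if self.graph.atom_count < SECOND_PASS_MIN_ATOMS:
            raise ValueError(
                f"protogroup {self.graph.component_id!r} has fewer than "
                f"{SECOND_PASS_MIN_ATOMS} atoms"
            )


#: Per-ligand map atom-index -> set of protogroup vocab indices covering it.
AtomAssignment = dict[int, set[int]]

_NODE_MATCH = isomorphism.categorical_node_match("element", None)


def _matcher(ligand: nx.Graph, candidate: nx.Graph) -> isomorphism.GraphMatcher:
    return isomorphism.GraphMatcher(ligand, candidate, node_match=_NODE_MATCH)


def matches_substructure(
    candidate: MolecularGraph, ligand: MolecularGraph, induced: bool = False
) -> bool:
    """True when *ligand* contains *candidate* as an element-labeled subgraph.

    Default semantics are subgraph monomorphism (each candidate bond must map
    to a ligand bond; extra ligand bonds are allowed), the usual chemical
    substructure reading.  ``induced=True`` switches to node-induced subgraph
    isomorphism.
    """
    gm = _matcher(ligand.to_networkx(), candidate.to_networkx())
    return gm.subgraph_is_isomorphic() if induced else gm.subgraph_is_monomorphic()


def count_substructure_matches(
    candidate: MolecularGraph,
    ligands: Iterable[MolecularGraph],
    induced: bool = False,
) -> int:
    """Number of ligands containing *candidate*; each ligand counts once.

    A ligand with several embeddings of the candidate still contributes one,
    and a candidate matches itself.
    """
    if not candidate.is_connected():
        raise ValueError(f"candidate {candidate.component_id!r} is not connected")
    return sum(1 for lig in ligands if matches_substructure(candidate, lig, induced=induced))


def rank_candidates(
    ligands: TypingSequence[MolecularGraph], induced: bool = False
) -> list[tuple[MolecularGraph, int]]:
    """Match frequency of every library member against the whole library.

    Sorted by descending frequency, ties broken lexicographically by
    component id.
    """
    scored = [
        (mol, count_substructure_matches(mol, ligands, induced=induced))
        for mol in ligands
    ]
    scored.sort(key=lambda item: (-item[1], item[0].component_id))
    return scored


def select_protogroups(
    ranked: TypingSequence[tuple[MolecularGraph, int]],
    first_pass_min_atoms: int = FIRST_PASS_MIN_ATOMS,
    second_pass_min_atoms: int = SECOND_PASS_MIN_ATOMS,
    first_pass_size: int = FIRST_PASS_SIZE,
    total_size: int = TOTAL_VOCAB_SIZE,
) -> list[Protogroup]:
    """Two-pass vocabulary selection from frequency-ranked candidates.

    Pass 1 takes the top candidates with >= *first_pass_min_atoms* atoms up
    to *first_pass_size*; pass 2 adds the top remaining candidates with
    >= *second_pass_min_atoms* atoms until *total_size* members.
    """
    ranked = sorted(ranked, key=lambda item: (-item[1], item[0].component_id))
    chosen: list[tuple[MolecularGraph, int]] = []
    taken: set[str] = set()
    for mol, freq in ranked:
        if len(chosen) >= first_pass_size:
            break
        if mol.atom_count >= first_pass_min_atoms and mol.component_id not in taken:
            chosen.append((mol, freq))
            taken.add(mol.component_id)
    for mol, freq in ranked:
        if len(chosen) >= total_size:
            break
        if mol.atom_count >= second_pass_min_atoms and mol.component_id not in taken:
            chosen.append((mol, freq))
            taken.add(mol.component_id)
    if len(chosen) < total_size:
        warnings.warn(
            f"only {len(chosen)} eligible candidates for a vocabulary of {total_size}",
            stacklevel=2,
        )
    return [
        Protogroup(graph=mol, rank=i + 1, match_frequency=freq, vocab_index=i + 1)
        for i, (mol, freq) in enumerate(chosen)
    ]


def mine_vocabulary(
    ligands: TypingSequence[MolecularGraph], induced: bool = False, **selection_kwargs
) -> list[Protogroup]:
    """Rank the library against itself and run the two-pass selection."""
    return select_protogroups(rank_candidates(ligands, induced=induced), **selection_kwargs)


def assign_atoms(
    vocabulary: TypingSequence[Protogroup],
    ligand: MolecularGraph,
    induced: bool = False,
) -> AtomAssignment:
    """Atom-level vocabulary assignment over all subgraph embeddings."""
    assignment: AtomAssignment = {i: set() for i in range(ligand.atom_count)}
    lig_nx = ligand.to_networkx()
    for pg in vocabulary:
        gm = _matcher(lig_nx, pg.graph.to_networkx())
        embeddings = (
            gm.subgraph_isomorphisms_iter() if induced else gm.subgraph_monomorphisms_iter()
        )
        for mapping in embeddings:
            for ligand_atom in mapping:
                assignment[ligand_atom].add(pg.vocab_index)
    return assignment


def coverage_overlap(
    vocabulary: TypingSequence[Protogroup],
    ligands: Iterable[MolecularGraph],
    induced: bool = False,
) -> tuple[float, float]:
    """Atom coverage and overlap of a vocabulary over a ligand library.

    coverage = fraction of ligand atoms assigned to >= 1 protogroup;
    overlap = fraction assigned to >= 2 distinct protogroups.
    """
    total = 0
    covered = 0
    multi = 0
    for ligand in ligands:
        assignment = (
            assign_atoms(vocabulary, ligand, induced=induced) if vocabulary else {}
        )
        total += ligand.atom_count
        covered += sum(1 for groups in assignment.values() if len(groups) >= 1)
        multi += sum(1 for groups in assignment.values() if len(groups) >= 2)
    if total == 0:
        return 0.0, 0.0
    return covered / total, multi / total


def label_interacting_protogroups(
    contacted_ligand_atoms: Iterable[int], assignment: AtomAssignment
) -> set[int]:
    """Vocab indices interacting with a record: groups of any contacted atom."""
    interacting: set[int] = set()
    for atom in contacted_ligand_atoms:
        groups = assignment.get(atom)
        if not groups:
            logger.warning("contacted ligand atom %d is assigned to no protogroup", atom)
            continue
        interacting |= groups
    return interacting


# ---------------------------------------------------------------------------
# SDF I/O (rdkit) and vocabulary manifests


def read_sdf(path: str | Path) -> list[MolecularGraph]:
    """Read an SDF/MOL library into hydrogen-free molecular graphs."""
    from rdkit import Chem

    graphs: list[MolecularGraph] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            logger.warning("unparseable SDF record %d in %s", i, path)
            continue
        mol = Chem.RemoveHs(mol, sanitize=False)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i}"
        keep = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() != "H"]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = tuple(mol.GetAtomWithIdx(i).GetSymbol() for i in keep)
        bonds = tuple(
            (remap[b.GetBeginAtomIdx()], remap[b.GetEndAtomIdx()])
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in remap and b.GetEndAtomIdx() in remap
        )
        graphs.append(MolecularGraph(component_id=name or f"mol{i}", atoms=atoms, bonds=bonds))
    return graphs


def write_sdf(graphs: Iterable[MolecularGraph], path: str | Path) -> None:
    """Write molecular graphs as a (2D-less) SDF file; single bonds throughout."""
    from rdkit import Chem

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    for graph in graphs:
        rw = Chem.RWMol()
        for element in graph.atoms:
            atom = Chem.Atom(element)
            atom.SetNoImplicit(True)
            rw.AddAtom(atom)
        for a, b in graph.bonds:
            rw.AddBond(a, b, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        mol.SetProp("_Name", graph.component_id)
        Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
        writer.write(mol)
    writer.close()


def write_vocabulary(vocabulary: TypingSequence[Protogroup], path: str | Path) -> None:
    """Vocabulary manifest TSV (index, id, formula, atoms, frequency, rank, graph)."""
    rows = [
        {
            "vocab_index": pg.vocab_index,
            "component_id": pg.graph.component_id,
            "formula": pg.graph.formula(),
            "atom_count": pg.graph.atom_count,
            "match_frequency": pg.match_frequency,
            "rank": pg.rank,
            "atoms": ",".join(pg.graph.atoms),
            "bonds": ";".join(f"{a}-{b}" for a, b in pg.graph.bonds),
        }
        for pg in vocabulary
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vocabulary(path: str | Path) -> list[Protogroup]:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    vocabulary = []
    for row in df.itertuples():
        bonds = tuple(
            tuple(int(x) for x in pair.split("-"))
            for pair in str(row.bonds).split(";")
            if pair
        )
        graph = MolecularGraph(
            component_id=str(row.component_id),
            atoms=tuple(str(row.atoms).split(",")),
            bonds=bonds,
        )
        vocabulary.append(
            Protogroup(
                graph=graph,
                rank=int(row.rank),
                match_frequency=int(row.match_frequency),
                vocab_index=int(row.vocab_index),
            )
        )
    return vocabulary


def reference_vocabulary() -> list[Protogroup]:
    """The shipped stand-in vocabulary (synthetic; mined from the toy library)."""
    return read_vocabulary(Path(__file__).parent / "data" / "synthetic_protogroups.tsv")
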
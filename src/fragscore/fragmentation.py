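"""Combinatorial bond-disconnection fragmentation and peak assignment.

Each candidate molecule is fragmented in silico by systematically breaking
bonds of its molecular graph: at every disconnection level each acyclic
bond of a fragment is removed (ring bonds must be removed pairwise to open
the ring), and the resulting connected components become child fragments.
Fragments carry the cumulative energy of their broken bonds, which serves
as a penalty in the fragmenter score and as a tie-break when several
fragments explain the same peak.

Fragment masses are computed on the hydrogen-capped neutral fragment:
open valences created by bond cleavage are saturated with hydrogens. The
synthetic spectra in :mod:`fragscore.synth` are generated from the same
convention, so training and scoring are mass-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors

from .spectra import Candidate, Peak, Spectrum

__all__ = [
    "PROTON_MASS",
    "FragmentStructure",
    "PeakAssignment",
    "LossAssignment",
    "fragment_candidate",
    "ion_mass",
    "assign_peaks",
    "compute_losses",
    "fragmenter_raw_score",
    "fragmenter_scores",
]

PROTON_MASS = 1.00727646688  # Da

#: default per-bond disconnection energies by bond order
_BOND_ENERGY = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


@dataclass(frozen=True)
class FragmentStructure:
    """A connected substructure of a candidate, identified by parent atom indices."""

    parent: Chem.Mol = field(compare=False, repr=False)
    atoms: frozenset[int]
    removed_bonds: frozenset[int]
    bond_energy: float
    depth: int

    def present_bonds(self) -> list[int]:
        out = []
        for b in self.parent.GetBonds():
            if (b.GetIdx() not in self.removed_bonds
                    and b.GetBeginAtomIdx() in self.atoms
                    and b.GetEndAtomIdx() in self.atoms):
                out.append(b.GetIdx())
        return out

    def to_mol(self) -> Chem.Mol:
        """Hydrogen-capped RDKit molecule of this fragment."""
        smi = Chem.MolFragmentToSmiles(
            self.parent, atomsToUse=sorted(self.atoms),
            bondsToUse=self.present_bonds() or None, canonical=True)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:  # pragma: no cover - kekulized parents always parse
            raise ValueError(f"fragment SMILES {smi!r} failed to parse")
        return mol

    @cached_property
    def formula_mass(self) -> float:
        """Monoisotopic mass (Da) of the neutral, H-capped fragment formula."""
        return Descriptors.ExactMolWt(self.to_mol())

    def sort_key(self) -> tuple:
        return (self.bond_energy, self.depth, tuple(sorted(self.atoms)))


@dataclass(frozen=True)
class PeakAssignment:
    """A peak explained by a fragment-structure, or unannotated (fragment=None)."""

    peak: Peak
    fragment: FragmentStructure | None
    theoretical_mz: float | None = None  # adduct-adjusted fragment ion mass


@dataclass(frozen=True)
class LossAssignment:
    """A neutral loss (mass difference of two peaks) and its loss structure."""

    loss_mz: float
    fragment: FragmentStructure | None


def _components(atoms: Iterable[int], adjacency: dict[int, list[tuple[int, int]]],
                dead_bonds: frozenset[int]) -> list[frozenset[int]]:
    remaining = set(atoms)
    comps = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            a = stack.pop()
            for nbr, bidx in adjacency[a]:
                if bidx not in dead_bonds and nbr in remaining:
                    remaining.discard(nbr)
                    comp.add(nbr)
                    stack.append(nbr)
        comps.append(frozenset(comp))
    return comps


def fragment_candidate(c: Candidate, max_depth: int = 2,
                       bond_energies: dict | None = None) -> list[FragmentStructure]:
    """Enumerate proper fragments of a candidate by breadth-first bond disconnection.

    Depth counts disconnection events: one acyclic bond cut, or one pairwise
    ring-bond cut, per level. Duplicate atom sets are pruned keeping the
    cheapest (lowest bond-energy) generation path. The intact molecule is
    not returned.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    if len(Chem.GetMolFrags(c.structure)) != 1:
        raise ValueError(f"candidate {c.id!r} is not connected; filter "
                         "candidate lists before fragmentation")
    energies = bond_energies or _BOND_ENERGY
    parent = Chem.Mol(c.structure)
    Chem.Kekulize(parent, clearAromaticFlags=True)

    adjacency: dict[int, list[tuple[int, int]]] = {a.GetIdx(): [] for a in parent.GetAtoms()}
    bond_ends: dict[int, tuple[int, int]] = {}
    bond_cost: dict[int, float] = {}
    ring_info = parent.GetRingInfo()
    for b in parent.GetBonds():
        i, j, idx = b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetIdx()
        adjacency[i].append((j, idx))
        adjacency[j].append((i, idx))
        bond_ends[idx] = (i, j)
        bond_cost[idx] = energies.get(b.GetBondType(), 1.0)

    def subgraph_bonds(atom_set: frozenset[int], removed: frozenset[int]) -> list[int]:
        return [idx for idx, (i, j) in bond_ends.items()
                if idx not in removed and i in atom_set and j in atom_set]

    def split(atom_set: frozenset[int], removed: frozenset[int]) -> list[frozenset[int]]:
        return _components(atom_set, adjacency, removed)

    root_atoms = frozenset(adjacency)
    best: dict[frozenset[int], FragmentStructure] = {}
    frontier: list[FragmentStructure] = [FragmentStructure(
        parent=parent, atoms=root_atoms, removed_bonds=frozenset(),
        bond_energy=0.0, depth=0)]

    for depth in range(1, max_depth + 1):
        children: dict[frozenset[int], FragmentStructure] = {}

        def emit(atom_set: frozenset[int], removed: frozenset[int], energy: float) -> None:
            if len(atom_set) == len(root_atoms):
                return
            sub_removed = frozenset(b for b in removed
                                    if bond_ends[b][0] in atom_set
                                    and bond_ends[b][1] in atom_set)
            frag = FragmentStructure(parent=parent, atoms=atom_set,
                                     removed_bonds=sub_removed,
                                     bond_energy=energy, depth=depth)
            prev = best.get(atom_set) or children.get(atom_set)
            if prev is None or frag.bond_energy < prev.bond_energy:
                children[atom_set] = frag

        for frag in frontier:
            bonds = subgraph_bonds(frag.atoms, frag.removed_bonds)
            ring_bonds = [b for b in bonds if ring_info.NumBondRings(b) > 0]
            for b in bonds:
                removed = frag.removed_bonds | {b}
                comps = split(frag.atoms, removed)
                if len(comps) == 2:
                    for comp in comps:
                        emit(comp, removed, frag.bond_energy + bond_cost[b])
            n = len(ring_bonds)
            for x in range(n):
                for y in range(x + 1, n):
                    b1, b2 = ring_bonds[x], ring_bonds[y]
                    removed = frag.removed_bonds | {b1, b2}
                    comps = split(frag.atoms, removed)
                    if len(comps) == 2:
                        cost = frag.bond_energy + bond_cost[b1] + bond_cost[b2]
                        for comp in comps:
                            emit(comp, removed, cost)
        for atom_set, frag in children.items():
            prev = best.get(atom_set)
            if prev is None or frag.bond_energy < prev.bond_energy:
                best[atom_set] = frag
        frontier = list(children.values())
        if not frontier:
            break
    return sorted(best.values(), key=lambda f: f.sort_key())


def ion_mass(neutral_mass: float, polarity: str, adduct_shift: float | None = None) -> float:
    """Adduct-adjusted ion m/z: protonation (+H) in positive mode,
    deprotonation (-H) in negative mode, unless an explicit shift is given."""
    if adduct_shift is not None:
        return neutral_mass + adduct_shift
    if polarity == "positive":
        return neutral_mass + PROTON_MASS
    if polarity == "negative":
        return neutral_mass - PROTON_MASS
    raise ValueError(f"unknown polarity {polarity!r}")


def assign_peaks(s: Spectrum, frags: Sequence[FragmentStructure], mzabs: float,
                 mzppm: float, polarity: str | None = None,
                 adduct_shift: float | None = None) -> list[PeakAssignment]:
    """Assign each peak to the best-matching fragment, or to ⊥ (None).

    The fragment whose adduct-adjusted mass is closest to the peak m/z
    within ``mzabs + mzppm*mz/1e6`` wins; exact-distance ties go to the
    fragment with the smaller broken-bond energy. The result is independent
    of the input fragment order.
    """
    if mzabs < 0 or mzppm < 0:
        raise ValueError("tolerances must be non-negative")
    polarity = polarity or s.polarity
    scored = sorted(((ion_mass(f.formula_mass, polarity, adduct_shift), f) for f in frags),
                    key=lambda t: (t[0], t[1].sort_key()))
    out: list[PeakAssignment] = []
    for peak in s.peaks:
        tol = mzabs + mzppm * peak.mz / 1e6
        hit: tuple[float, float, FragmentStructure] | None = None
        for ion_mz, f in scored:
            d = abs(ion_mz - peak.mz)
            if d <= tol and (hit is None or (d, f.bond_energy) < (hit[0], hit[1])):
                hit = (d, f.bond_energy, f)
        if hit is None:
            out.append(PeakAssignment(peak=peak, fragment=None))
        else:
            f = hit[2]
            out.append(PeakAssignment(
                peak=peak, fragment=f,
                theoretical_mz=ion_mass(f.formula_mass, polarity, adduct_shift)))
    return out


def compute_losses(assignments: Sequence[PeakAssignment],
                   bottom_pairs: bool = False) -> list[LossAssignment]:
    """Neutral-loss assignments from all ordered peak pairs of one candidate.

    For peaks k, h with m_k > m_h and both assigned real fragments, the loss
    structure is f_k minus f_h's atoms and bonds. It is emitted only when
    f_h is a genuine proper substructure of f_k (atom-index subset — both
    fragments share the parent's indexing) and the difference is connected.
    With ``bottom_pairs`` (query-time option) pairs of annotated peaks whose
    difference fails those conditions yield a ⊥ loss.
    """
    real = [(a.peak.mz, a.fragment) for a in assignments if a.fragment is not None]
    out: list[LossAssignment] = []
    for mk, fk in real:
        for mh, fh in real:
            if mk <= mh:
                continue
            loss = mk - mh
            frag = _difference_fragment(fk, fh)
            if frag is not None:
                out.append(LossAssignment(loss_mz=loss, fragment=frag))
            elif bottom_pairs:
                out.append(LossAssignment(loss_mz=loss, fragment=None))
    return out


def _difference_fragment(fk: FragmentStructure,
                         fh: FragmentStructure) -> FragmentStructure | None:
    if not (fh.atoms < fk.atoms):
        return None
    diff_atoms = fk.atoms - fh.atoms
    # connectivity of the difference within f_k's present bonds
    adjacency: dict[int, list[tuple[int, int]]] = {a: [] for a in diff_atoms}
    present = set(fk.present_bonds())
    parent = fk.parent
    for bidx in present:
        b = parent.GetBondWithIdx(bidx)
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in diff_atoms and j in diff_atoms:
            adjacency[i].append((j, bidx))
            adjacency[j].append((i, bidx))
    comps = _components(diff_atoms, adjacency, frozenset())
    if len(comps) != 1:
        return None
    return FragmentStructure(parent=parent, atoms=diff_atoms,
                             removed_bonds=frozenset(b for b in fk.removed_bonds
                                                     if parent.GetBondWithIdx(b).GetBeginAtomIdx() in diff_atoms
                                                     and parent.GetBondWithIdx(b).GetEndAtomIdx() in diff_atoms),
                             bond_energy=fk.bond_energy, depth=fk.depth)


# ---------------------------------------------------------------------------
# Fragmenter score (simplified, pluggable stand-in)
# ---------------------------------------------------------------------------

def fragmenter_raw_score(assignments: Sequence[PeakAssignment], s: Spectrum,
                         lam: float = 0.2) -> float:
    """Raw combinatorial-fragmenter score of one candidate.

    Sums ``rel_intensity**0.6 * (mz/precursor_mz)**3`` over explained peaks,
    discounted by a saturating broken-bond-energy penalty (``lam`` caps the
    discount fraction). Intensity enters only relatively, so the score is
    invariant to uniform intensity scaling. This is a deliberately simple
    scoring rule exposing the same contract (non-negative raw value,
    normalized to [0, 1] across the candidate list) as MetFrag's native
    fragmenter score; it is pluggable wherever a candidate-level fragmenter
    score is consumed.
    """
    if not 0 <= lam <= 1:
        raise ValueError("lam must be in [0, 1]")
    max_int = max(p.intensity for p in s.peaks)
    if max_int <= 0:
        return 0.0
    total = 0.0
    energy = 0.0
    for a in assignments:
        if a.fragment is None:
            continue
        rel = a.peak.intensity / max_int
        total += rel ** 0.6 * (a.peak.mz / s.precursor_mz) ** 3
        energy += a.fragment.bond_energy
    return total * (1.0 - lam * energy / (1.0 + energy))


def fragmenter_scores(per_candidate: Sequence[Sequence[PeakAssignment]], s: Spectrum,
                      lam: float = 0.2) -> list[float]:
    """Normalized fragmenter scores across a candidate list (max maps to 1)."""
    raws = [fragmenter_raw_score(a, s, lam) for a in per_candidate]
    top = max(raws, default=0.0)
    if top <= 0:
        return [0.0 for _ in raws]
    return [r / top for r in raws]
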
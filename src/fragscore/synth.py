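"""Synthetic molecules, spectra, and benchmark sets.

Generates small connected C/N/O molecules, simulates centroided MS/MS
spectra from their own bond-disconnection fragments (with ppm jitter,
fragment dropout, and spurious noise peaks), and assembles train/query
benchmarks with mass-matched decoy candidates — so the entire
train → score → rank path runs with no external data.

The peak intensities are synthetic draws: the annotation model itself uses
intensity only for the top-40 reduction and the fragmenter score, so a
simple exponential (or uniform) intensity model suffices. Real spectra
additionally carry instrument-specific intensity structure, rearrangement
peaks, and adduct/isotope patterns that these fixtures deliberately omit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .fragmentation import fragment_candidate, ion_mass
from .spectra import Candidate, Peak, Spectrum, reduce_to_top_peaks

__all__ = ["FixtureSpec", "Benchmark", "generate_molecules",
           "simulate_spectrum", "make_benchmark"]

_VALENCE = {"C": 4, "N": 3, "O": 2}
_ELEMENTS = ("C", "N", "O")
_ELEMENT_P = (0.70, 0.15, 0.15)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions of a synthetic benchmark; ``seed`` fixes everything."""

    n_molecules: int = 30
    n_replicates: int = 3  # spectra per training molecule (replicate acquisitions)
    n_queries: int = 10
    n_decoys_per_query: int = 20
    peak_jitter_ppm: float = 5.0
    intensity_model: str = "exponential"  # or "uniform"
    dropout_rate: float = 0.10
    noise_peaks: int = 3
    mass_window: float = 50.0  # Da around the query precursor for decoys
    max_decoy_overlap: float = 0.6  # max fraction of true peaks a decoy may explain
    decoy_pool_size: int = 150
    max_depth: int = 2
    polarity: str = "positive"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.intensity_model not in ("uniform", "exponential"):
            raise ValueError(f"unknown intensity model {self.intensity_model!r}")


@dataclass
class Benchmark:
    """A self-contained train/query data set."""

    train_spectra: list[Spectrum]
    train_candidates: dict[str, list[Candidate]]
    query_spectra: list[Spectrum]
    query_candidates: dict[str, list[Candidate]]


#: building blocks shared by every generated molecule. Assembling molecules
#: from a small motif alphabet makes fragment vocabulary recur across
#: molecules — emulating the recurring substructures of real metabolite
#: space, and ensuring that held-out molecules produce fragments the
#: annotation model has seen during training.
_MOTIFS = ("CCO", "CCN", "CCC", "CC(C)C", "COC", "CC(N)C", "CC(C)O",
           "C1CCCC1", "C1CCOC1")


def _free_valence_sites(mol: Chem.Mol) -> list[int]:
    out = []
    for atom in mol.GetAtoms():
        used = sum(int(b.GetBondTypeAsDouble()) for b in atom.GetBonds())
        if _VALENCE.get(atom.GetSymbol(), 0) - used > 0:
            out.append(atom.GetIdx())
    return out


def _random_molecule(rng: np.random.Generator) -> Chem.Mol | None:
    """Assemble a connected C/N/O molecule (4-12 heavy atoms) by joining
    2-3 motifs from the shared alphabet with single bonds."""
    n_motifs = int(rng.integers(2, 4))
    mol = Chem.MolFromSmiles(str(rng.choice(_MOTIFS)))
    for _ in range(n_motifs - 1):
        part = Chem.MolFromSmiles(str(rng.choice(_MOTIFS)))
        if mol.GetNumAtoms() + part.GetNumAtoms() > 12:
            break
        combined = Chem.RWMol(Chem.CombineMols(mol, part))
        offset = mol.GetNumAtoms()
        left = [i for i in _free_valence_sites(combined) if i < offset]
        right = [i for i in _free_valence_sites(combined) if i >= offset]
        if not left or not right:
            return None
        combined.AddBond(int(rng.choice(left)), int(rng.choice(right)),
                         Chem.BondType.SINGLE)
        mol = combined.GetMol()
        if Chem.SanitizeMol(mol, catchErrors=True) != Chem.SanitizeFlags.SANITIZE_NONE:
            return None
    if not 4 <= mol.GetNumAtoms() <= 12:
        return None
    return mol


def generate_molecules(n: int, seed: int | np.random.Generator,
                       exclude_blocks: set[str] | None = None) -> list[Candidate]:
    """Generate ``n`` connected molecules with pairwise distinct InChIKey
    first blocks (optionally also distinct from ``exclude_blocks``)."""
    if n < 1:
        raise ValueError("need n >= 1 molecules")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: list[Candidate] = []
    blocks = set(exclude_blocks or ())
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("molecule generation failed to converge")
        mol = _random_molecule(rng)
        if mol is None:
            continue
        key = Chem.MolToInchiKey(mol)
        block1 = key.split("-")[0]
        if block1 in blocks:
            continue
        blocks.add(block1)
        out.append(Candidate(
            id=f"mol{len(out):04d}_{block1[:6]}",
            structure=mol,
            monoisotopic_mass=Descriptors.ExactMolWt(mol),
            inchikey_block1=block1,
            smiles=Chem.MolToSmiles(mol),
        ))
    return out


def simulate_spectrum(c: Candidate, spec: FixtureSpec,
                      rng: np.random.Generator | None = None,
                      spectrum_id: str | None = None) -> Spectrum:
    """Simulate a centroided MS/MS spectrum from a candidate's own fragments.

    Every depth-``max_depth`` fragment surviving dropout becomes a peak at
    its adduct-adjusted mass with multiplicative ppm jitter; spurious noise
    peaks are added uniformly over the mass range; the spectrum is reduced
    to its 40 most intense peaks.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    frags = fragment_candidate(c, spec.max_depth)
    masses = sorted({round(ion_mass(f.formula_mass, spec.polarity), 6)
                     for f in frags})
    if not masses:
        raise ValueError(f"candidate {c.id!r} produced no fragments")
    keep = [m for m in masses if rng.random() >= spec.dropout_rate]
    if not keep:  # never emit an empty spectrum
        keep = [masses[int(rng.integers(len(masses)))]]

    def intensity() -> float:
        if spec.intensity_model == "uniform":
            return float(rng.uniform(0.1, 1.0))
        return float(rng.exponential(1.0)) + 1e-3

    precursor = ion_mass(c.monoisotopic_mass, spec.polarity)
    peaks = [Peak(m * (1.0 + rng.uniform(-spec.peak_jitter_ppm,
                                         spec.peak_jitter_ppm) * 1e-6),
                  intensity()) for m in keep]
    lo, hi = min(keep), precursor
    for _ in range(spec.noise_peaks):
        peaks.append(Peak(float(rng.uniform(lo, hi)), intensity()))
    s = Spectrum(
        peaks=tuple(sorted(peaks, key=lambda p: p.mz)),
        precursor_mz=precursor,
        polarity=spec.polarity,
        id=spectrum_id or f"sim_{c.id}",
        inchikey=f"{c.inchikey_block1}-UHFFFAOYSA-N",
        source="synthetic",
    )
    return reduce_to_top_peaks(s, 40)


def _peak_overlap(spectrum: Spectrum, decoy: Candidate, spec: FixtureSpec,
                  frag_cache: dict) -> float:
    """Fraction of the spectrum's peaks within tolerance of any decoy
    fragment ion mass."""
    if decoy.id not in frag_cache:
        frag_cache[decoy.id] = np.array(sorted(
            {ion_mass(f.formula_mass, spec.polarity)
             for f in fragment_candidate(decoy, spec.max_depth)}))
    masses = frag_cache[decoy.id]
    hits = 0
    for p in spectrum.peaks:
        tol = 0.005 + 2 * spec.peak_jitter_ppm * p.mz / 1e6
        i = int(np.searchsorted(masses, p.mz))
        near = [masses[j] for j in (i - 1, i) if 0 <= j < len(masses)]
        if any(abs(m - p.mz) <= tol for m in near):
            hits += 1
    return hits / len(spectrum.peaks)


def _pick_decoys(query: Candidate, spectrum: Spectrum, pool: Sequence[Candidate],
                 spec: FixtureSpec, rng: np.random.Generator,
                 frag_cache: dict) -> list[Candidate]:
    """Mass-matched decoys that cannot explain more than
    ``spec.max_decoy_overlap`` of the query's peaks (the separability
    guarantee of the benchmark); least-overlapping decoys fill any gap."""
    n = spec.n_decoys_per_query
    eligible = [c for c in pool if c.inchikey_block1 != query.inchikey_block1]
    in_window = [c for c in eligible
                 if abs(c.monoisotopic_mass - query.monoisotopic_mass)
                 <= spec.mass_window]
    if len(in_window) < n:
        in_window = sorted(eligible, key=lambda c: abs(c.monoisotopic_mass
                                                       - query.monoisotopic_mass))[:max(n, len(in_window))]
    overlaps = {c.id: _peak_overlap(spectrum, c, spec, frag_cache)
                for c in in_window}
    separable = [c for c in in_window if overlaps[c.id] <= spec.max_decoy_overlap]
    if len(separable) >= n:
        idx = rng.choice(len(separable), size=n, replace=False)
        return [separable[i] for i in sorted(idx)]
    rest = sorted((c for c in in_window if c not in separable),
                  key=lambda c: (overlaps[c.id], c.id))
    return separable + rest[:n - len(separable)]


def make_benchmark(spec: FixtureSpec) -> Benchmark:
    """Build a complete benchmark: labelled training spectra with candidate
    lists (correct + decoys) and held-out query spectra whose candidate
    lists contain the planted correct molecule exactly once."""
    rng = np.random.default_rng(spec.seed)
    train_mols = generate_molecules(spec.n_molecules, rng)
    train_blocks = {c.inchikey_block1 for c in train_mols}
    query_mols = generate_molecules(spec.n_queries, rng,
                                    exclude_blocks=train_blocks)
    all_blocks = train_blocks | {c.inchikey_block1 for c in query_mols}
    pool = generate_molecules(spec.decoy_pool_size, rng,
                              exclude_blocks=all_blocks)

    frag_cache: dict = {}
    train_spectra, train_candidates = [], {}
    for c in train_mols:
        for r in range(spec.n_replicates):
            s = simulate_spectrum(c, spec, rng, spectrum_id=f"sim_{c.id}_r{r}")
            train_spectra.append(s)
            decoys = _pick_decoys(c, s, pool, spec, rng, frag_cache)
            train_candidates[s.id] = [c] + decoys

    query_spectra, query_candidates = [], {}
    for c in query_mols:
        s = simulate_spectrum(c, spec, rng)
        query_spectra.append(s)
        decoys = _pick_decoys(c, s, pool, spec, rng, frag_cache)
        query_candidates[s.id] = [c] + decoys
    return Benchmark(train_spectra=train_spectra,
                     train_candidates=train_candidates,
                     query_spectra=query_spectra,
                     query_candidates=query_candidates)
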
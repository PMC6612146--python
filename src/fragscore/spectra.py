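"""Spectrum and candidate I/O, replicate merging, and peak-count reduction.

Centroided MS/MS spectra are read from MGF or MSP peak lists. Replicate
spectra of one molecule are merged by grouping peaks that fall within the
instrument tolerance window, averaging their m/z and retaining the maximum
intensity. Spectra are then reduced to their most abundant peaks (40 by
default) to bound the spectral complexity seen by the annotation model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "Peak",
    "Spectrum",
    "Candidate",
    "read_spectra",
    "write_mgf",
    "merge_spectra",
    "reduce_to_top_peaks",
    "read_candidates",
    "write_candidates",
    "candidate_from_smiles",
]


@dataclass(frozen=True)
class Peak:
    """A centroided fragment peak: m/z in Da, intensity in arbitrary units."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be non-negative, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS/MS measurement.

    Peaks are kept sorted by ascending m/z. ``inchikey`` carries the
    correct-candidate label (full InChIKey) for training spectra and is
    ``None`` for unlabelled queries. ``source`` identifies the originating
    library/institution and participates in the default merge grouping.
    """

    peaks: tuple[Peak, ...]
    precursor_mz: float
    polarity: str  # "positive" | "negative"
    id: str
    inchikey: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if len(self.peaks) < 1:
            raise ValueError(f"spectrum {self.id!r} has no peaks")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be 'positive' or 'negative', got {self.polarity!r}")
        mzs = [p.mz for p in self.peaks]
        if mzs != sorted(mzs):
            object.__setattr__(self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz)))

    @property
    def inchikey_block1(self) -> str | None:
        return self.inchikey.split("-")[0] if self.inchikey else None

    @property
    def mzs(self) -> list[float]:
        return [p.mz for p in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [p.intensity for p in self.peaks]


@dataclass(frozen=True)
class Candidate:
    """A database candidate molecule for a query spectrum.

    Construction is permissive about structure quality (database exports
    contain salts and isotope-labelled entries); use
    :func:`fragscore.ranking.filter_candidates` to drop disconnected or
    isotope-labelled candidates before scoring.
    """

    id: str
    structure: Chem.Mol = field(compare=False)
    monoisotopic_mass: float
    inchikey_block1: str
    smiles: str = ""

    def __post_init__(self) -> None:
        if len(self.inchikey_block1) != 14 or not self.inchikey_block1.isalpha():
            raise ValueError(f"candidate {self.id!r}: invalid InChIKey first block "
                             f"{self.inchikey_block1!r}")


def candidate_from_smiles(smiles: str, cid: str) -> Candidate:
    """Build a Candidate from a SMILES string, deriving mass and InChIKey."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"candidate {cid!r}: unparseable SMILES {smiles!r}")
    key = Chem.MolToInchiKey(mol)
    return Candidate(
        id=cid,
        structure=mol,
        monoisotopic_mass=Descriptors.ExactMolWt(mol),
        inchikey_block1=key.split("-")[0],
        smiles=Chem.MolToSmiles(mol),
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_POLARITY_ALIASES = {
    "positive": "positive", "pos": "positive", "p": "positive", "+": "positive",
    "1+": "positive", "1": "positive",
    "negative": "negative", "neg": "negative", "n": "negative", "-": "negative",
    "1-": "negative", "-1": "negative",
}


def _normalize_polarity(raw: str | None, override: str | None, where: str) -> str:
    if override is not None:
        return _POLARITY_ALIASES[override.lower()]
    if raw is None:
        raise ValueError(f"{where}: polarity missing and no override given")
    key = str(raw).strip().lower()
    if key not in _POLARITY_ALIASES:
        raise ValueError(f"{where}: unrecognized polarity {raw!r}")
    return _POLARITY_ALIASES[key]


def read_spectra(path: str | Path, format: str | None = None, *,
                 polarity: str | None = None) -> list[Spectrum]:
    """Read spectra from an MGF or MSP file.

    ``format`` defaults to the file extension. ``polarity`` overrides (or
    supplies, when the file lacks it) the ionization mode for every record.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mgf":
        return _read_mgf(path, polarity)
    if fmt == "msp":
        return _read_msp(path, polarity)
    raise ValueError(f"unknown spectrum format {fmt!r}")


def _read_mgf(path: Path, polarity: str | None) -> list[Spectrum]:
    from pyteomics import mgf

    out: list[Spectrum] = []
    with mgf.MGF(str(path)) as reader:
        it = iter(reader)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:  # pyteomics raises on malformed peak lines
                raise ValueError(f"malformed MGF record {i} in {path}: {exc}") from exc
            params = rec.get("params", {})
            try:
                mzs = rec["m/z array"]
                ints = rec["intensity array"]
                if mzs is None or len(mzs) == 0:
                    raise ValueError("no peaks")
                pepmass = params["pepmass"][0]
                charge = params.get("charge")
                raw_pol = params.get("ionmode") or params.get("polarity")
                if raw_pol is None and charge:
                    raw_pol = "positive" if int(charge[0]) > 0 else "negative"
                pol = _normalize_polarity(raw_pol, polarity, f"MGF record {i}")
                peaks = tuple(Peak(float(m), float(x)) for m, x in zip(mzs, ints))
                out.append(Spectrum(
                    peaks=peaks,
                    precursor_mz=float(pepmass),
                    polarity=pol,
                    id=str(params.get("title", f"{path.stem}_{i}")),
                    inchikey=params.get("inchikey"),
                    source=params.get("source"),
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed MGF record {i} in {path}: {exc}") from exc
            i += 1
    return out


def _read_msp(path: Path, polarity: str | None) -> list[Spectrum]:
    from matchms.importing import load_from_msp

    out: list[Spectrum] = []
    for i, sp in enumerate(load_from_msp(str(path), metadata_harmonization=True)):
        if sp is None:
            raise ValueError(f"malformed MSP record {i} in {path}")
        meta = sp.metadata
        prec = meta.get("precursor_mz") or meta.get("precursormz")
        if prec is None:
            raise ValueError(f"malformed MSP record {i} in {path}: no precursor m/z")
        pol = _normalize_polarity(meta.get("ionmode"), polarity, f"MSP record {i}")
        peaks = tuple(Peak(float(m), float(x))
                      for m, x in zip(sp.peaks.mz, sp.peaks.intensities))
        out.append(Spectrum(
            peaks=peaks,
            precursor_mz=float(prec),
            polarity=pol,
            id=str(meta.get("compound_name") or meta.get("name") or f"{path.stem}_{i}"),
            inchikey=meta.get("inchikey"),
            source=meta.get("source"),
        ))
    return out


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF (round-trips through :func:`read_spectra`)."""
    lines: list[str] = []
    for s in spectra:
        lines.append("BEGIN IONS")
        lines.append(f"TITLE={s.id}")
        lines.append(f"PEPMASS={s.precursor_mz:.6f}")
        lines.append("CHARGE=1+" if s.polarity == "positive" else "CHARGE=1-")
        lines.append(f"IONMODE={s.polarity}")
        if s.inchikey:
            lines.append(f"INCHIKEY={s.inchikey}")
        if s.source:
            lines.append(f"SOURCE={s.source}")
        for p in s.peaks:
            lines.append(f"{p.mz:.6f} {p.intensity:.6f}")
        lines.append("END IONS")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_candidates(path: str | Path) -> list[Candidate]:
    """Read a candidate list from TSV with columns
    id, smiles_or_inchi, monoisotopic_mass, inchikey."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "smiles_or_inchi", "monoisotopic_mass", "inchikey"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: candidate TSV missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        struct = row.smiles_or_inchi
        mol = (Chem.MolFromInchi(struct) if struct.startswith("InChI=")
               else Chem.MolFromSmiles(struct))
        if mol is None:
            raise ValueError(f"{path}: unparseable structure for candidate {row.id!r}")
        out.append(Candidate(
            id=str(row.id),
            structure=mol,
            monoisotopic_mass=float(row.monoisotopic_mass),
            inchikey_block1=str(row.inchikey).split("-")[0],
            smiles=Chem.MolToSmiles(mol),
        ))
    return out


def write_candidates(cands: Sequence[Candidate], path: str | Path) -> None:
    lines = ["id\tsmiles_or_inchi\tmonoisotopic_mass\tinchikey"]
    for c in cands:
        lines.append(f"{c.id}\t{c.smiles or Chem.MolToSmiles(c.structure)}\t"
                     f"{c.monoisotopic_mass:.6f}\t{c.inchikey_block1}-UHFFFAOYSA-N")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Merging and reduction
# ---------------------------------------------------------------------------

def merge_spectra(spectra: Sequence[Spectrum], mzabs: float, mzppm: float) -> Spectrum:
    """Merge replicate spectra of one molecule into a consensus spectrum.

    All peaks are pooled and grouped greedily in ascending m/z: the group
    seed is the lowest unassigned m/z, and every peak within
    ``2 * (mzabs + mzppm * seed / 1e6)`` of the seed joins the group. Each
    group contributes one peak at the group's mean m/z carrying the group's
    maximum intensity. The operation is idempotent.
    """
    if not spectra:
        raise ValueError("merge_spectra needs at least one spectrum")
    polarities = {s.polarity for s in spectra}
    if len(polarities) > 1:
        raise ValueError(f"cannot merge spectra of mixed polarity: {sorted(polarities)}")
    pooled = sorted((p for s in spectra for p in s.peaks), key=lambda p: p.mz)

    def one_pass(peaks: list[Peak]) -> list[Peak]:
        merged: list[Peak] = []
        i = 0
        while i < len(peaks):
            seed = peaks[i].mz
            window = 2.0 * (mzabs + mzppm * seed / 1e6)
            j = i
            while j < len(peaks) and peaks[j].mz - seed <= window:
                j += 1
            group = peaks[i:j]
            merged.append(Peak(
                mz=math.fsum(p.mz for p in group) / len(group),
                intensity=max(p.intensity for p in group),
            ))
            i = j
        return merged

    # iterate to a fixpoint: group means can themselves fall within one
    # window, and the merge must be idempotent
    merged = one_pass(pooled)
    while True:
        again = one_pass(merged)
        if len(again) == len(merged):
            break
        merged = again
    base = spectra[0]
    return replace(base, peaks=tuple(merged))


def reduce_to_top_peaks(s: Spectrum, k: int = 40) -> Spectrum:
    """Keep the ``k`` most intense peaks (ties broken toward lower m/z)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(s.peaks) <= k:
        return s
    # stable sort on (-intensity, mz) keeps the lower-mz peak at the cutoff
    chosen = sorted(s.peaks, key=lambda p: (-p.intensity, p.mz))[:k]
    return replace(s, peaks=tuple(sorted(chosen, key=lambda p: p.mz)))
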
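"""Molecular fingerprints defining fragment-structure equality.

Comparing fragment-structures by graph isomorphism is too expensive when
hundreds of thousands of fragments are generated, so every fragment is
mapped to a fixed-length bit string and two fragments are considered equal
iff their fingerprints are identical. Structurally different fragments may
collide; that generalization is intentional — only the induced equivalence
classes matter to the annotation model.

Four backends cover the standard fingerprint roles:

``maccs``
    166 substructure keys (RDKit's MACCS implementation).
``circular``
    Morgan/ECFP-like radius-2 environments folded to 1024 bits.
``path_lingo``
    q-grams (default length 4) of the canonical SMILES hashed to 1024 bits.
``graph_only``
    path fingerprint of the bond-order-stripped skeleton (all bonds treated
    as single, aromaticity removed), hence blind to bond order — benzene
    and cyclohexane collide by construction.

The ``BOT`` sentinel represents "no fragment-structure assigned" and is
distinct from every real fingerprint.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

__all__ = ["Fingerprint", "BOT", "FINGERPRINT_FUNCTIONS", "compute_fingerprint",
           "fragments_equal", "fingerprint_from_mol"]

FINGERPRINT_FUNCTIONS = ("maccs", "circular", "path_lingo", "graph_only")

_FOLDED_LENGTH = 1024  # circular / path_lingo / graph_only folded size
_LINGO_Q = 4           # q-gram length for path_lingo


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit string; hashable so it can key count tables."""

    bits: bytes
    n_bits: int
    function_id: str

    @property
    def is_bot(self) -> bool:
        return self.function_id == "bot"

    def to_hex(self) -> str:
        return "BOT" if self.is_bot else self.bits.hex()

    @classmethod
    def from_hex(cls, s: str, n_bits: int, function_id: str) -> "Fingerprint":
        if s == "BOT":
            return BOT
        return cls(bits=bytes.fromhex(s), n_bits=n_bits, function_id=function_id)


#: sentinel for an unannotated peak or loss
BOT = Fingerprint(bits=b"", n_bits=0, function_id="bot")


def _bitvect_to_fp(bv, function_id: str) -> Fingerprint:
    n = bv.GetNumBits()
    raw = bytearray((n + 7) // 8)
    for i in bv.GetOnBits():
        raw[i // 8] |= 1 << (i % 8)
    return Fingerprint(bits=bytes(raw), n_bits=n, function_id=function_id)


def _lingo_fp(mol: Chem.Mol) -> Fingerprint:
    smi = Chem.MolToSmiles(mol)
    raw = bytearray(_FOLDED_LENGTH // 8)
    grams = {smi} if len(smi) < _LINGO_Q else \
        {smi[i:i + _LINGO_Q] for i in range(len(smi) - _LINGO_Q + 1)}
    for g in grams:
        h = int.from_bytes(hashlib.sha1(g.encode()).digest()[:8], "big")
        i = h % _FOLDED_LENGTH
        raw[i // 8] |= 1 << (i % 8)
    return Fingerprint(bits=bytes(raw), n_bits=_FOLDED_LENGTH, function_id="path_lingo")


def _strip_bond_orders(mol: Chem.Mol) -> Chem.Mol:
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetIsAromatic(False)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    out = rw.GetMol()
    Chem.SanitizeMol(out, catchErrors=True)
    return out


def fingerprint_from_mol(mol: Chem.Mol, function_id: str) -> Fingerprint:
    """Compute the fingerprint of an RDKit molecule under the named backend."""
    if function_id not in FINGERPRINT_FUNCTIONS:
        raise ValueError(f"unknown fingerprint function {function_id!r}; "
                         f"choose from {FINGERPRINT_FUNCTIONS}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError("fingerprint input must be a connected molecular graph")
    if function_id == "maccs":
        return _bitvect_to_fp(MACCSkeys.GenMACCSKeys(mol), "maccs")
    if function_id == "circular":
        gen = _morgan_generator()
        return _bitvect_to_fp(gen.GetFingerprint(mol), "circular")
    if function_id == "path_lingo":
        return _lingo_fp(mol)
    stripped = _strip_bond_orders(mol)
    gen = _rdkit_path_generator()
    return _bitvect_to_fp(gen.GetFingerprint(stripped), "graph_only")


_GEN_CACHE: dict = {}


def _morgan_generator():
    if "morgan" not in _GEN_CACHE:
        _GEN_CACHE["morgan"] = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=_FOLDED_LENGTH)
    return _GEN_CACHE["morgan"]


def _rdkit_path_generator():
    if "path" not in _GEN_CACHE:
        _GEN_CACHE["path"] = rdFingerprintGenerator.GetRDKitFPGenerator(
            fpSize=_FOLDED_LENGTH, useBondOrder=False)
    return _GEN_CACHE["path"]


def compute_fingerprint(fragment, function_id: str) -> Fingerprint:
    """Fingerprint of a fragment-structure (see :mod:`fragscore.fragmentation`)."""
    return fingerprint_from_mol(fragment.to_mol(), function_id)


def fragments_equal(f1: Fingerprint, f2: Fingerprint) -> bool:
    """Fragment equality = bitwise fingerprint identity; constant time."""
    if f1.is_bot or f2.is_bot:
        return f1.is_bot and f2.is_bot
    if f1.function_id != f2.function_id:
        raise ValueError(f"cannot compare fingerprints from different functions: "
                         f"{f1.function_id!r} vs {f2.function_id!r}")
    return f1.bits == f2.bits
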
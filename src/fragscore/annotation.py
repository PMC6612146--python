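"""Bayesian annotation model: count tables, estimators, and scoring terms.

The model learns, from annotated training spectra, how probable each
fragment-structure fingerprint is given a discretized m/z peak (and,
analogously, given a neutral-loss mass). Probabilities are mean-posterior
(MP) estimates under a product Dirichlet prior whose pseudo counts are
``alpha`` for real fingerprints and ``beta`` for the ⊥ outcome (an
unannotated peak). ⊥ is never observed in training (its count is fixed at
zero), so its probability mass comes entirely from ``beta`` — this is what
lets a query peak without any matching fragment still contribute a finite
likelihood.

Per-candidate scores: the raw score is the reciprocal of the negative
log-likelihood of the candidate's assignments; it is normalized across the
query's candidate list so the best candidate scores 1, and the consensus
score is a convex combination of the fragmenter score and the two
statistical (peak and loss) scores.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .binning import MassBinning, discretize
from .fingerprints import BOT, Fingerprint, compute_fingerprint
from .fragmentation import (LossAssignment, PeakAssignment, assign_peaks,
                            compute_losses, fragment_candidate, fragmenter_scores)
from .spectra import Candidate, Spectrum

__all__ = [
    "AssignmentTable", "CountTable", "HyperParams", "ScoreWeights",
    "AnnotationModel", "collect_counts", "estimate_ml", "estimate_mp",
    "raw_score", "normalize_scores", "consensus_score",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class AssignmentTable:
    """Discretized training assignments: (bin-center m/z or loss, fingerprint)."""

    kind: str  # "peak" | "loss"
    entries: tuple[tuple[float, Fingerprint], ...]

    def __post_init__(self) -> None:
        if self.kind not in ("peak", "loss"):
            raise ValueError(f"kind must be 'peak' or 'loss', got {self.kind!r}")
        if any(f.is_bot for _, f in self.entries):
            raise ValueError("training assignment tables must not contain ⊥ rows")


@dataclass
class CountTable:
    """Absolute assignment frequencies N[(bin, fingerprint)] with row totals.

    The ⊥ fingerprint is part of every row's outcome domain but its count is
    structurally zero. Bins or fingerprints first seen at query time are
    handled as zero-count lookups; the table itself is never mutated.
    """

    kind: str
    counts: dict[tuple[float, Fingerprint], int] = field(default_factory=dict)
    row_totals: dict[float, int] = field(default_factory=dict)
    domain_bins: set[float] = field(default_factory=set)
    domain_fps: set[Fingerprint] = field(default_factory=set)

    def count(self, m: float, f: Fingerprint) -> int:
        if f.is_bot:
            return 0
        return self.counts.get((m, f), 0)

    def row_total(self, m: float) -> int:
        return self.row_totals.get(m, 0)

    def n_real_fps(self, extra_fps: Iterable[Fingerprint] = ()) -> int:
        extra = {f for f in extra_fps if not f.is_bot}
        return len(self.domain_fps | extra)


def collect_counts(tables: Sequence[AssignmentTable],
                   binning: MassBinning | None = None) -> CountTable:
    """Tally assignment tables into a count table.

    All tables must share the kind; if ``binning`` is given every m/z value
    is checked to be one of its bin centers.
    """
    if not tables:
        raise ValueError("collect_counts needs at least one assignment table")
    kinds = {t.kind for t in tables}
    if len(kinds) > 1:
        raise ValueError(f"cannot mix assignment kinds {sorted(kinds)}")
    ct = CountTable(kind=tables[0].kind)
    for t in tables:
        for m, f in t.entries:
            if binning is not None and discretize(m, binning) != m:
                raise ValueError(f"assignment value {m} is not a bin center")
            ct.counts[(m, f)] = ct.counts.get((m, f), 0) + 1
            ct.row_totals[m] = ct.row_totals.get(m, 0) + 1
            ct.domain_bins.add(m)
            ct.domain_fps.add(f)
    return ct


@dataclass(frozen=True)
class HyperParams:
    """Dirichlet pseudo counts: alpha/beta for peaks, alpha_L/beta_L for losses."""

    alpha: float
    beta: float
    alpha_L: float
    beta_L: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "alpha_L", "beta_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"pseudo count {name} must be positive")

    def for_kind(self, kind: str) -> tuple[float, float]:
        return (self.alpha, self.beta) if kind == "peak" else (self.alpha_L, self.beta_L)


@dataclass(frozen=True)
class ScoreWeights:
    """Convex weights of (fragmenter, peak, loss) scores in the consensus."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("score weights must be non-negative")
        if abs(self.w1 + self.w2 + self.w3 - 1.0) > 1e-9:
            raise ValueError("score weights must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


def estimate_ml(ct: CountTable, m: float, f: Fingerprint) -> float:
    """Maximum-likelihood estimate N[m,f] / N[m,·]; undefined for empty rows."""
    total = ct.row_total(m)
    if total == 0:
        raise ValueError(f"ML estimate undefined: no observations in bin {m}")
    return ct.count(m, f) / total


def estimate_mp(ct: CountTable, hyper: HyperParams, m: float, f: Fingerprint,
                extra_fps: Iterable[Fingerprint] = ()) -> float:
    """Mean-posterior estimate (N + pseudo count) / sum(N' + pseudo counts).

    The outcome domain is the table's fingerprint domain, extended by
    ``extra_fps`` (query-time fingerprints) and by ``f`` itself when unseen,
    plus the ⊥ outcome. ⊥ carries pseudo count beta and zero observations.
    """
    alpha, beta = hyper.for_kind(ct.kind)
    extra = set(extra_fps)
    if not f.is_bot:
        extra.add(f)
    n_real = ct.n_real_fps(extra)
    denom = ct.row_total(m) + n_real * alpha + beta
    num = beta if f.is_bot else ct.count(m, f) + alpha
    return num / denom


def raw_score(assignments: Sequence[PeakAssignment | LossAssignment],
              ct: CountTable, hyper: HyperParams, binning: MassBinning,
              fingerprint_function: str,
              extra_fps: Iterable[Fingerprint] = ()) -> float:
    """Reciprocal negative log-likelihood of a candidate's assignments.

    Each assignment contributes log P(f̃ | bin(value)) under the MP
    estimates; the score is 1 / (-sum of logs). Larger is better. Values
    outside the binned range are scored as zero-count rows.
    """
    pairs = assignment_pairs(assignments, binning, fingerprint_function)
    return raw_score_from_pairs(pairs, ct, hyper, extra_fps)


def assignment_pairs(assignments: Sequence[PeakAssignment | LossAssignment],
                     binning: MassBinning, fingerprint_function: str,
                     ) -> list[tuple[float, Fingerprint]]:
    """Discretize assignments into (bin-center, fingerprint-or-⊥) pairs.

    Out-of-range masses keep their raw value (an implicit empty bin: any
    lookup yields zero counts, matching the lazy domain-extension rule).
    """
    pairs: list[tuple[float, Fingerprint]] = []
    for a in assignments:
        value = a.loss_mz if isinstance(a, LossAssignment) else a.peak.mz
        binned = discretize(value, binning) if binning.covers(value) else value
        fp = BOT if a.fragment is None else compute_fingerprint(a.fragment,
                                                                fingerprint_function)
        pairs.append((binned, fp))
    return pairs


def raw_score_from_pairs(pairs: Sequence[tuple[float, Fingerprint]], ct: CountTable,
                         hyper: HyperParams,
                         extra_fps: Iterable[Fingerprint] = ()) -> float:
    if not pairs:
        raise ValueError("raw score needs at least one assignment")
    extra = set(extra_fps)
    loglik = 0.0
    for m, f in pairs:
        loglik += math.log(estimate_mp(ct, hyper, m, f, extra))
    return 1.0 / -loglik


def normalize_scores(raw: Sequence[float]) -> list[float]:
    """Divide by the per-query maximum so the best candidate scores 1.

    An all-zero list maps to all zeros.
    """
    if not raw:
        raise ValueError("normalize_scores needs at least one candidate")
    if min(raw) < 0:
        raise ValueError("raw scores must be non-negative")
    top = max(raw)
    if top == 0:
        return [0.0 for _ in raw]
    return [r / top for r in raw]


def consensus_score(s_metfrag: float, s_peak: float, s_loss: float,
                    w: ScoreWeights) -> float:
    """Weighted consensus of the three [0, 1] scoring terms."""
    for name, s in (("fragmenter", s_metfrag), ("peak", s_peak), ("loss", s_loss)):
        if not 0.0 <= s <= 1.0 + 1e-12:
            raise ValueError(f"{name} score {s} outside [0, 1]")
    return w.w1 * s_metfrag + w.w2 * s_peak + w.w3 * s_loss


# ---------------------------------------------------------------------------
# The assembled model
# ---------------------------------------------------------------------------

@dataclass
class AnnotationModel:
    """Trained fragment-annotation scorer for one ionization mode."""

    peak_counts: CountTable
    loss_counts: CountTable
    hyper: HyperParams
    weights: ScoreWeights
    binning: MassBinning
    fingerprint_function: str
    polarity: str
    mzabs: float
    mzppm: float
    max_depth: int = 2
    loss_bottom_pairs: bool = False

    # -- scoring ------------------------------------------------------------

    def score_query(self, spectrum: Spectrum,
                    candidates: Sequence[Candidate]) -> pd.DataFrame:
        """Score every candidate of one query spectrum.

        Returns a DataFrame with columns candidate_id, inchikey_block1,
        s_metfrag, s_peak, s_loss, s_fin (unranked, input order preserved).
        """
        if not candidates:
            raise ValueError("score_query needs at least one candidate")
        per_peak: list[list[PeakAssignment]] = []
        per_loss: list[list[LossAssignment]] = []
        for cand in candidates:
            frags = fragment_candidate(cand, self.max_depth)
            assigns = assign_peaks(spectrum, frags, self.mzabs, self.mzppm,
                                   self.polarity)
            per_peak.append(assigns)
            per_loss.append(compute_losses(assigns, self.loss_bottom_pairs))

        peak_pairs = [assignment_pairs(a, self.binning, self.fingerprint_function)
                      for a in per_peak]
        loss_pairs = [assignment_pairs(a, self.binning, self.fingerprint_function)
                      for a in per_loss]
        # query-time domain extension: fingerprints of all candidates' assignments
        extra_peak = {f for pairs in peak_pairs for _, f in pairs if not f.is_bot}
        extra_loss = {f for pairs in loss_pairs for _, f in pairs if not f.is_bot}

        raw_peak = [raw_score_from_pairs(p, self.peak_counts, self.hyper, extra_peak)
                    for p in peak_pairs]
        raw_loss = [raw_score_from_pairs(p, self.loss_counts, self.hyper, extra_loss)
                    if p else 0.0 for p in loss_pairs]
        s_peak = normalize_scores(raw_peak)
        s_loss = normalize_scores(raw_loss)
        s_metfrag = fragmenter_scores(per_peak, spectrum)
        s_fin = [consensus_score(sm, sp, sl, self.weights)
                 for sm, sp, sl in zip(s_metfrag, s_peak, s_loss)]
        return pd.DataFrame({
            "candidate_id": [c.id for c in candidates],
            "inchikey_block1": [c.inchikey_block1 for c in candidates],
            "s_metfrag": s_metfrag,
            "s_peak": s_peak,
            "s_loss": s_loss,
            "s_fin": s_fin,
        })

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the model as versioned JSON + TSV count tables into a directory."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "binning": self.binning.to_dict(),
            "hyper": {"alpha": self.hyper.alpha, "beta": self.hyper.beta,
                      "alpha_L": self.hyper.alpha_L, "beta_L": self.hyper.beta_L},
            "weights": {"w1": self.weights.w1, "w2": self.weights.w2,
                        "w3": self.weights.w3},
            "fingerprint_function": self.fingerprint_function,
            "fingerprint_n_bits": next(iter(self.peak_counts.domain_fps)).n_bits
            if self.peak_counts.domain_fps else 0,
            "polarity": self.polarity,
            "mzabs": self.mzabs,
            "mzppm": self.mzppm,
            "max_depth": self.max_depth,
            "loss_bottom_pairs": self.loss_bottom_pairs,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=2))
        for name, ct in (("peak_counts.tsv", self.peak_counts),
                         ("loss_counts.tsv", self.loss_counts)):
            lines = ["bin_center\tfingerprint_hex\tcount"]
            for (m, f), n in sorted(ct.counts.items(),
                                    key=lambda kv: (kv[0][0], kv[0][1].to_hex())):
                lines.append(f"{m!r}\t{f.to_hex()}\t{n}")
            (path / name).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AnnotationModel":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version "
                             f"{meta['format_version']}")
        binning = MassBinning.from_dict(meta["binning"])
        fp_fn = meta["fingerprint_function"]
        n_bits = meta["fingerprint_n_bits"]

        def read_table(name: str, kind: str) -> CountTable:
            tables = []
            text = (path / name).read_text().splitlines()[1:]
            entries = []
            for line in text:
                m_s, hex_s, n_s = line.split("\t")
                fp = Fingerprint.from_hex(hex_s, n_bits, fp_fn)
                entries.extend([(float(m_s), fp)] * int(n_s))
            tables.append(AssignmentTable(kind=kind, entries=tuple(entries)))
            return collect_counts(tables)

        return cls(
            peak_counts=read_table("peak_counts.tsv", "peak"),
            loss_counts=read_table("loss_counts.tsv", "loss"),
            hyper=HyperParams(**meta["hyper"]),
            weights=ScoreWeights(**meta["weights"]),
            binning=binning,
            fingerprint_function=fp_fn,
            polarity=meta["polarity"],
            mzabs=meta["mzabs"],
            mzppm=meta["mzppm"],
            max_depth=meta["max_depth"],
            loss_bottom_pairs=meta["loss_bottom_pairs"],
        )

    def with_params(self, hyper: HyperParams | None = None,
                    weights: ScoreWeights | None = None) -> "AnnotationModel":
        return replace(self, hyper=hyper or self.hyper,
                       weights=weights or self.weights)
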
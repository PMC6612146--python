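"""Two-phase training of the annotation model.

Phase 1 collects assignment counts from training spectra paired with their
correct candidates only, after correcting each explained peak's m/z to the
theoretical mass of its assigned fragment (so spectra from instruments with
different mass accuracy land in the same bins). Phase 2 ranks the correct
candidate of held-out spectra against decoy candidates and optimizes the
Dirichlet pseudo counts by grid search (with multiplicative border
extension) and the consensus weights by uniform sampling on the simplex,
maximizing the number of Top1 ranks. Finally the counts are recomputed on
the full training set with the optimized parameters frozen.

The user-facing entry point is :class:`FragmentAnnotationModel`, whose
``fit`` returns a :class:`FragmentAnnotationResults` carrying the trained
:class:`~fragscore.annotation.AnnotationModel`, the optimization
trajectory, and a ``summary()`` table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (AnnotationModel, AssignmentTable, CountTable,
                         HyperParams, ScoreWeights, assignment_pairs,
                         collect_counts)
from .binning import MassBinning, build_binning, discretize
from .fingerprints import BOT, Fingerprint
from .fragmentation import (PeakAssignment, assign_peaks, compute_losses,
                            fragment_candidate, fragmenter_scores, ion_mass)
from .spectra import Candidate, Peak, Spectrum

__all__ = [
    "TrainingConfig",
    "split_by_inchikey",
    "phase1_collect",
    "sample_weights",
    "grid_search",
    "finalize_model",
    "FragmentAnnotationModel",
    "FragmentAnnotationResults",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the two-phase training procedure."""

    split_ratio: float = 0.70
    hyper_grid_init: tuple[float, ...] = (0.0025, 0.0005, 0.0001)
    extension_factor: float = 5.0
    stop_improvement: float = 0.01
    n_weight_samples: int = 1000
    max_decoys: int = 500
    max_depth: int = 2
    loss_bottom_pairs: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.extension_factor <= 1:
            raise ValueError("extension_factor must be > 1")


# ---------------------------------------------------------------------------
# Phase 1
# ---------------------------------------------------------------------------

def split_by_inchikey(spectra: Sequence[Spectrum], ratio: float,
                      seed: int) -> tuple[list[Spectrum], list[Spectrum]]:
    """Split spectra into two disjoint groups by InChIKey first block.

    The unique first blocks (in order of first appearance) are shuffled with
    ``seed``; the first ceil(ratio * U) blocks, with all their spectra, form
    the phase-1 group. No molecule appears on both sides.
    """
    blocks: list[str] = []
    seen = set()
    for s in spectra:
        if s.inchikey_block1 is None:
            raise ValueError(f"spectrum {s.id!r} has no InChIKey label")
        if s.inchikey_block1 not in seen:
            seen.add(s.inchikey_block1)
            blocks.append(s.inchikey_block1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    n1 = math.ceil(ratio * len(blocks))
    phase1_blocks = {blocks[i] for i in order[:n1]}
    g1 = [s for s in spectra if s.inchikey_block1 in phase1_blocks]
    g2 = [s for s in spectra if s.inchikey_block1 not in phase1_blocks]
    return g1, g2


def _corrected_assignments(spectrum: Spectrum, candidate: Candidate,
                           mzabs: float, mzppm: float,
                           max_depth: int) -> list[PeakAssignment]:
    """Assign peaks of a spectrum to its correct candidate's fragments and
    replace each explained peak's m/z by the theoretical ion mass."""
    frags = fragment_candidate(candidate, max_depth)
    assigns = assign_peaks(spectrum, frags, mzabs, mzppm, spectrum.polarity)
    corrected = []
    for a in assigns:
        if a.fragment is None:
            continue  # ⊥ observations are dropped: N_{m⊥} = 0
        corrected.append(PeakAssignment(
            peak=Peak(a.theoretical_mz, a.peak.intensity),
            fragment=a.fragment, theoretical_mz=a.theoretical_mz))
    return corrected


def raw_annotations(items: Sequence[tuple[Spectrum, Candidate]], mzabs: float,
                    mzppm: float, max_depth: int = 2,
                    precursor_check: bool = True,
                    ) -> tuple[list[tuple[float, "FragmentStructure"]],
                               list[tuple[float, "FragmentStructure"]]]:
    """Undiscretized (mass, fragment) peak and loss annotations of correct
    candidates; used both to size the binning and to fill the count tables."""
    peak_items: list = []
    loss_items: list = []
    for spectrum, candidate in items:
        if precursor_check:
            expected = ion_mass(candidate.monoisotopic_mass, spectrum.polarity)
            tol = 3 * (mzabs + mzppm * spectrum.precursor_mz / 1e6)
            if abs(expected - spectrum.precursor_mz) > tol:
                warnings.warn(f"spectrum {spectrum.id!r}: precursor m/z "
                              f"{spectrum.precursor_mz:.4f} inconsistent with "
                              f"candidate mass (expected {expected:.4f}); skipped")
                continue
        corrected = _corrected_assignments(spectrum, candidate, mzabs, mzppm,
                                           max_depth)
        for a in corrected:
            peak_items.append((a.peak.mz, a.fragment))
        for l in compute_losses(corrected):
            loss_items.append((l.loss_mz, l.fragment))
    return peak_items, loss_items


def phase1_collect(items: Sequence[tuple[Spectrum, Candidate]],
                   binning: MassBinning, fingerprint_function: str,
                   mzabs: float, mzppm: float, max_depth: int = 2,
                   ) -> tuple[AssignmentTable, AssignmentTable]:
    """Build the discretized peak and loss assignment tables from training
    spectra paired with their correct candidates."""
    from .fingerprints import compute_fingerprint

    peak_items, loss_items = raw_annotations(items, mzabs, mzppm, max_depth)
    peak_entries = tuple((discretize(m, binning),
                          compute_fingerprint(f, fingerprint_function))
                         for m, f in peak_items if binning.covers(m))
    loss_entries = tuple((discretize(m, binning),
                          compute_fingerprint(f, fingerprint_function))
                         for m, f in loss_items if binning.covers(m))
    return (AssignmentTable(kind="peak", entries=peak_entries),
            AssignmentTable(kind="loss", entries=loss_entries))


# ---------------------------------------------------------------------------
# Phase 2: weight sampling and grid search
# ---------------------------------------------------------------------------

def sample_weights(n: int, seed: int | np.random.Generator) -> list[ScoreWeights]:
    """Draw ``n`` weight triples uniformly on the 2-simplex (Dirichlet(1,1,1))."""
    if n < 1:
        raise ValueError("need n >= 1 weight samples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.dirichlet([1.0, 1.0, 1.0], size=n)
    return [ScoreWeights(*map(float, row)) for row in w]


@dataclass
class _QueryCache:
    """Per-(query, candidate) sufficient statistics for fast re-scoring."""

    correct_idx: int
    s_metfrag: np.ndarray                  # (C,)
    peak_stats: list[tuple[np.ndarray, np.ndarray, np.ndarray]]  # per cand: N, Nrow, bot
    loss_stats: list[tuple[np.ndarray, np.ndarray, np.ndarray] | None]
    n_fps_peak: int                        # |F̃| incl. query extension, real only
    n_fps_loss: int


def _pair_stats(pairs, ct: CountTable):
    if not pairs:
        return None
    n = np.array([ct.count(m, f) for m, f in pairs], dtype=float)
    nrow = np.array([ct.row_total(m) for m, f in pairs], dtype=float)
    bot = np.array([f.is_bot for _, f in pairs], dtype=bool)
    return n, nrow, bot


def _build_query_cache(spectrum: Spectrum, candidates: Sequence[Candidate],
                       correct_idx: int, peak_counts: CountTable,
                       loss_counts: CountTable, binning: MassBinning,
                       fingerprint_function: str, mzabs: float, mzppm: float,
                       max_depth: int, loss_bottom_pairs: bool) -> _QueryCache:
    per_peak, peak_pairs, loss_pairs = [], [], []
    for cand in candidates:
        frags = fragment_candidate(cand, max_depth)
        assigns = assign_peaks(spectrum, frags, mzabs, mzppm, spectrum.polarity)
        per_peak.append(assigns)
        peak_pairs.append(assignment_pairs(assigns, binning, fingerprint_function))
        loss_pairs.append(assignment_pairs(
            compute_losses(assigns, loss_bottom_pairs), binning,
            fingerprint_function))
    extra_peak = {f for pairs in peak_pairs for _, f in pairs if not f.is_bot}
    extra_loss = {f for pairs in loss_pairs for _, f in pairs if not f.is_bot}
    return _QueryCache(
        correct_idx=correct_idx,
        s_metfrag=np.array(fragmenter_scores(per_peak, spectrum)),
        peak_stats=[_pair_stats(p, peak_counts) for p in peak_pairs],
        loss_stats=[_pair_stats(p, loss_counts) for p in loss_pairs],
        n_fps_peak=peak_counts.n_real_fps(extra_peak),
        n_fps_loss=loss_counts.n_real_fps(extra_loss),
    )


def _raw_scores_for_grid(stats, n_fps: int, alphas: np.ndarray,
                         betas: np.ndarray) -> np.ndarray:
    """Raw 1/-loglik for one candidate on a vector of (alpha, beta) pairs."""
    if stats is None:
        return np.zeros(len(alphas))
    n, nrow, bot = stats
    a = alphas[:, None]
    b = betas[:, None]
    denom = nrow[None, :] + n_fps * a + b
    num = np.where(bot[None, :], b, n[None, :] + a)
    loglik = np.sum(np.log(num) - np.log(denom), axis=1)
    return 1.0 / -loglik


def _normalize_rows(raw: np.ndarray) -> np.ndarray:
    """Normalize each row (hyper pair) of a (H, C) raw-score array to [0, 1]."""
    top = raw.max(axis=1, keepdims=True)
    out = np.zeros_like(raw)
    np.divide(raw, top, out=out, where=top > 0)
    return out


def grid_search(queries: Sequence[_QueryCache], config: TrainingConfig,
                weight_samples: Sequence[ScoreWeights],
                ) -> tuple[HyperParams, ScoreWeights, int, dict]:
    """Optimize pseudo counts and consensus weights by Top1 count.

    Evaluates every combination of the per-axis hyper-parameter grids with
    every sampled weight triple. If the optimum sits on the border of any
    axis, that axis is extended multiplicatively (x factor / x 1/factor) and
    the search repeats until the improvement falls below
    ``config.stop_improvement`` (relative) or no axis is on its border.
    Ties resolve to the lexicographically smallest hyper set, then the
    smallest w1.
    """
    if not queries:
        raise ValueError("grid search needs at least one phase-2 query")
    axes = {name: sorted(config.hyper_grid_init)
            for name in ("alpha", "beta", "alpha_L", "beta_L")}
    wmat = np.array([w.as_tuple() for w in weight_samples])  # (W, 3)

    evaluated: dict[tuple[float, float, float, float], tuple[int, int]] = {}
    log: dict = {"rounds": [], "initial_hyper_sets": 0, "initial_combinations": 0,
                 "total_hyper_sets": 0, "total_combinations": 0}

    def evaluate(combos: list[tuple[float, float, float, float]]) -> None:
        # share the per-(alpha, beta) score computation across combos
        ab_pairs = sorted({(c[0], c[1]) for c in combos})
        lb_pairs = sorted({(c[2], c[3]) for c in combos})
        ab_index = {p: i for i, p in enumerate(ab_pairs)}
        lb_index = {p: i for i, p in enumerate(lb_pairs)}
        a_vec = np.array([p[0] for p in ab_pairs])
        b_vec = np.array([p[1] for p in ab_pairs])
        al_vec = np.array([p[0] for p in lb_pairs])
        bl_vec = np.array([p[1] for p in lb_pairs])

        top1 = np.zeros((len(combos), len(wmat)), dtype=int)
        for q in queries:
            C = len(q.s_metfrag)
            raw_p = np.stack([_raw_scores_for_grid(s, q.n_fps_peak, a_vec, b_vec)
                              for s in q.peak_stats], axis=1)   # (HP, C)
            raw_l = np.stack([_raw_scores_for_grid(s, q.n_fps_loss, al_vec, bl_vec)
                              for s in q.loss_stats], axis=1)   # (HL, C)
            s_peak = _normalize_rows(raw_p)
            s_loss = _normalize_rows(raw_l)
            for ci, combo in enumerate(combos):
                sp = s_peak[ab_index[(combo[0], combo[1])]]
                sl = s_loss[lb_index[(combo[2], combo[3])]]
                fin = (wmat[:, 0:1] * q.s_metfrag[None, :]
                       + wmat[:, 1:2] * sp[None, :]
                       + wmat[:, 2:3] * sl[None, :])            # (W, C)
                corr = fin[:, q.correct_idx]
                others = np.delete(fin, q.correct_idx, axis=1)
                top1[ci] += (corr > others.max(axis=1)).astype(int)
        for ci, combo in enumerate(combos):
            w_best = int(np.lexsort((wmat[:, 0], -top1[ci]))[0])
            evaluated[combo] = (int(top1[ci, w_best]), w_best)

    def current_best() -> tuple[tuple, int, int]:
        best_combo = min(evaluated,
                         key=lambda c: (-evaluated[c][0], c,
                                        wmat[evaluated[c][1], 0]))
        count, w_idx = evaluated[best_combo]
        return best_combo, count, w_idx

    combos = [tuple(v) for v in itertools.product(
        axes["alpha"], axes["beta"], axes["alpha_L"], axes["beta_L"])]
    evaluate(combos)
    log["initial_hyper_sets"] = len(combos)
    log["initial_combinations"] = len(combos) * len(wmat)
    best_combo, best_count, best_w = current_best()
    log["rounds"].append({"hyper_sets": len(combos), "best_top1": best_count})

    while True:
        extended = False
        for axis_i, name in enumerate(("alpha", "beta", "alpha_L", "beta_L")):
            vals = axes[name]
            v = best_combo[axis_i]
            if v == vals[0]:
                axes[name] = sorted(vals + [v / config.extension_factor])
                extended = True
            elif v == vals[-1]:
                axes[name] = sorted(vals + [v * config.extension_factor])
                extended = True
        if not extended:
            break
        new_combos = [c for c in itertools.product(
            axes["alpha"], axes["beta"], axes["alpha_L"], axes["beta_L"])
            if tuple(c) not in evaluated]
        if not new_combos:
            break
        evaluate([tuple(c) for c in new_combos])
        prev_count = best_count
        best_combo, best_count, best_w = current_best()
        log["rounds"].append({"hyper_sets": len(new_combos),
                              "best_top1": best_count})
        gain = math.inf if prev_count == 0 and best_count > 0 else (
            (best_count - prev_count) / prev_count if prev_count else 0.0)
        if gain < config.stop_improvement:
            break

    log["total_hyper_sets"] = len(evaluated)
    log["total_combinations"] = len(evaluated) * len(wmat)
    hyper = HyperParams(*best_combo)
    weights = weight_samples[best_w]
    return hyper, weights, best_count, log


def finalize_model(all_items: Sequence[tuple[Spectrum, Candidate]],
                   binning: MassBinning, fingerprint_function: str,
                   hyper: HyperParams, weights: ScoreWeights, mzabs: float,
                   mzppm: float, polarity: str, max_depth: int = 2,
                   loss_bottom_pairs: bool = False) -> AnnotationModel:
    """Recompute the count tables on the entire training set and assemble
    the final model with the optimized hyper parameters and weights."""
    peak_tab, loss_tab = phase1_collect(all_items, binning,
                                        fingerprint_function, mzabs, mzppm,
                                        max_depth)
    return AnnotationModel(
        peak_counts=collect_counts([peak_tab], binning),
        loss_counts=collect_counts([loss_tab], binning),
        hyper=hyper, weights=weights, binning=binning,
        fingerprint_function=fingerprint_function, polarity=polarity,
        mzabs=mzabs, mzppm=mzppm, max_depth=max_depth,
        loss_bottom_pairs=loss_bottom_pairs)


# ---------------------------------------------------------------------------
# Model / Results front end
# ---------------------------------------------------------------------------

class FragmentAnnotationModel:
    """Fragment-annotation scoring model, fitted from labelled spectra.

    Parameters
    ----------
    spectra
        Labelled training spectra (``inchikey`` set), all of one polarity.
    candidates
        Mapping from spectrum id to its candidate list. Each list must
        contain the spectrum's correct candidate (matched by InChIKey first
        block); the remaining entries serve as decoys during phase-2
        optimization (down-sampled to ``config.max_decoys``).
    mzabs, mzppm
        Instrument tolerances (Da / ppm) used for fragment assignment and
        for the bin widths of the m/z discretization.
    fingerprint_function
        One of ``maccs``, ``circular``, ``path_lingo``, ``graph_only``.
    """

    def __init__(self, spectra: Sequence[Spectrum],
                 candidates: Mapping[str, Sequence[Candidate]], *,
                 mzabs: float = 0.005, mzppm: float = 10.0,
                 fingerprint_function: str = "circular",
                 config: TrainingConfig | None = None) -> None:
        if not spectra:
            raise ValueError("need at least one training spectrum")
        polarities = {s.polarity for s in spectra}
        if len(polarities) != 1:
            raise ValueError("positive and negative mode are trained "
                             f"independently; got {sorted(polarities)}")
        self.spectra = list(spectra)
        self.candidates = {k: list(v) for k, v in candidates.items()}
        self.mzabs = mzabs
        self.mzppm = mzppm
        self.polarity = polarities.pop()
        self.fingerprint_function = fingerprint_function
        self.config = config or TrainingConfig()
        for s in self.spectra:
            self._correct_candidate(s)  # validate upfront

    def _correct_candidate(self, s: Spectrum) -> Candidate:
        cands = self.candidates.get(s.id)
        if not cands:
            raise ValueError(f"no candidate list for spectrum {s.id!r}")
        hits = [c for c in cands if c.inchikey_block1 == s.inchikey_block1]
        if not hits:
            raise ValueError(f"correct candidate (block {s.inchikey_block1}) "
                             f"missing from candidate list of {s.id!r}")
        return hits[0]

    def fit(self, seed: int = 0) -> "FragmentAnnotationResults":
        """Run the full two-phase training and return the fitted results."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        split_seed = int(rng.integers(2 ** 31))
        weight_seed = int(rng.integers(2 ** 31))
        decoy_rng = np.random.default_rng(int(rng.integers(2 ** 31)))

        g1, g2 = split_by_inchikey(self.spectra, cfg.split_ratio, split_seed)
        if not g2:
            raise ValueError("phase-2 split is empty; too few molecules")
        items1 = [(s, self._correct_candidate(s)) for s in g1]
        all_items = [(s, self._correct_candidate(s)) for s in self.spectra]

        # size the binning from the phase-1 annotations (peaks and losses)
        peak_items, loss_items = raw_annotations(items1, self.mzabs, self.mzppm,
                                                 cfg.max_depth)
        values = [m for m, _ in peak_items] + [m for m, _ in loss_items]
        if not values:
            raise ValueError("phase 1 produced no explainable peaks")
        lo, hi = min(values), max(values)
        width0 = 2 * (lo * self.mzppm / 1e6 + self.mzabs)
        binning = build_binning(max(lo - width0, width0), hi + 1.0,
                                self.mzabs, self.mzppm)

        peak_tab, loss_tab = phase1_collect(items1, binning,
                                            self.fingerprint_function,
                                            self.mzabs, self.mzppm,
                                            cfg.max_depth)
        peak_counts = collect_counts([peak_tab], binning)
        loss_counts = collect_counts([loss_tab], binning)

        caches = []
        for s in g2:
            correct = self._correct_candidate(s)
            decoys = [c for c in self.candidates[s.id]
                      if c.inchikey_block1 != s.inchikey_block1]
            if len(decoys) > cfg.max_decoys:
                idx = decoy_rng.choice(len(decoys), size=cfg.max_decoys,
                                       replace=False)
                decoys = [decoys[i] for i in sorted(idx)]
            cands = [correct] + decoys
            caches.append(_build_query_cache(
                s, cands, 0, peak_counts, loss_counts, binning,
                self.fingerprint_function, self.mzabs, self.mzppm,
                cfg.max_depth, cfg.loss_bottom_pairs))

        weight_samples = sample_weights(cfg.n_weight_samples, weight_seed)
        hyper, weights, top1, log = grid_search(caches, cfg, weight_samples)

        model = finalize_model(all_items, binning, self.fingerprint_function,
                               hyper, weights, self.mzabs, self.mzppm,
                               self.polarity, cfg.max_depth,
                               cfg.loss_bottom_pairs)
        return FragmentAnnotationResults(
            model=self, annotation_model=model, hyper=hyper, weights=weights,
            top1_count=top1, n_phase1=len(g1), n_phase2=len(g2),
            search_log=log, seed=seed)


@dataclass
class FragmentAnnotationResults:
    """Results of a :meth:`FragmentAnnotationModel.fit` run."""

    model: FragmentAnnotationModel
    annotation_model: AnnotationModel
    hyper: HyperParams
    weights: ScoreWeights
    top1_count: int
    n_phase1: int
    n_phase2: int
    search_log: dict
    seed: int

    def score_query(self, spectrum: Spectrum,
                    candidates: Sequence[Candidate]) -> pd.DataFrame:
        return self.annotation_model.score_query(spectrum, candidates)

    def rank_query(self, spectrum: Spectrum, candidates: Sequence[Candidate],
                   correct_block1: str | None = None,
                   tie_convention: str = "worst"):
        from .ranking import rank_candidates

        return rank_candidates(self.annotation_model, spectrum, candidates,
                               correct_block1=correct_block1,
                               tie_convention=tie_convention)

    def save(self, path) -> None:
        self.annotation_model.save(path)

    def summary(self) -> str:
        """Plain-text summary of the fitted parameters and training run."""
        h, w = self.hyper, self.weights
        m = self.annotation_model
        rows = [
            ("Polarity", m.polarity),
            ("Fingerprint function", m.fingerprint_function),
            ("Tolerances (mzabs / mzppm)", f"{m.mzabs:g} Da / {m.mzppm:g} ppm"),
            ("Spectra (phase 1 / phase 2)", f"{self.n_phase1} / {self.n_phase2}"),
            ("Top1 on phase 2", f"{self.top1_count} / {self.n_phase2}"),
            ("alpha / beta (peaks)", f"{h.alpha:g} / {h.beta:g}"),
            ("alpha_L / beta_L (losses)", f"{h.alpha_L:g} / {h.beta_L:g}"),
            ("weights (fragmenter, peak, loss)",
             f"({w.w1:.3f}, {w.w2:.3f}, {w.w3:.3f})"),
            ("|M| peak bins / |F| fingerprints",
             f"{len(m.peak_counts.domain_bins)} / {len(m.peak_counts.domain_fps)}"),
            ("|L| loss bins / |F_L| fingerprints",
             f"{len(m.loss_counts.domain_bins)} / {len(m.loss_counts.domain_fps)}"),
            ("Hyper sets evaluated",
             f"{self.search_log['total_hyper_sets']} "
             f"({self.search_log['initial_hyper_sets']} initial)"),
            ("Scored combinations",
             f"{self.search_log['total_combinations']} "
             f"({self.search_log['initial_combinations']} initial)"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Fragment annotation model", "=" * 42]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)
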
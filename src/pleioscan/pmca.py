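"""Phylogenetic motif-module complexity scoring (PMCA).

Scans 120 bp variant-flanking windows and their orthologs for transcription
factor binding motifs (PWM log-odds, both strands), finds motif *modules* —
sets of >= 3 motif-family hits whose order and pairwise spacing are
conserved between the reference species and at least one other species —
and scores each window by the count of non-overlapping reference hits that
participate in any conserved module. Enrichment is assessed against
permuted / background orthologous sets with an add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PSEUDO = 1e-3
NEG_INF = -1e9  # effective -inf for N bases; keeps arithmetic finite
_QSTEP = 1e-3   # shared log-odds quantization for thresholds and scans


@dataclass
class OrthologSet:
    """Variant-flanking windows for one locus across species.

    ``windows`` maps species name to an uppercase ACGT sequence; the
    reference species carries the variant at mid-position.
    """

    set_id: str
    reference: str            # reference species name
    windows: dict[str, str]
    planted_offsets: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.reference not in self.windows:
            raise ValueError("reference species missing from windows")


@dataclass
class Pwm:
    """Position weight matrix over ACGT (columns sum to 1)."""

    motif_id: str
    probs: np.ndarray            # (length, 4)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (length, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM columns must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """Log2 odds vs uniform background, with a small pseudocount."""
        p = (self.probs + _PSEUDO) / (1 + 4 * _PSEUDO)
        return np.log2(p / 0.25)

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.probs[::-1, ::-1])


def pwm_from_consensus(motif_id: str, consensus: str,
                       match_prob: float = 0.97) -> Pwm:
    """Near-deterministic PWM whose max column is the consensus base."""
    off = (1 - match_prob) / 3
    m = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus.upper()):
        m[i, _BASE_INDEX[b]] = match_prob
    return Pwm(motif_id, m)


@dataclass
class MotifLibrary:
    """PWMs grouped into motif families (one family per motif)."""

    motifs: list[Pwm]
    family_map: dict[str, str]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("empty motif library")
        for m in self.motifs:
            if m.motif_id not in self.family_map:
                raise ValueError(f"motif {m.motif_id} has no family")

    @property
    def max_length(self) -> int:
        return max(len(m) for m in self.motifs)


def read_meme(path, family_map: dict[str, str] | None = None) -> MotifLibrary:
    """Load a minimal-MEME motif file; default family = motif id."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    pwms = []
    for rec in records:
        counts = np.array([[rec.counts[b][i] for b in "ACGT"]
                           for i in range(rec.length)], dtype=float)
        probs = counts / counts.sum(axis=1, keepdims=True)
        pwms.append(Pwm(rec.name, probs))
    fam = family_map or {p.motif_id: p.motif_id for p in pwms}
    return MotifLibrary(pwms, fam)


def group_families_by_correlation(pwms: list[Pwm],
                                  min_corr: float = 0.8) -> dict[str, str]:
    """Cluster PWMs whose flattened columns correlate >= min_corr under the
    best ungapped offset; single-linkage merge. Utility stand-in for
    similarity-based family grouping of a motif catalog."""
    n = len(pwms)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def best_corr(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) < len(b):
            a, b = b, a
        best = -1.0
        for off in range(len(a) - len(b) + 1):
            x = a[off:off + len(b)].ravel()
            y = b.ravel()
            if x.std() == 0 or y.std() == 0:
                continue
            best = max(best, float(np.corrcoef(x, y)[0, 1]))
        return best

    for i, j in combinations(range(n), 2):
        if best_corr(pwms[i].probs, pwms[j].probs) >= min_corr:
            parent[find(i)] = find(j)
    return {p.motif_id: f"F{find(i)}" for i, p in enumerate(pwms)}


@dataclass(frozen=True)
class MotifHit:
    """One PWM match in one species' window (0-based window coords)."""

    species: str
    family: str
    start: int
    strand: str              # '+' or '-'
    score: float
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def score_threshold(pwm: Pwm, pvalue: float) -> float:
    """Score cutoff whose background tail probability is <= pvalue.

    The exact distribution of the log-odds score under the uniform
    background is built by dynamic-programming convolution over positions
    (scores discretized to 1e-3); the returned threshold is the smallest
    discretized score with upper-tail mass <= pvalue.
    """
    if not 0 < pvalue < 1:
        raise ValueError("pvalue must lie in (0,1)")
    step = _QSTEP
    lo = np.round(pwm.log_odds / step).astype(int)
    dist = {0: 1.0}
    for col in lo:
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for v in col:
                nxt[s + v] = nxt.get(s + v, 0.0) + p * 0.25
        dist = nxt
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    tail = np.cumsum(probs[::-1])[::-1]
    ok = scores[tail <= pvalue]
    if ok.size == 0:
        return float(scores[-1] * step) + step  # only the top score qualifies
    return float(ok[0] * step)


def scan_motifs(window: str, library: MotifLibrary,
                pvalue_threshold: float = 1e-4,
                species: str = "") -> list[MotifHit]:
    """All PWM hits in a window on both strands above the p-value threshold.

    N bases poison every overlapping placement. Hits are deduplicated to
    the best score per (family, start, strand).
    """
    if not library.motifs:
        raise ValueError("empty motif library")
    enc = _encode(window)
    L = len(enc)
    hits: dict[tuple[str, int, str], MotifHit] = {}
    for pwm in library.motifs:
        m = len(pwm)
        if m > L:
            continue
        thr = score_threshold(pwm, pvalue_threshold)
        fam = library.family_map[pwm.motif_id]
        for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
            # quantize like score_threshold so cutoff and scan agree exactly;
            # a 5th column of -inf makes N (code 4) poison any placement
            q = np.round(mat.log_odds / _QSTEP) * _QSTEP
            lo = np.hstack([q, np.full((m, 1), NEG_INF)])
            windows = np.lib.stride_tricks.sliding_window_view(enc, m)
            scores = lo[np.arange(m), windows].sum(axis=1)
            for start in np.flatnonzero(scores >= thr - _QSTEP / 2):
                key = (fam, int(start), strand)
                h = MotifHit(species, fam, int(start), strand,
                             float(scores[start]), m)
                if key not in hits or h.score > hits[key].score:
                    hits[key] = h
    return sorted(hits.values(), key=lambda h: (h.start, h.family, h.strand))


def _non_overlapping(hits: list[MotifHit]) -> bool:
    s = sorted(hits, key=lambda h: h.start)
    return all(a.end <= b.start for a, b in zip(s, s[1:]))


def _conserved_in(combo: tuple[MotifHit, ...], other: list[MotifHit],
                  tol: int) -> bool:
    """Does ``other`` contain hits with the same family order and pairwise
    gaps equal within +/- tol bp, non-overlapping?"""
    fams = [h.family for h in combo]
    gaps = [b.start - a.start for a, b in zip(combo, combo[1:])]
    by_fam: dict[str, list[MotifHit]] = {}
    for h in other:
        by_fam.setdefault(h.family, []).append(h)
    if any(f not in by_fam for f in fams):
        return False

    def extend(i: int, chosen: list[MotifHit]) -> bool:
        if i == len(fams):
            return _non_overlapping(chosen)
        for h in by_fam[fams[i]]:
            if chosen:
                if h.start <= chosen[-1].start:
                    continue
                if abs((h.start - chosen[-1].start) - gaps[i - 1]) > tol:
                    continue
            if extend(i + 1, chosen + [h]):
                return True
        return False

    return extend(0, [])


# combinatorial guard: reference windows are 120 bp and the scan threshold
# sparse, so hit counts stay small; cap defends against pathological inputs
_MAX_REF_HITS = 24


def find_conserved_modules(hits_by_species: dict[str, list[MotifHit]],
                           reference: str = "human", min_motifs: int = 3,
                           distance_tolerance: int = 10,
                           ) -> list[tuple[MotifHit, ...]]:
    """Maximal conserved modules: >= min_motifs reference hits whose family
    order and pairwise gaps recur (within tolerance) in >= 1 other species.

    Seeds with conserved combinations of exactly ``min_motifs``
    non-overlapping reference hits and greedily extends each seed while
    conservation holds; returns maximal modules (no module a subset of
    another).
    """
    if reference not in hits_by_species:
        raise ValueError(f"reference species {reference!r} absent")
    ref_hits = sorted(hits_by_species[reference], key=lambda h: h.start)
    if len(ref_hits) > _MAX_REF_HITS:
        ref_hits = sorted(ref_hits, key=lambda h: -h.score)[:_MAX_REF_HITS]
        ref_hits.sort(key=lambda h: h.start)
    others = {s: h for s, h in hits_by_species.items() if s != reference}

    def conserved(combo: tuple[MotifHit, ...]) -> bool:
        return _non_overlapping(list(combo)) and any(
            _conserved_in(combo, hs, distance_tolerance)
            for hs in others.values())

    modules: list[tuple[MotifHit, ...]] = []
    for seed in combinations(ref_hits, min_motifs):
        if not conserved(seed):
            continue
        cur = list(seed)
        for h in ref_hits:
            if h in cur:
                continue
            cand = tuple(sorted(cur + [h], key=lambda x: x.start))
            if conserved(cand):
                cur = list(cand)
        modules.append(tuple(sorted(cur, key=lambda h: h.start)))

    # keep maximal, deduplicated modules
    uniq = sorted(set(modules), key=lambda m: (-len(m), m[0].start))
    maximal = []
    for m in uniq:
        if not any(set(m) < set(b) for b in maximal):
            maximal.append(m)
    return maximal


@dataclass
class ModuleScore:
    """PMCA result for one ortholog set."""

    modules: list[tuple[MotifHit, ...]]
    score: int
    perm_p: float | None = None


def pmca_score(ortholog_set, library: MotifLibrary,
               pvalue_threshold: float = 1e-4, min_motifs: int = 3,
               distance_tolerance: int = 10) -> ModuleScore:
    """Count non-overlapping reference hits in conserved modules (0 if none)."""
    hits_by_species = {
        sp: scan_motifs(seq, library, pvalue_threshold, species=sp)
        for sp, seq in ortholog_set.windows.items()
    }
    modules = find_conserved_modules(
        hits_by_species, reference=ortholog_set.reference,
        min_motifs=min_motifs, distance_tolerance=distance_tolerance)
    # count distinct reference hits across modules, greedily non-overlapping
    all_hits = sorted({h for m in modules for h in m},
                      key=lambda h: (h.start, h.end))
    count, last_end = 0, -1
    for h in all_hits:
        if h.start >= last_end:
            count += 1
            last_end = h.end
    return ModuleScore(modules, count)


def permutation_pvalue(observed_score: int, background_scores,
                       n_perm: int = 10_000, seed: int | None = None,
                       ) -> float:
    """Add-one permutation p: (1 + #{bg >= obs}) / (n + 1); never 0.

    ``background_scores`` is either a sequence of pre-computed background
    set scores or a callable ``f(rng) -> score`` drawn ``n_perm`` times.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if callable(background_scores):
        rng = np.random.default_rng(seed)
        bg = np.array([background_scores(rng) for _ in range(n_perm)])
    else:
        bg = np.asarray(list(background_scores))[:n_perm]
    n = len(bg)
    return float((1 + int((bg >= observed_score).sum())) / (n + 1))
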
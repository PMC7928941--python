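"""Synthetic fixtures with the statistical structure the analyses assume.

Every generator is a pure function of a :class:`SimulationConfig`: the global
seed expands into fixed per-generator substreams so adding a generator never
perturbs the output of another. DNA is uppercase ACGT only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pmca import OrthologSet

DNA = np.array(list("ACGT"))

# fixed substream offsets, one per generator
_STREAM = {
    "summary": 11,
    "ortholog": 23,
    "counts": 37,
    "peaks": 53,
    "epigenome": 71,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of every synthetic fixture; one seed fixes all outputs.

    Defaults mirror the study conditions: two-trait GWAS sample sizes of a
    bone-density and a fasting-glucose consortium scan, sample-overlap z-score
    correlation 0.3, 120 bp ortholog windows, a 1.9-fold chromatin imbalance
    over 20 variants at depth 50, and an 8 bp anchor k-mer.
    """

    seed: int = 0
    # --- paired GWAS summary statistics ---
    n_snps: int = 10_000
    trait_correlation: float = 0.0        # genetic effect correlation at planted loci
    overlap_correlation: float = 0.3      # null z-score correlation from shared samples
    planted_loci: tuple[tuple[int, float, float], ...] = ()
    n_a: int = 32_961
    n_b: int = 46_186
    # --- ortholog windows / motif modules ---
    n_species: int = 5
    window_bp: int = 120
    module_motifs: tuple[str, ...] = ("M1", "M2", "M3")
    module_spacings: tuple[int, ...] = (10, 12)
    module_jitter: int = 0
    n_background_sets: int = 100
    # --- allele counts ---
    imbalance_fold: float = 1.9
    depth: int = 50
    n_variants: int = 20
    n_donors: int = 1
    # --- peak sequences ---
    # 12 bp so the full consensus fits the default conv stack's 13 bp
    # receptive field; per-base noise makes every position informative
    motif_consensus: str = "TGACGTCATTGA"
    n_pos: int = 1000
    n_neg: int = 1000
    seq_length: int = 100
    motif_noise: float = 0.05             # per-base mutation prob inside planted motif
    n_disrupting: int = 25
    n_neutral: int = 25
    # --- epigenome fixture ---
    n_leaves: int = 8
    enriched_clade: str = "cladeA"
    clade_fold: float = 2.0
    leaf_noise: float = 0.0
    genome_bp: int = 50_000
    kmer: str = "TGGCGTGA"
    kmer_alt: str = "CACGCCGG"
    kmer_fold: float = 2.0
    n_kmer_sites: int = 50
    track_noise: float = 0.0

    def __post_init__(self) -> None:
        if not -1 < self.trait_correlation < 1:
            raise ValueError("trait_correlation must lie in (-1, 1)")
        if not 0 <= self.overlap_correlation < 1:
            raise ValueError("overlap_correlation must lie in [0, 1)")
        for name in ("n_snps", "n_species", "n_a", "n_b", "window_bp",
                     "seq_length", "n_leaves", "genome_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("imbalance_fold", "clade_fold", "kmer_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(int(self.seed) + _STREAM[stream])

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# paired GWAS summary statistics
# ---------------------------------------------------------------------------

# non-ambiguous allele pairs (strand-ambiguous A/T and C/G avoided so
# harmonization keeps every SNP unless a fixture plants ambiguity on purpose)
_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T")]


def gen_summary_stats(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two GWAS summary-statistic tables over a shared SNP panel.

    Null SNPs draw their (z_a, z_b) pair from a bivariate normal with unit
    variances and correlation ``overlap_correlation`` — the correlation that
    shared samples induce between two scans under the null. Planted loci add
    (effect_a, effect_b) to the pair's mean. Betas are reconstructed through
    the standard GWAS standard-error approximation
    SE = 1 / sqrt(2 N MAF (1-MAF)), BETA = z * SE.

    Returns
    -------
    (stats_a, stats_b) : pair of DataFrames
        Columns SNP CHR BP A1 A2 BETA SE P N MAF, one row per SNP,
        allele-consistent between the two tables.
    """
    if config.n_snps < 100:
        raise ValueError("n_snps must be >= 100")
    for idx, _, _ in config.planted_loci:
        if not 0 <= idx < config.n_snps:
            raise ValueError(f"planted locus index {idx} out of range")
    rng = config.rng("summary")
    n = config.n_snps

    r = config.overlap_correlation
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n,
                                method="cholesky")
    for idx, ea, eb in config.planted_loci:
        z[idx, 0] += ea
        z[idx, 1] += eb

    maf = rng.uniform(0.05, 0.5, size=n)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    a1 = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    chrom = rng.integers(1, 23, size=n)
    order = np.lexsort((np.arange(n), chrom))
    # positions increase within chromosome; SNP ids keep the planted indexing
    bp = np.zeros(n, dtype=int)
    for c in np.unique(chrom):
        m = chrom == c
        bp[m] = np.sort(rng.integers(1, 250_000_000, size=m.sum()))

    from scipy import stats as sps

    def table(zcol: np.ndarray, n_samples: int) -> pd.DataFrame:
        se = 1.0 / np.sqrt(2.0 * n_samples * maf * (1.0 - maf))
        beta = zcol * se
        p = 2.0 * sps.norm.sf(np.abs(zcol))
        return pd.DataFrame({
            "SNP": [f"rs{i}" for i in range(n)],
            "CHR": chrom,
            "BP": bp,
            "A1": a1,
            "A2": a2,
            "BETA": beta,
            "SE": se,
            "P": np.clip(p, np.finfo(float).tiny, 1.0),
            "N": n_samples,
            "MAF": maf,
        })

    del order  # tables stay in SNP-index order; consumers sort as needed
    return table(z[:, 0], config.n_a), table(z[:, 1], config.n_b)


# ---------------------------------------------------------------------------
# ortholog windows with planted conserved motif modules
# ---------------------------------------------------------------------------

# tiny built-in consensus set used when the caller supplies no PWM library;
# consensi are long enough that chance hits in 120 bp are rare
DEMO_MOTIF_CONSENSI = {
    "M1": "TGACGTCA",
    "M2": "CACGTGAC",
    "M3": "GGGCGGGA",
}


def _plant_module(rng, window: str, consensi: list[str], spacings: list[int],
                  jitter: int, offset: int) -> tuple[str, list[int]]:
    """Overwrite ``window`` with the motif module starting at ``offset``."""
    seq = list(window)
    starts = []
    pos = offset
    for i, cons in enumerate(consensi):
        if i > 0:
            gap = spacings[i - 1]
            if jitter:
                gap += int(rng.integers(-jitter, jitter + 1))
            pos += gap
        starts.append(pos)
        seq[pos:pos + len(cons)] = list(cons)
        pos += len(cons)
    return "".join(seq), starts


def gen_ortholog_sets(
    config: SimulationConfig,
    motif_consensi: dict[str, str] | None = None,
) -> tuple[OrthologSet, list[OrthologSet]]:
    """One case set with a planted conserved module, plus background sets.

    The case set carries the configured motif consensi in order, with the
    configured inter-motif gaps, at identical relative offsets in the
    reference (human) window and in one other species (jitter optional).
    Background sets are i.i.d. uniform DNA across all species.
    """
    if config.n_species < 2:
        raise ValueError("n_species must be >= 2")
    consensi = [
        (motif_consensi or DEMO_MOTIF_CONSENSI)[m] for m in config.module_motifs
    ]
    if len(config.module_spacings) != len(consensi) - 1:
        raise ValueError("need one spacing per adjacent motif pair")
    module_len = sum(len(c) for c in consensi) + sum(config.module_spacings)
    if module_len + config.module_jitter * len(config.module_spacings) > config.window_bp:
        raise ValueError("module longer than window")

    rng = config.rng("ortholog")
    species = ["human"] + [f"sp{i}" for i in range(1, config.n_species)]
    w = config.window_bp

    windows = {s: _random_dna(rng, w) for s in species}
    offset = int(rng.integers(0, w - module_len + 1))
    planted: dict[str, list[int]] = {}
    for s in ("human", species[1]):
        jit = 0 if s == "human" else config.module_jitter
        windows[s], starts = _plant_module(
            rng, windows[s], consensi, list(config.module_spacings), jit, offset)
        planted[s] = starts
    case = OrthologSet("case", "human", windows, planted)

    background = [
        OrthologSet(f"bg{i}", "human", {s: _random_dna(rng, w) for s in species})
        for i in range(config.n_background_sets)
    ]
    return case, background


# ---------------------------------------------------------------------------
# allele-specific read counts
# ---------------------------------------------------------------------------

def gen_allele_counts(config: SimulationConfig) -> pd.DataFrame:
    """Haplotype-resolved read counts with a planted imbalance fold.

    Per variant, the haplotype-1 count is Binomial(depth, f/(1+f)) with
    f = ``imbalance_fold``; haplotype 2 receives the remaining reads.
    Columns: VARIANT DONOR ASSAY TIMEPOINT HAP1 HAP2.
    """
    if config.depth <= 0:
        raise ValueError("depth must be > 0")
    rng = config.rng("counts")
    f = config.imbalance_fold
    p1 = f / (1.0 + f)
    rows = []
    for d in range(config.n_donors):
        for v in range(config.n_variants):
            k1 = int(rng.binomial(config.depth, p1))
            rows.append({
                "VARIANT": f"var{v}",
                "DONOR": f"donor{d}",
                "ASSAY": "ATAC",
                "TIMEPOINT": "D0",
                "HAP1": k1,
                "HAP2": config.depth - k1,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak sequences with a planted accessibility motif
# ---------------------------------------------------------------------------

@dataclass
class PlantedVariant:
    """A substitution with its ground-truth regulatory label."""

    seq_index: int            # positive-sequence index the variant lies in
    pos: int                  # 0-based position within the window
    ref: str
    alt: str
    disrupting: bool          # True if it alters a planted consensus base


def gen_peak_dataset(
    config: SimulationConfig,
) -> tuple[list[str], list[str], np.ndarray, list[PlantedVariant]]:
    """Labeled fixed-width sequences and truth-labeled variants.

    Positives carry ``motif_consensus`` at a random offset (with optional
    per-base mutation noise); negatives are uniform DNA. The variant list
    pairs motif-disrupting substitutions (a consensus base changed) with
    neutral ones placed >= 10 bp outside the motif, each tagged with its
    truth label.

    Returns ``(sequences, labels_ignored, motif_offsets, variants)`` where
    sequences are positives followed by negatives, ``motif_offsets`` holds
    the planted start per positive (-1 for negatives).
    """
    if config.n_pos <= 0 or config.n_neg <= 0:
        raise ValueError("n_pos and n_neg must be > 0")
    motif = config.motif_consensus
    L, ml = config.seq_length, len(motif)
    if L < ml:
        raise ValueError("seq_length shorter than motif")
    rng = config.rng("peaks")

    seqs: list[str] = []
    offsets = np.full(config.n_pos + config.n_neg, -1, dtype=int)
    for i in range(config.n_pos):
        seq = list(_random_dna(rng, L))
        off = int(rng.integers(0, L - ml + 1))
        planted = list(motif)
        if config.motif_noise > 0:
            for j in range(ml):
                if rng.random() < config.motif_noise:
                    planted[j] = str(rng.choice([b for b in "ACGT" if b != motif[j]]))
        seq[off:off + ml] = planted
        seqs.append("".join(seq))
        offsets[i] = off
    for _ in range(config.n_neg):
        seqs.append(_random_dna(rng, L))

    variants: list[PlantedVariant] = []
    pos_idx = rng.choice(config.n_pos, size=config.n_disrupting + config.n_neutral,
                         replace=config.n_pos < config.n_disrupting + config.n_neutral)
    for k, i in enumerate(pos_idx):
        i = int(i)
        off = int(offsets[i])
        if k < config.n_disrupting:
            j = off + int(rng.integers(0, ml))
        else:
            # neutral: >= 10 bp clear of the planted motif
            choices = [p for p in range(L)
                       if p < off - 10 - 0 or p >= off + ml + 10]
            if not choices:
                raise ValueError("window too short to place neutral variants")
            j = int(rng.choice(choices))
        ref = seqs[i][j]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        variants.append(PlantedVariant(i, j, ref, alt, k < config.n_disrupting))

    labels = np.concatenate([np.ones(config.n_pos), np.zeros(config.n_neg)])
    return seqs, labels, offsets, variants


# ---------------------------------------------------------------------------
# chromatin segmentation, epigenome tree, and k-mer-anchored signal track
# ---------------------------------------------------------------------------

@dataclass
class EpigenomeFixture:
    """Everything the annotation and IGR stages consume, with ground truth."""

    segmentation: pd.DataFrame        # chrom start end state epigenome
    expected_clusters: list[tuple[int, int]]
    newick: str
    leaf_signals: dict[str, float]
    enriched_leaves: list[str]
    genome: str
    track: np.ndarray                 # per-base signal over the genome
    kmer_positions: list[int]         # planted forward-strand starts (ref k-mer)
    kmer_alt_positions: list[int]


def _balanced_newick(leaves: list[str]) -> str:
    """Balanced binary newick over the leaf list, internal nodes unlabeled."""
    nodes = list(leaves)
    while len(nodes) > 1:
        nxt = []
        for i in range(0, len(nodes) - 1, 2):
            nxt.append(f"({nodes[i]},{nodes[i + 1]})")
        if len(nodes) % 2:
            nxt.append(nodes[-1])
        nodes = nxt
    return nodes[0] + ";"


def gen_epigenome_fixture(config: SimulationConfig) -> EpigenomeFixture:
    """Segmentation with known merge structure, tree with one enriched clade,
    and a signal track elevated around planted occurrences of one k-mer.

    The segmentation plants repressed-state ("24") runs whose gaps alternate
    at/below and above the 200 bp join rule, so the expected clusters are
    known by construction. Leaf signals are ``1.0`` outside and
    ``clade_fold`` inside the enriched clade (Gaussian noise optional).
    The bedGraph-style track is baseline 1.0, multiplied by ``kmer_fold``
    within +/-25 bp of each planted reference k-mer occurrence.
    """
    rng = config.rng("epigenome")

    # --- segmentation: alternating state-24 runs with known gaps ---
    rows, expected, cur = [], [], None
    pos = 1000
    gaps = [100, 200, 201, 500, 0, 150, 300, 200]
    for i, gap in enumerate(gaps):
        start, end = pos, pos + 400
        rows.append({"chrom": "chr1", "start": start, "end": end,
                     "state": "24", "epigenome": "E1"})
        if cur is None:
            cur = [start, end]
        elif start - cur[1] <= 200:
            cur[1] = end
        else:
            expected.append(tuple(cur))
            cur = [start, end]
        pos = end + gap
    expected.append(tuple(cur))
    seg = pd.DataFrame(rows)

    # --- epigenome tree with one enriched clade ---
    if config.n_leaves < 4 or config.n_leaves % 2:
        raise ValueError("n_leaves must be an even count >= 4")
    leaves = [f"E{i:03d}" for i in range(config.n_leaves)]
    clades = {"cladeA": leaves[: config.n_leaves // 4 or 2]}
    if config.enriched_clade not in clades:
        raise ValueError(f"unknown clade label {config.enriched_clade!r}")
    enriched = clades[config.enriched_clade]
    signals = {}
    for leaf in leaves:
        base = config.clade_fold if leaf in enriched else 1.0
        if config.leaf_noise > 0:
            base += float(rng.normal(0, config.leaf_noise))
        signals[leaf] = max(base, 1e-9)
    newick = _balanced_newick(leaves)

    # --- genome + track with k-mer anchors ---
    genome = list(_random_dna(rng, config.genome_bp))
    k = len(config.kmer)
    n_each = config.n_kmer_sites
    slots = rng.choice(np.arange(100, config.genome_bp - 100 - k, 2 * k + 60),
                       size=2 * n_each, replace=False)
    slots = np.sort(slots)
    ref_pos, alt_pos = [], []
    for i, s in enumerate(slots):
        s = int(s)
        if i % 2 == 0:
            genome[s:s + k] = list(config.kmer)
            ref_pos.append(s)
        else:
            genome[s:s + len(config.kmer_alt)] = list(config.kmer_alt)
            alt_pos.append(s)
    # scramble chance occurrences of either k-mer (both strands) outside the
    # planted slots so anchor counts equal the planted truth exactly
    comp = str.maketrans("ACGT", "TGCA")
    words = set()
    for km in (config.kmer, config.kmer_alt):
        words.add(km)
        words.add(km.translate(comp)[::-1])
    planted_at = set(ref_pos) | set(alt_pos)
    text = "".join(genome)
    for _ in range(20):
        dirty = []
        for wd in words:
            start = text.find(wd)
            while start != -1:
                if start not in planted_at:
                    dirty.append(start)
                start = text.find(wd, start + 1)
        if not dirty:
            break
        g = list(text)
        for s in dirty:
            g[s] = str(DNA[rng.integers(0, 4)])
        text = "".join(g)
    genome = text
    track = np.ones(config.genome_bp)
    for s in ref_pos:
        lo, hi = max(0, s - 25), min(config.genome_bp, s + k + 25)
        track[lo:hi] *= config.kmer_fold
    if config.track_noise > 0:
        track = track + rng.normal(0, config.track_noise, size=track.shape)
        track = np.clip(track, 0, None)

    return EpigenomeFixture(seg, expected, newick, signals, enriched,
                            genome, track, ref_pos, alt_pos)


# ---------------------------------------------------------------------------
# serialization helpers (TSV / FASTA / BED / bedGraph / Newick)
# ---------------------------------------------------------------------------

def write_summary_stats(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_ortholog_fasta(oset: OrthologSet, path) -> None:
    with open(path, "w") as fh:
        for sp, seq in oset.windows.items():
            fh.write(f">{sp}|{oset.set_id}|0-{len(seq)}\n{seq}\n")


def write_counts_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_segmentation_bed(seg: pd.DataFrame, path) -> None:
    seg[["chrom", "start", "end", "state"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_track_bedgraph(track: np.ndarray, path, chrom: str = "chr1") -> None:
    # run-length encode the per-base track
    change = np.flatnonzero(np.diff(track)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(track)]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            fh.write(f"{chrom}\t{s}\t{e}\t{track[s]:g}\n")
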
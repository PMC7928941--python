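"""Polycomb repressor clustering and clade-level epigenome enrichment.

Repressed chromatin segments (chromHMM-style state calls, default state
"24": high H3K27me3, low promoter/enhancer marks) are merged into clusters
by joining consecutive same-chromosome elements 200 bp apart or less —
transitively — and reported with their span length, highlighting master
regulatory loci. Separately, per-epigenome mean H3K27me3 signal over a
locus is placed on an epigenome linkage tree and every proper clade is
scored by the ratio of the mean signal inside the clade to the mean
outside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import inf

import dendropy
import numpy as np
import pandas as pd


@dataclass
class RepressorCluster:
    """A run of repressed segments joined by the gap rule."""

    chrom: str
    span_start: int
    span_end: int
    members: list[tuple[int, int]] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        """Span length (end - start of the cluster hull)."""
        return self.span_end - self.span_start

    @property
    def member_length(self) -> int:
        return sum(e - s for s, e in self.members)


def merge_repressed(segmentation: pd.DataFrame, state: str = "24",
                    gap_bp: int = 200) -> list[RepressorCluster]:
    """Merge same-state intervals whose gap is <= gap_bp (transitively).

    Gap is next.start - prev.end on 0-based half-open intervals, so
    touching intervals have gap 0 and "200 bp apart or less" is gap <= 200.
    Input columns: chrom start end state (epigenome optional; clustering is
    per chromosome over the selected state's intervals).
    """
    seg = segmentation[segmentation["state"].astype(str) == str(state)]
    clusters: list[RepressorCluster] = []
    for chrom, sub in seg.groupby("chrom", sort=True):
        sub = sub.sort_values(["start", "end"])
        cur: RepressorCluster | None = None
        for s, e in zip(sub["start"].astype(int), sub["end"].astype(int)):
            if s >= e:
                raise ValueError(f"invalid interval {chrom}:{s}-{e}")
            if cur is not None and s - cur.span_end <= gap_bp:
                cur.span_end = max(cur.span_end, e)
                cur.members.append((s, e))
            else:
                if cur is not None:
                    clusters.append(cur)
                cur = RepressorCluster(chrom, s, e, [(s, e)])
        if cur is not None:
            clusters.append(cur)
    return clusters


def clusters_to_frame(clusters: list[RepressorCluster]) -> pd.DataFrame:
    return pd.DataFrame([{
        "chrom": c.chrom, "start": c.span_start, "end": c.span_end,
        "n_members": len(c.members), "total_length": c.total_length,
    } for c in clusters])


def locus_mean_signal(track: pd.DataFrame, chrom: str, start: int,
                      end: int) -> float:
    """Base-pair-weighted mean of a bedGraph track over [start, end).

    ``track`` columns: chrom start end value (0-based half-open). Bases of
    the interval not covered by the track contribute value 0.
    """
    if end <= start:
        raise ValueError("zero-length interval")
    sub = track[(track["chrom"] == chrom) & (track["end"] > start)
                & (track["start"] < end)]
    total = 0.0
    for s, e, v in zip(sub["start"], sub["end"], sub["value"]):
        total += float(v) * (min(int(e), end) - max(int(s), start))
    return total / (end - start)


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


@dataclass
class CladeRatio:
    """Relative enrichment of one proper clade of the linkage tree."""

    clade_leaves: tuple[str, ...]
    in_mean: float
    out_mean: float
    ratio: float                 # inf flagged when out-of-clade mean is 0
    infinite: bool = False


def clade_enrichment(newick: str | dendropy.Tree,
                     leaf_signals: dict[str, float]) -> list[CladeRatio]:
    """Per-clade in/out mean-signal ratios on an epigenome linkage tree.

    For every internal node other than the root, the clade's enrichment is
    the mean leaf signal inside the clade divided by the mean outside.
    Leaf set and signal-table keys must agree; ratios are sorted largest
    first.
    """
    if isinstance(newick, dendropy.Tree):
        tree = newick
    else:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label.replace(" ", "_") if lf.taxon else None
              for lf in tree.leaf_node_iter()]
    if None in leaves:
        raise ValueError("unlabeled leaf in tree")
    if set(leaves) != set(leaf_signals):
        missing = set(leaves) ^ set(leaf_signals)
        raise ValueError(f"leaf/signal mismatch: {sorted(missing)}")
    if len(leaves) < 2:
        raise ValueError("tree must have >= 2 leaves")
    for v in leaf_signals.values():
        if not np.isfinite(v) or v < 0:
            raise ValueError("leaf signals must be finite and >= 0")

    all_leaves = set(leaves)
    out: list[CladeRatio] = []
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        clade = tuple(sorted(
            lf.taxon.label.replace(" ", "_") for lf in node.leaf_iter()))
        rest = all_leaves - set(clade)
        if not rest:
            continue
        in_mean = float(np.mean([leaf_signals[x] for x in clade]))
        out_mean = float(np.mean([leaf_signals[x] for x in rest]))
        if out_mean == 0:
            out.append(CladeRatio(clade, in_mean, out_mean, inf, True))
        else:
            out.append(CladeRatio(clade, in_mean, out_mean, in_mean / out_mean))
    out.sort(key=lambda c: (-c.ratio, c.clade_leaves))
    return out


def clade_table(ratios: list[CladeRatio]) -> pd.DataFrame:
    return pd.DataFrame([{
        "clade": ",".join(c.clade_leaves), "n_leaves": len(c.clade_leaves),
        "in_mean": c.in_mean, "out_mean": c.out_mean, "ratio": c.ratio,
    } for c in ratios])
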
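"""Community-structure comparisons: CARD-FISH percentages, ARISA binning,
Bray-Curtis dissimilarity and UPGMA dendrograms.

CARD-FISH probe counts become percentages of the total DAPI-stained cells.
ARISA peak profiles are filtered (100-1000 bp length window, relative
fluorescence intensity cutoff 0.09 on per-sample-normalized intensities)
and binned into 3-bp fragment-length windows using the shifting-window
strategy: candidate binning frames at 0.1-bp offsets are enumerated and the
frame maximizing the mean pairwise sample similarity of the resulting OTU
table is kept. Sample distances are Bray-Curtis, clustered by average
linkage (UPGMA) and exported as Newick with ultrametric branch lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PROBE_COLUMNS",
    "relative_abundance",
    "filter_peaks",
    "FilteredProfile",
    "bin_fragments",
    "BinningResult",
    "bray_curtis",
    "cluster_dendrogram",
    "DendrogramResult",
    "cluster_concordance",
    "ConcordanceResult",
]

PROBE_COLUMNS = ("SAR11", "Rhodobacteraceae", "Gammaproteobacteria", "Bacteroidetes")


# ---------------------------------------------------------------------------
# CARD-FISH
# ---------------------------------------------------------------------------


def relative_abundance(
    table: pd.DataFrame,
    probes: Sequence[str] = PROBE_COLUMNS,
    dapi_column: str = "dapi_total",
) -> pd.DataFrame:
    """Probe counts as percentages of total DAPI counts, per sample.

    Adds a ``summed_coverage_percent`` column (how much of the DAPI-stained
    community the probes jointly identify). Probe counts exceeding the DAPI
    total are rejected.
    """
    dapi = table[dapi_column].to_numpy(float)
    if np.any(dapi <= 0):
        raise ValueError("DAPI totals must be positive")
    out = table.copy()
    for probe in probes:
        counts = table[probe].to_numpy(float)
        if np.any(counts < 0) or np.any(counts > dapi):
            raise ValueError(f"probe {probe!r} counts must lie in [0, DAPI total]")
        out[f"{probe}_percent"] = 100.0 * counts / dapi
    out["summed_coverage_percent"] = sum(
        out[f"{p}_percent"] for p in probes
    )
    return out


# ---------------------------------------------------------------------------
# ARISA filtering
# ---------------------------------------------------------------------------


@dataclass
class FilteredProfile:
    """One sample's ARISA profile after length/intensity filtering."""

    peaks: pd.DataFrame  # columns fragment_bp, rfi (normalized, sums to 1)
    empty: bool
    n_raw: int
    n_removed_length: int
    n_removed_intensity: int


def filter_peaks(
    profile: pd.DataFrame,
    min_bp: float = 100.0,
    max_bp: float = 1000.0,
    rfi_cutoff: float = 0.09,
) -> FilteredProfile:
    """Apply the ARISA length window and background-noise intensity cutoff.

    Order of operations: drop peaks outside [min_bp, max_bp] (inclusive),
    normalize intensities to sum 1, drop peaks with normalized intensity
    strictly below the cutoff (>= cutoff is retained), renormalize. Samples
    left with no peaks are flagged ``empty``.
    """
    p = profile[["fragment_bp", "rfi"]].copy()
    if np.any(p["rfi"].to_numpy(float) < 0):
        raise ValueError("intensities must be >= 0")
    n_raw = len(p)
    in_len = p["fragment_bp"].between(min_bp, max_bp)
    p = p[in_len]
    n_len = int(n_raw - len(p))
    total = p["rfi"].sum()
    if len(p) == 0 or total <= 0:
        return FilteredProfile(p.iloc[0:0], True, n_raw, n_len, 0)
    p = p.assign(rfi=p["rfi"] / total)
    keep = p["rfi"] >= rfi_cutoff
    n_int = int((~keep).sum())
    p = p[keep]
    if len(p) == 0:
        return FilteredProfile(p, True, n_raw, n_len, n_int)
    p = p.assign(rfi=p["rfi"] / p["rfi"].sum()).reset_index(drop=True)
    return FilteredProfile(p, False, n_raw, n_len, n_int)


# ---------------------------------------------------------------------------
# Shifting-window binning
# ---------------------------------------------------------------------------


@dataclass
class BinningResult:
    """OTU table from shifting-window fragment binning."""

    otu_table: pd.DataFrame  # samples x bin-start columns, summed rfi
    offset: float
    window: float
    anchor: float
    frame_scores: pd.Series  # mean pairwise similarity per candidate offset


def _bin_table(
    profiles: Mapping[str, pd.DataFrame],
    window: float,
    start: float,
) -> pd.DataFrame:
    rows = {}
    for sample, peaks in profiles.items():
        L = peaks["fragment_bp"].to_numpy(float)
        rfi = peaks["rfi"].to_numpy(float)
        idx = np.floor((L - start) / window).astype(int)
        binned: dict[float, float] = {}
        for i, v in zip(idx, rfi):
            b = start + i * window
            binned[b] = binned.get(b, 0.0) + v
        rows[sample] = binned
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return table[sorted(table.columns)]


def _mean_pairwise_similarity(table: pd.DataFrame) -> float:
    if len(table) < 2:
        return 0.0
    d = pdist(table.to_numpy(float), metric="braycurtis")
    d = d[np.isfinite(d)]
    return float(1.0 - d.mean()) if d.size else 0.0


def bin_fragments(
    profiles: Mapping[str, pd.DataFrame],
    window: float = 3.0,
    shift: float = 0.1,
    anchor: float = 100.0,
) -> BinningResult:
    """Bin fragment lengths into fixed-width windows, choosing the frame
    (bin-grid offset) that maximizes mean pairwise sample similarity.

    Candidate frames are anchored at ``anchor + k * shift`` for
    ``k = 0 .. window/shift - 1``; within a frame every fragment falls into
    exactly one ``[start, start + window)`` bin. The selected frame's OTU
    table (samples x occupied bins, values = summed relative intensities)
    preserves each sample's total intensity. Ties go to the smallest
    offset.
    """
    if window <= 0 or shift <= 0 or shift > window:
        raise ValueError("need 0 < shift <= window")
    profiles = {
        s: (p.peaks if isinstance(p, FilteredProfile) else p)
        for s, p in profiles.items()
    }
    profiles = {s: p for s, p in profiles.items() if len(p) > 0}
    if not profiles:
        raise ValueError("no non-empty profiles to bin")
    n_frames = int(round(window / shift))
    offsets = np.round(np.arange(n_frames) * shift, 10)
    scores = {}
    best = None
    for off in offsets:
        table = _bin_table(profiles, window, anchor + off)
        score = _mean_pairwise_similarity(table)
        scores[float(off)] = score
        if best is None or score > best[0] + 1e-12:
            best = (score, float(off), table)
    _, offset, table = best
    return BinningResult(
        otu_table=table, offset=offset, window=window, anchor=anchor,
        frame_scores=pd.Series(scores).sort_index(),
    )


# ---------------------------------------------------------------------------
# Bray-Curtis and dendrograms
# ---------------------------------------------------------------------------


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity, BC = sum|x-y| / sum(x+y).

    Rows are samples. Pairs in which both samples are all-zero are
    undefined and returned as NaN with a warning.
    """
    x = table.to_numpy(float)
    if np.any(x < 0):
        raise ValueError("abundances must be >= 0")
    if len(table) < 2:
        raise ValueError("need >= 2 samples")
    zero_rows = ~x.any(axis=1)
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if zero_rows.any():
        warnings.warn("all-zero samples: some pairs undefined", stacklevel=2)
        zz = np.outer(zero_rows, zero_rows)
        d[zz] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


@dataclass
class DendrogramResult:
    """Agglomerative clustering of a dissimilarity matrix."""

    linkage_matrix: np.ndarray
    labels: tuple[str, ...]
    newick: str
    cophenetic: pd.DataFrame
    method: str
    trivial: bool = False


def _newick(node, labels, parent_height: float | None = None) -> str:
    # Ultrametric convention: every leaf sits at depth root_height / 2,
    # branch length = (parent merge height - node height) / 2.
    height = node.dist
    if node.is_leaf():
        name = labels[node.id]
        body = name
    else:
        left = _newick(node.left, labels, height)
        right = _newick(node.right, labels, height)
        body = f"({left},{right})"
    if parent_height is None:
        return f"{body};"
    return f"{body}:{(parent_height - height) / 2:.10g}"


def cluster_dendrogram(
    dm: pd.DataFrame,
    method: str = "average",
) -> DendrogramResult:
    """Hierarchical clustering (UPGMA by default) with Newick export.

    Accepts a square symmetric dissimilarity matrix; alternative linkages
    ``"complete"`` and ``"single"`` are supported. Fewer than 3 samples
    produce a trivial tree with a warning. Cophenetic distances are
    returned alongside.
    """
    if method not in ("average", "complete", "single"):
        raise ValueError(f"unsupported linkage {method!r}")
    labels = tuple(str(i) for i in dm.index)
    d = dm.to_numpy(float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    if np.isnan(d).any():
        raise ValueError("dissimilarity matrix contains undefined entries")
    if len(labels) < 3:
        warnings.warn("fewer than 3 samples: trivial tree", stacklevel=2)
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method=method)
    coph = squareform(cophenet(z))
    tree = to_tree(z)
    return DendrogramResult(
        linkage_matrix=z,
        labels=labels,
        newick=_newick(tree, labels),
        cophenetic=pd.DataFrame(coph, index=dm.index, columns=dm.index),
        method=method,
        trivial=len(labels) < 3,
    )


# ---------------------------------------------------------------------------
# Clade concordance with sample groupings
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceResult:
    """Fraction of label groups whose leaves form an exclusive clade."""

    fraction: float
    concordant: dict[str, bool] = field(default_factory=dict)
    n_groups: int = 0
    n_singletons: int = 0


def cluster_concordance(
    dendrogram: DendrogramResult,
    groups: Mapping[str, str],
) -> ConcordanceResult:
    """Test which label groups are monophyletic on the dendrogram.

    ``groups`` maps each leaf label to a group label. A multi-leaf group is
    concordant when some internal node's leaf set equals exactly the
    group's leaf set; singleton groups are trivially concordant and
    reported separately (they do not enter the fraction).
    """
    labels = dendrogram.labels
    missing = [leaf for leaf in labels if leaf not in groups]
    if missing:
        raise ValueError(f"no group for leaves {missing}")
    clades: set[frozenset] = set()

    def collect(node) -> frozenset:
        if node.is_leaf():
            s = frozenset([labels[node.id]])
        else:
            s = collect(node.left) | collect(node.right)
        clades.add(s)
        return s

    collect(to_tree(dendrogram.linkage_matrix))

    members: dict[str, set] = {}
    for leaf, g in groups.items():
        if leaf in labels:
            members.setdefault(g, set()).add(leaf)
    concordant = {}
    n_singletons = 0
    for g, leaves in sorted(members.items()):
        if len(leaves) == 1:
            n_singletons += 1
            continue
        concordant[g] = frozenset(leaves) in clades
    frac = (sum(concordant.values()) / len(concordant)) if concordant else 1.0
    return ConcordanceResult(
        fraction=float(frac), concordant=concordant,
        n_groups=len(concordant), n_singletons=n_singletons,
    )
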
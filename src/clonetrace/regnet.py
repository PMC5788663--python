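"""PWM promoter-affinity scoring, TF/miRNA activity inference and key-driver analysis.

Transcription-factor activity is inferred indirectly from its footprint:
per gene, a position weight matrix (PWM) is scanned over the accessible
cis-regulatory window to obtain a total binding affinity; per sample, the
genome-wide expression profile is regressed on that affinity vector and
the slope is read as the TF's activity in that sample.  Functional
targets are genes combining high affinity with expression significantly
correlated to the inferred activity.  miRNA activity uses the same
regression with a binary target-membership indicator (repression shows
up as a negative slope).  Key-driver analysis ranks nodes of a directed
regulatory network by the hypergeometric enrichment of their downstream
neighborhood for a gene signature of interest.

Affinity scoring sums the likelihood ratio of the PWM against a uniform
background over every accessible site on both strands (a TRAP-like
soft-count rather than thresholded hits), which keeps the downstream
regression well-posed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PWM:
    """Column-stochastic position weight matrix (rows A, C, G, T)."""

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 0.5

    @classmethod
    def from_counts(cls, tf_name: str, counts: np.ndarray, pseudocount: float = 0.5) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] != 4 or counts.shape[1] < 4:
            raise ValueError("counts must be 4 x L with L >= 4")
        m = counts + pseudocount
        m /= m.sum(axis=0, keepdims=True)
        return cls(tf_name=tf_name, matrix=m, pseudocount=pseudocount)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PWM":
        return PWM(self.tf_name, self.matrix[::-1, ::-1].copy(), self.pseudocount)


@dataclass
class CisWindow:
    """Accessible cis-regulatory sequence around a gene's promoter."""

    gene: str
    sequence: str
    accessible_mask: Optional[np.ndarray] = None  # bool per position; None = all open
    window_kb: int = 1

    def __post_init__(self):
        if self.accessible_mask is not None:
            self.accessible_mask = np.asarray(self.accessible_mask, dtype=bool)
            if len(self.accessible_mask) != len(self.sequence):
                raise ValueError("accessible_mask length must equal sequence length")
        if not 1 <= self.window_kb <= 10:
            raise ValueError("window_kb must lie in 1..10")


@dataclass
class ActivityMatrix:
    """Inferred regulator activities (regulators x samples) plus method metadata."""

    values: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def regulators(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def read_jaspar(path: str | Path, pseudocount: float = 0.5) -> list[PWM]:
    """Read JASPAR-format count matrices via Biopython."""
    from Bio import motifs

    pwms = []
    with open(path) as fh:
        for m in motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            name = m.name or m.matrix_id
            pwms.append(PWM.from_counts(name, counts, pseudocount))
    return pwms


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_INDEX.get(b, 4) for b in seq.upper()), dtype=np.int64,
                       count=len(seq))


def promoter_affinity(pwm: PWM, window: CisWindow) -> float:
    """Total binding affinity of a TF over an accessible window.

    Sum over all sliding positions, on both strands, of the PWM
    likelihood ratio against a uniform (0.25) background.  Sites whose
    span touches a masked position contribute nothing; ambiguous bases
    (N) score as background.  Returns 0 (with a warning) when the
    sequence is shorter than the motif.
    """
    L = pwm.length
    n = len(window.sequence)
    if n < L:
        warnings.warn(f"window for {window.gene} shorter than motif ({n} < {L}); affinity 0")
        return 0.0
    idx = _encode(window.sequence)
    n_sites = n - L + 1
    if window.accessible_mask is not None:
        open_count = np.convolve(window.accessible_mask.astype(int), np.ones(L, dtype=int),
                                 mode="valid")
        site_ok = open_count == L
    else:
        site_ok = np.ones(n_sites, dtype=bool)
    if not site_ok.any():
        return 0.0

    total = 0.0
    for mat in (pwm.matrix, pwm.reverse_complement().matrix):
        ratios = np.vstack([np.concatenate([mat[:, j] / 0.25, [1.0]]) for j in range(L)])
        lr = np.ones(n_sites)
        for j in range(L):
            lr *= ratios[j][idx[j:j + n_sites]]
        total += float(lr[site_ok].sum())
    return total


def affinity_table(pwms: Sequence[PWM], windows: Sequence[CisWindow]) -> pd.DataFrame:
    """TFs x genes matrix of total promoter affinities."""
    data = {w.gene: [promoter_affinity(p, w) for p in pwms] for w in windows}
    return pd.DataFrame(data, index=[p.tf_name for p in pwms])


def _slopes(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS slope (with intercept) of each column of y on x."""
    xc = x - x.mean()
    denom = float(xc @ xc)
    return (xc @ (y - y.mean(axis=0))) / denom


def infer_tf_activity(expression: pd.DataFrame, affinities: pd.DataFrame) -> ActivityMatrix:
    """Per-sample TF activities by regressing expression on promoter affinity.

    ``expression`` is genes x samples, ``affinities`` is TFs x genes over
    the same genes.  For each sample and TF, the activity is the slope of
    a simple linear regression (with intercept) of that sample's
    expression across genes on the TF's affinity vector.  TFs with a
    zero-variance affinity vector are dropped with a warning.
    """
    genes = expression.index
    aff = affinities.reindex(columns=genes)
    if aff.isna().any().any():
        raise ValueError("affinity vector missing some expression genes")
    y = expression.to_numpy(dtype=float)
    rows, kept = [], []
    for tf in aff.index:
        x = aff.loc[tf].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"TF {tf}: zero-variance affinity vector; activity undefined")
            continue
        rows.append(_slopes(y, x))
        kept.append(tf)
    values = pd.DataFrame(rows, index=kept, columns=expression.columns)
    return ActivityMatrix(values=values, metadata={"method": "ols_slope_per_sample"})


def _activity_correlation(expression: pd.DataFrame, activity: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Pearson r and two-sided p of each gene's expression with a TF activity across samples."""
    y = expression.to_numpy(dtype=float)
    a = activity.reindex(expression.columns).to_numpy(dtype=float)
    n = len(a)
    if n < 3:
        raise ValueError("need at least 3 samples for correlation testing")
    ac = a - a.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    denom = np.sqrt((yc ** 2).sum(axis=1) * (ac ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ ac) / denom
    r = np.clip(np.nan_to_num(r), -0.9999999999, 0.9999999999)
    tstat = r * np.sqrt((n - 2) / (1 - r ** 2))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    return (pd.Series(r, index=expression.index), pd.Series(p, index=expression.index))


def tf_targets(
    affinity_vector: pd.Series,
    activities: pd.Series,
    expression: pd.DataFrame,
    affinity_quantile: float = 0.9,
    fdr: float = 0.05,
) -> set[str]:
    """Functional targets: high affinity AND activity-correlated expression.

    The intersection of genes above the ``affinity_quantile`` of the
    affinity vector with genes whose expression-activity Pearson
    correlation passes Benjamini-Hochberg at ``fdr``.
    """
    genes = expression.index
    aff = affinity_vector.reindex(genes)
    if affinity_quantile <= 0:
        high = set(genes)
    else:
        cut = aff.quantile(affinity_quantile)
        high = set(genes[aff > cut])
    if fdr >= 1:
        correlated = set(genes)
    else:
        _, p = _activity_correlation(expression, activities)
        reject, _, _, _ = multipletests(p.to_numpy(), alpha=fdr, method="fdr_bh")
        correlated = set(genes[reject])
    return high & correlated


def select_window(
    expression: pd.DataFrame,
    affinities_by_window_kb: Mapping[int, pd.DataFrame],
    affinity_quantile: float = 0.9,
    fdr: float = 0.05,
    enrichment_alpha: float = 0.05,
) -> pd.DataFrame:
    """Choose, per TF, the cis-window size whose affinities best explain expression.

    For each window size k the TF activities are inferred, high-affinity
    genes (top decile) are intersected with activity-correlated genes
    (BH FDR < ``fdr``), and the overlap is scored by hypergeometric
    enrichment; the k with the smallest enrichment p wins (ties to the
    smaller k).  TFs for which no window reaches ``enrichment_alpha`` are
    flagged unselected (window NaN).
    """
    n_genes = len(expression.index)
    if n_genes < 20:
        raise ValueError("window selection needs at least 20 genes")
    ks = sorted(affinities_by_window_kb)
    tfs = list(affinities_by_window_kb[ks[0]].index)
    best: dict[str, tuple[float, Optional[int]]] = {tf: (np.inf, None) for tf in tfs}
    genes = set(expression.index)
    for k in ks:
        aff_k = affinities_by_window_kb[k]
        act = infer_tf_activity(expression, aff_k)
        for tf in tfs:
            if tf not in act.values.index:
                continue
            aff = aff_k.loc[tf].reindex(expression.index)
            cut = aff.quantile(affinity_quantile)
            high = set(expression.index[aff > cut])
            _, pvals = _activity_correlation(expression, act.values.loc[tf])
            reject, _, _, _ = multipletests(pvals.to_numpy(), alpha=fdr, method="fdr_bh")
            correlated = set(expression.index[reject])
            p = geneset_enrichment(high, correlated, genes)
            if p < best[tf][0]:
                best[tf] = (p, k)
    rows = []
    for tf in tfs:
        p, k = best[tf]
        selected = p <= enrichment_alpha
        rows.append((tf, k if selected else np.nan, p if np.isfinite(p) else np.nan, selected))
    return pd.DataFrame(rows, columns=["tf", "window_kb", "enrichment_p", "selected"]).set_index("tf")


def infer_mirna_activity(
    expression: pd.DataFrame,
    mirna_target_sets: Mapping[str, Iterable[str]],
    min_targets: int = 100,
) -> ActivityMatrix:
    """Per-sample miRNA activities from target-set membership regression.

    miRNAs with fewer than ``min_targets`` targets (among the expression
    genes) are dropped for robustness.  Activity is the OLS slope of a
    sample's expression on the binary target indicator, which equals the
    mean expression difference targets minus non-targets; active
    repressors therefore score negative.
    """
    genes = list(expression.index)
    gene_set = set(genes)
    y = expression.to_numpy(dtype=float)
    rows, kept, sizes = [], [], {}
    for mir, targets in mirna_target_sets.items():
        tset = set(targets) & gene_set
        if len(tset) < min_targets:
            logger.info("miRNA %s dropped: %d targets < %d", mir, len(tset), min_targets)
            continue
        x = np.fromiter((g in tset for g in genes), dtype=float, count=len(genes))
        rows.append(_slopes(y, x))
        kept.append(mir)
        sizes[mir] = len(tset)
    if not kept:
        warnings.warn("no miRNA passed the minimum-target filter")
    values = pd.DataFrame(rows, index=kept, columns=expression.columns)
    return ActivityMatrix(values=values, metadata={"target_set_size": sizes,
                                                   "min_targets": min_targets})


def key_driver_analysis(
    network: nx.DiGraph,
    signature_genes: Iterable[str],
    neighborhood_depth: int = 2,
) -> pd.DataFrame:
    """Rank candidate drivers of a gene signature on a directed network.

    Candidates are the signature genes plus all nodes within
    ``neighborhood_depth`` (edge direction ignored for candidate
    gathering).  Each candidate's downstream set is every node reachable
    within ``neighborhood_depth`` directed hops; its enrichment p is the
    hypergeometric upper tail of the downstream overlap with the
    signature against all network nodes; adjusted p is Bonferroni over
    candidates.  Ranked by p, then downstream size (descending).
    """
    sig = set(signature_genes)
    if not sig:
        raise ValueError("signature gene set is empty")
    present = sig & set(network.nodes)
    dropped = sig - present
    if dropped:
        warnings.warn(f"{len(dropped)} signature genes absent from network: "
                      f"{sorted(dropped)[:5]}...")
    if not present:
        raise ValueError("no signature gene is present in the network")

    undirected = network.to_undirected(as_view=True)
    candidates: set[str] = set()
    for g in present:
        candidates.update(nx.single_source_shortest_path_length(
            undirected, g, cutoff=neighborhood_depth))
    universe = set(network.nodes)
    rows = []
    for node in sorted(candidates):
        downstream = set(nx.single_source_shortest_path_length(
            network, node, cutoff=neighborhood_depth)) - {node}
        p = geneset_enrichment(downstream, present, universe) if downstream else 1.0
        rows.append((node, len(downstream), p))
    n_cand = len(rows)
    df = pd.DataFrame(rows, columns=["driver", "n_downstream", "enrichment_p"])
    df["adjusted_p"] = (df["enrichment_p"] * n_cand).clip(upper=1.0)
    df = df.sort_values(["enrichment_p", "n_downstream", "driver"],
                        ascending=[True, False, True]).reset_index(drop=True)
    return df


def geneset_enrichment(query_set: Iterable[str], annotation_set: Iterable[str],
                       universe: Iterable[str]) -> float:
    """Hypergeometric upper-tail p of the overlap of two gene sets in a universe."""
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    q = set(query_set) & uni
    a = set(annotation_set) & uni
    k = len(q & a)
    return float(stats.hypergeom.sf(k - 1, len(uni), len(a), len(q)))


def read_edge_list(path: str | Path) -> nx.DiGraph:
    """Directed network from a two-column (source, target) TSV; '#' comments allowed."""
    g = nx.DiGraph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed edge line {line!r}")
            g.add_edge(parts[0], parts[1])
    return g


def write_edge_list(network: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(network.edges):
            fh.write(f"{u}\t{v}\n")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """GMT-like gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gene_sets(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")
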
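"""Synthetic data generators mirroring the statistical structure of the analyses.

Every generator is seed-deterministic and returns a machine-readable
truth record sufficient to score the downstream operation without
re-deriving ground truth:

* :func:`simulate_clonal_sequencing` -- a clone tree with sector-specific
  clone fractions, sampled to read counts binomially at configurable
  depth (negative-binomial depth draws avoid unrealistically uniform
  coverage).
* :func:`simulate_growth` -- exponential growth as a passage series with
  Gaussian noise on cumulative PDL.
* :func:`simulate_genome_and_mutations` -- a toy genome plus emergent /
  pre-existing mutation sets where the emergent set mixes an
  alkylator-signature channel (C>T at NpCpC/NpCpT) with uniform
  background at a configurable fraction.
* :func:`simulate_regulatory_data` and :func:`simulate_driver_network` --
  expression built as affinity x activity (+ miRNA repression + noise)
  and a directed network with planted key drivers.

Default parameters follow the case study being emulated: sequencing
depth 2000x, clone ratios around 2:1 / 3:1, doubling time 2.24 days over
a 70-day passage series, and an 80% signature channel for
treatment-emergent mutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dynamics import GrowthRecord
from .variant_io import Sample, SampleSheet, VariantCall


@dataclass
class CloneTreeSpec:
    """A labelled clone tree with per-sector clone fractions.

    ``parents`` maps clone -> parent clone (None for the founding clone);
    a clone carries its own private variants plus all ancestral ones.
    ``sector_fractions`` maps sector -> {clone: cell fraction}; per-sector
    fractions may sum to < 1, the remainder being normal cells.
    """

    parents: dict[str, Optional[str]]
    n_private: dict[str, int]
    sector_fractions: dict[str, dict[str, float]]
    ploidy: int = 2
    het_dosage: int = 1

    def __post_init__(self):
        for sector, fr in self.sector_fractions.items():
            if any(f < 0 for f in fr.values()):
                raise ValueError(f"sector {sector}: negative clone fraction")
            if sum(fr.values()) > 1 + 1e-9:
                raise ValueError(f"sector {sector}: clone fractions sum to > 1")
            unknown = set(fr) - set(self.parents)
            if unknown:
                raise ValueError(f"sector {sector}: unknown clones {unknown}")

    def lineage(self, clone: str) -> list[str]:
        out, cur = [], clone
        while cur is not None:
            out.append(cur)
            cur = self.parents[cur]
        return out


def default_clone_spec() -> CloneTreeSpec:
    """Trunk plus two mutually exclusive subclones across three sectors.

    Emulates a recurrent tumor in which two sibling subclones partition
    the cellularity at roughly 2:1 (sectors A, C) and 3:1 (sector B).
    """
    return CloneTreeSpec(
        parents={"trunk": None, "cloneA": "trunk", "cloneB": "trunk"},
        n_private={"trunk": 2, "cloneA": 3, "cloneB": 3},
        sector_fractions={
            "sectorA": {"cloneA": 2 / 3, "cloneB": 1 / 3},
            "sectorB": {"cloneA": 3 / 4, "cloneB": 1 / 4},
            "sectorC": {"cloneA": 2 / 3, "cloneB": 1 / 3},
        },
    )


def simulate_clonal_sequencing(
    spec: CloneTreeSpec,
    seed: int = 0,
    depth: float = 2000,
    depth_dispersion: float = 20.0,
    mode: str = "prevalence",
) -> tuple[list[VariantCall], SampleSheet, dict]:
    """Sample a per-sector variant table from a clone tree.

    The expected allele VAF of variant v in sector s is
    sum over clones carrying v of fraction * het_dosage / ploidy; observed
    alt reads are Binomial(depth draw, expected VAF) with the depth drawn
    per site from a negative binomial around the mean depth.

    ``mode='prevalence'`` reports VAF x ploidy/het_dosage (capped at 1),
    the cellular-prevalence convention under which two mutually exclusive
    heterozygous clones have VAFs summing to ~1; ``mode='allele_fraction'``
    reports the raw read fraction together with the read counts.
    """
    if mode not in ("prevalence", "allele_fraction"):
        raise ValueError(f"unknown reporting mode {mode!r}")
    rng = np.random.default_rng(seed)
    clones = sorted(spec.parents)
    variants: list[tuple[str, str]] = []  # (variant_key parts resolved later, clone)
    pos = 1000
    variant_clone: dict[str, str] = {}
    coords: dict[str, tuple[str, int]] = {}
    for clone in clones:
        for i in range(spec.n_private[clone]):
            key = f"sim1:{pos}:A:G"
            variant_clone[key] = clone
            coords[key] = ("sim1", pos)
            pos += 10
    scale = spec.het_dosage / spec.ploidy
    expected: dict[str, dict[str, float]] = {}
    for sector, fractions in spec.sector_fractions.items():
        ev = {}
        for key, clone in variant_clone.items():
            f = sum(fr for cl, fr in fractions.items() if clone in spec.lineage(cl))
            ev[key] = f * scale
        expected[sector] = ev

    calls: list[VariantCall] = []
    raw_counts: dict[str, dict[str, tuple[int, int]]] = {}
    for sector in sorted(spec.sector_fractions):
        raw_counts[sector] = {}
        for key, clone in variant_clone.items():
            evaf = expected[sector][key]
            if evaf == 0 or depth <= 0:
                continue
            p_nb = depth_dispersion / (depth_dispersion + depth)
            d = int(rng.negative_binomial(depth_dispersion, p_nb))
            if d == 0:
                continue
            alt = int(rng.binomial(d, evaf))
            raw_counts[sector][key] = (alt, d)
            if alt == 0:
                continue
            chrom, p = coords[key]
            if mode == "prevalence":
                vaf = min(1.0, round(alt / d / scale, 3))
                alt_reads = dep = None
            else:
                from .variant_io import vaf_from_reads

                vaf = vaf_from_reads(alt, d)
                alt_reads, dep = alt, d
            calls.append(VariantCall(
                chrom=chrom, pos=p, ref_allele="A", alt_allele="G",
                vaf=vaf, sample_id=sector, gene=clone,
                alt_reads=alt_reads, depth=dep,
            ))
    sheet = SampleSheet([
        Sample(sample_id=s, patient_id="SIM", specimen="bulk", sector=s)
        for s in sorted(spec.sector_fractions)
    ])
    truth = {
        "clone_of_variant": variant_clone,
        "expected_allele_vaf": expected,
        "occupancy": {key: sorted(s for s in expected if expected[s][key] > 0)
                      for key in variant_clone},
        "raw_counts": raw_counts,
        "mode": mode,
        "seed": seed,
    }
    return calls, sheet, truth


def simulate_growth(
    c: float = 2.24,
    t_onset: float = 0.0,
    noise_sd: float = 0.2,
    n_records: int = 20,
    interval_days: float = 3.5,
    cells_seeded: float = 1e5,
    seed: int = 0,
) -> tuple[list[GrowthRecord], dict]:
    """Passage series under exponential growth with log-scale noise.

    Cumulative PDL at passage time t is (t - t_onset)/c + N(0, noise_sd);
    per-passage seeded/harvested counts are reconstructed from the PDL
    increments.  A draw implying a negative increment is clipped to zero
    growth with a warning.
    """
    if c <= 0 or n_records < 1:
        raise ValueError("need positive doubling time and at least one record")
    rng = np.random.default_rng(seed)
    times = t_onset + interval_days * np.arange(1, n_records + 1)
    cum = (times - t_onset) / c + rng.normal(0.0, noise_sd, size=n_records)
    records, prev = [], 0.0
    for t, cp in zip(times, cum):
        inc = cp - prev
        if inc < 0:
            warnings.warn(f"negative PDL increment at day {t:.1f}; clipped to 0")
            inc = 0.0
        harvested = cells_seeded * 2.0 ** inc
        records.append(GrowthRecord(time=float(t), cells_seeded=cells_seeded,
                                    cells_harvested=float(harvested)))
        prev += inc
    truth = {"c": c, "t_onset": t_onset, "noise_sd": noise_sd, "seed": seed}
    return records, truth


@dataclass(frozen=True)
class SimulatedMutation:
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str
    channel: str        # "signature" | "background"


def simulate_genome_and_mutations(
    genome_length: int = 20000,
    n_emergent: int = 200,
    n_preexisting: int = 200,
    signature_mixture: float = 0.8,
    gc_content: float = 0.5,
    seed: int = 0,
    chrom: str = "sim1",
) -> tuple[dict[str, str], list[SimulatedMutation], list[SimulatedMutation], dict]:
    """Toy genome plus emergent and pre-existing substitution sets.

    Emergent mutations are drawn from the alkylator-signature channel
    (C>T at a site whose pyrimidine-strand 3' neighbor is C or T, on
    either strand) with probability ``signature_mixture`` and uniformly
    otherwise; pre-existing mutations are always uniform.  Contexts are
    recomputable from the returned reference.
    """
    if not 0 <= signature_mixture <= 1:
        raise ValueError("signature_mixture must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    bases = np.array(list("ACGT"))
    seq_arr = rng.choice(bases, size=genome_length, p=p)
    seq = "".join(seq_arr)

    # positions (0-based) eligible for the signature channel
    is_c = seq_arr == "C"
    is_g = seq_arr == "G"
    nxt = np.roll(seq_arr, -1)
    prv = np.roll(seq_arr, 1)
    plus_sig = is_c & np.isin(nxt, list("CT"))
    minus_sig = is_g & np.isin(prv, list("AG"))  # revcomp: C with 3' C/T on minus
    eligible = np.flatnonzero(plus_sig | minus_sig)
    eligible = eligible[(eligible >= 1) & (eligible <= genome_length - 2)]

    used: set[int] = set()

    def draw_signature() -> SimulatedMutation:
        while True:
            i = int(rng.choice(eligible))
            if i not in used:
                used.add(i)
                break
        ref = seq[i]
        alt = "T" if ref == "C" else "A"
        return SimulatedMutation(chrom, i + 1, ref, alt, "signature")

    def draw_background() -> SimulatedMutation:
        while True:
            i = int(rng.integers(1, genome_length - 1))
            if i not in used:
                used.add(i)
                break
        ref = seq[i]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return SimulatedMutation(chrom, i + 1, ref, alt, "background")

    emergent = [
        draw_signature() if rng.random() < signature_mixture else draw_background()
        for _ in range(n_emergent)
    ]
    preexisting = [draw_background() for _ in range(n_preexisting)]
    truth = {
        "signature_mixture": signature_mixture,
        "n_signature_emergent": sum(m.channel == "signature" for m in emergent),
        "seed": seed,
    }
    return {chrom: seq}, emergent, preexisting, truth


@dataclass
class RegulatorySim:
    """Planted regulatory model: expression = affinity x activity + repression + noise."""

    expression: pd.DataFrame                  # genes x samples
    affinities: pd.DataFrame                  # TFs x genes
    tf_activities: pd.DataFrame               # TFs x samples (truth)
    tf_targets: dict[str, set[str]]           # truth target sets
    mirna_target_sets: dict[str, set[str]]
    mirna_activities: pd.DataFrame            # miRNAs x samples (truth, negative)
    truth: dict = field(default_factory=dict)


def simulate_regulatory_data(
    n_genes: int = 2000,
    n_tfs: int = 3,
    n_samples: int = 20,
    noise_sd: float = 0.5,
    targets_per_tf: int = 100,
    n_mirnas: int = 2,
    targets_per_mirna: int = 150,
    seed: int = 0,
) -> RegulatorySim:
    """Linear-Gaussian regulatory model with planted TF targets and miRNA repressors.

    Each TF gets a disjoint block of ``targets_per_tf`` genes with high
    promoter affinity (U(2, 4)); all other genes carry near-zero baseline
    affinity (U(0, 0.05)), reflecting promoters lacking the motif.  TF
    activities are N(0, 1) per sample; miRNA repression strengths are
    U(0.5, 1.5) per sample (so true miRNA activity is their negative).
    """
    if n_tfs * targets_per_tf + n_mirnas * targets_per_mirna > n_genes:
        raise ValueError("planted target blocks exceed the gene universe")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"S{j:02d}" for j in range(n_samples)]
    tfs = [f"TF{k}" for k in range(n_tfs)]

    aff = pd.DataFrame(rng.uniform(0.0, 0.05, size=(n_tfs, n_genes)),
                       index=tfs, columns=genes)
    tf_target_sets: dict[str, set[str]] = {}
    start = 0
    for tf in tfs:
        block = genes[start:start + targets_per_tf]
        aff.loc[tf, block] = rng.uniform(2.0, 4.0, size=targets_per_tf)
        tf_target_sets[tf] = set(block)
        start += targets_per_tf

    acts = pd.DataFrame(rng.normal(0.0, 1.0, size=(n_tfs, n_samples)),
                        index=tfs, columns=samples)

    mirnas = [f"MIR{k}" for k in range(n_mirnas)]
    mirna_sets: dict[str, set[str]] = {}
    mir_strength = pd.DataFrame(rng.uniform(0.5, 1.5, size=(n_mirnas, n_samples)),
                                index=mirnas, columns=samples)
    for mir in mirnas:
        block = genes[start:start + targets_per_mirna]
        mirna_sets[mir] = set(block)
        start += targets_per_mirna

    expr = aff.T.to_numpy() @ acts.to_numpy()
    for mir in mirnas:
        indicator = np.fromiter((g in mirna_sets[mir] for g in genes), dtype=float,
                                count=n_genes)
        expr -= np.outer(indicator, mir_strength.loc[mir].to_numpy())
    expr = expr + rng.normal(0.0, noise_sd, size=expr.shape)
    expression = pd.DataFrame(expr, index=genes, columns=samples)

    return RegulatorySim(
        expression=expression,
        affinities=aff,
        tf_activities=acts,
        tf_targets=tf_target_sets,
        mirna_target_sets=mirna_sets,
        mirna_activities=-mir_strength,
        truth={"noise_sd": noise_sd, "seed": seed},
    )


def windowed_affinities(
    sim: RegulatorySim, true_window_kb: int = 5, seed: int = 0
) -> dict[int, pd.DataFrame]:
    """Affinity tables for window sizes 1..10 kb where only one size carries signal.

    The true window returns the planted affinities; every other size gets
    a gene-permuted copy, emulating motif signal diluted away by a wrong
    cis-window choice.
    """
    rng = np.random.default_rng(seed)
    out = {}
    genes = list(sim.affinities.columns)
    for k in range(1, 11):
        if k == true_window_kb:
            out[k] = sim.affinities.copy()
        else:
            perm = rng.permutation(len(genes))
            shuffled = sim.affinities.to_numpy()[:, perm]
            out[k] = pd.DataFrame(shuffled, index=sim.affinities.index, columns=genes)
    return out


def simulate_driver_network(
    module_size: int = 30,
    n_background: int = 60,
    n_background_edges: int = 150,
    seed: int = 0,
):
    """Directed network with two planted drivers over disjoint gene modules.

    Driver D1 regulates module-1 genes and D2 module-2 genes directly;
    background nodes are wired at random (including occasional edges into
    the modules).  Returns (graph, drivers, modules); the signature set
    of interest is typically module 1.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.DiGraph()
    mod1 = [f"M1_{i:02d}" for i in range(module_size)]
    mod2 = [f"M2_{i:02d}" for i in range(module_size)]
    bg = [f"B{i:03d}" for i in range(n_background)]
    g.add_nodes_from(mod1 + mod2 + bg + ["D1", "D2"])
    g.add_edges_from(("D1", m) for m in mod1)
    g.add_edges_from(("D2", m) for m in mod2)
    targets = bg + mod1 + mod2
    for _ in range(n_background_edges):
        u = bg[int(rng.integers(len(bg)))]
        v = targets[int(rng.integers(len(targets)))]
        if u != v:
            g.add_edge(u, v)
    return g, ("D1", "D2"), {"module1": set(mod1), "module2": set(mod2)}


def write_fasta(reference: Mapping[str, str], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()]
    SeqIO.write(records, str(path), "fasta")
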
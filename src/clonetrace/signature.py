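"""Strand-aware trinucleotide context handling and alkylator-signature classification.

Alkylating chemotherapies such as temozolomide leave a characteristic
mutational footprint (Signature 11): C:G>T:A transitions concentrated at
NpCpC and NpCpT trinucleotides.  Contexts are normalized so the mutated
base is always the pyrimidine: a G>A change is reported as C>T on the
opposite strand, together with the reverse-complemented 3-mer.  CpG
contexts (3' neighbor G) are excluded from the signature because C>T at
CpG is the hallmark of spontaneous 5-methylcytosine deamination instead.

Contexts can be computed from a reference sequence
(:func:`trinucleotide_context`) or ingested verbatim from an annotated
table printing them as e.g. ``"G>A (CCG+)"`` (:func:`parse_printed_context`),
where the sign is the genomic strand carrying the pyrimidine-centered 3-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

PURINES = "AG"
PYRIMIDINES = "CT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MutationContext:
    """Pyrimidine-normalized single-base substitution context."""

    trinucleotide: str   # 3-mer, central base is the mutated pyrimidine
    strand: str          # genomic strand ('+' or '-') carrying the pyrimidine
    base_change: str     # normalized, e.g. "C>T"

    def __post_init__(self):
        if len(self.trinucleotide) != 3 or self.trinucleotide[1] not in PYRIMIDINES:
            raise ValueError(f"bad normalized trinucleotide {self.trinucleotide!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        ref, _, alt = self.base_change.partition(">")
        if ref != self.trinucleotide[1] or len(alt) != 1:
            raise ValueError(f"base_change {self.base_change!r} inconsistent with context")

    @property
    def is_transition(self) -> bool:
        return self.base_change in ("C>T", "T>C")

    @property
    def is_cpg(self) -> bool:
        return self.trinucleotide[1] == "C" and self.trinucleotide[2] == "G"


@dataclass
class SignatureCounts:
    """2x2 split of signature-positive / -negative variants by exposure group."""

    emergent_sig: int
    emergent_nonsig: int
    preexisting_sig: int
    preexisting_nonsig: int
    p_two_sided: float

    @property
    def table(self) -> tuple[int, int, int, int]:
        return (self.emergent_sig, self.emergent_nonsig,
                self.preexisting_sig, self.preexisting_nonsig)


def trinucleotide_context(
    reference: Mapping[str, str],
    chrom: str,
    pos: int,
    ref_allele: str,
    alt_allele: str,
) -> Optional[MutationContext]:
    """Extract the normalized context of a substitution from a reference.

    ``pos`` is 1-based.  Returns ``None`` ("not applicable") for indels.
    Raises ``ValueError`` on reference mismatch or a position at the
    contig edge where no 3-mer exists.
    """
    if len(ref_allele) != 1 or len(alt_allele) != 1:
        return None
    seq = reference[chrom]
    if not 2 <= pos <= len(seq) - 1:
        raise ValueError(f"{chrom}:{pos} too close to contig edge for a 3-mer")
    if seq[pos - 1].upper() != ref_allele.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {ref_allele}, "
            f"found {seq[pos - 1]}"
        )
    tri = seq[pos - 2:pos + 1].upper()
    if ref_allele.upper() in PURINES:
        return MutationContext(
            trinucleotide=revcomp(tri), strand="-",
            base_change=f"{revcomp(ref_allele.upper())}>{revcomp(alt_allele.upper())}",
        )
    return MutationContext(trinucleotide=tri, strand="+",
                           base_change=f"{ref_allele.upper()}>{alt_allele.upper()}")


def parse_printed_context(base_change: str, context: str) -> Optional[MutationContext]:
    """Normalize a printed (base change, context) annotation.

    ``context`` is a 3-mer plus strand sign, e.g. ``"CCG+"`` -- the 3-mer
    is already pyrimidine-centered and the sign names the genomic strand
    it lies on.  Purine-reported base changes (e.g. G>A) are complemented
    to the pyrimidine strand.  Returns ``None`` for indels or when no
    context is given.
    """
    if not context or not isinstance(context, str):
        return None
    ref, _, alt = base_change.partition(">")
    if len(ref) != 1 or len(alt) != 1:
        return None
    tri, strand = context[:3].upper(), context[3]
    if ref.upper() in PURINES:
        ref, alt = revcomp(ref.upper()), revcomp(alt.upper())
    if tri[1] != ref.upper():
        raise ValueError(
            f"context {context!r} central base does not match normalized change "
            f"{ref}>{alt}"
        )
    return MutationContext(trinucleotide=tri, strand=strand,
                           base_change=f"{ref.upper()}>{alt.upper()}")


def is_signature11(context: Optional[MutationContext]) -> bool:
    """True iff the change is C:G>T:A in an NpCpC or NpCpT context.

    CpG-context transitions are excluded (attributable to 5mC deamination),
    as are all non-C>T changes and indels (``None``).
    """
    if context is None:
        return False
    return context.base_change == "C>T" and context.trinucleotide[2] in "CT"


def count_signature(
    emergent_contexts: Iterable[Optional[MutationContext]],
    preexisting_contexts: Iterable[Optional[MutationContext]],
) -> SignatureCounts:
    """Tally signature-positive variants per exposure group and test enrichment.

    Indels (``None`` contexts) are excluded from both numerator and
    denominator.  The p-value is the two-sided Fisher exact test of the
    resulting 2x2 table.
    """
    def tally(contexts):
        pos = neg = 0
        for ctx in contexts:
            if ctx is None:
                continue
            if is_signature11(ctx):
                pos += 1
            else:
                neg += 1
        return pos, neg

    a, b = tally(emergent_contexts)
    c, d = tally(preexisting_contexts)
    return SignatureCounts(a, b, c, d, fisher_exact(a, b, c, d))


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Sums the hypergeometric probabilities of every table with the same
    margins whose point probability is at most that of the observed table
    (within relative tolerance 1e-7).  Computed in exact integer
    arithmetic, so it agrees with brute-force enumeration to the last bit.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, row2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - row2), min(col1, row1)
    # integer weights proportional to hypergeometric point probabilities
    weights = {k: comb(row1, k) * comb(row2, col1 - k) for k in range(lo, hi + 1)}
    obs = weights[a]
    # w <= obs * (1 + 1e-7), kept in exact integer arithmetic
    total = sum(weights.values())
    tail = sum(w for w in weights.values() if w * 10**7 <= obs * (10**7 + 1))
    return float(Fraction(tail, total))


def read_context_table(path: str | Path) -> pd.DataFrame:
    """Read an annotated-variant TSV with printed contexts.

    Expects columns [gene, chrom, pos, ref, alt, context] and optionally
    ``tmz_emergent`` (0/1).  Adds a ``mutation_context`` column holding
    the normalized :class:`MutationContext` (or None for indels/blank
    contexts) and ``signature11`` booleans.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}).fillna({"context": ""})
    required = {"gene", "chrom", "pos", "ref", "alt", "context"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    contexts = [
        parse_printed_context(f"{r.ref}>{r.alt}", r.context)
        for r in df.itertuples()
    ]
    df = df.copy()
    df["mutation_context"] = contexts
    df["signature11"] = [is_signature11(ctx) for ctx in contexts]
    return df


def count_signature_from_table(df: pd.DataFrame) -> SignatureCounts:
    """Apply :func:`count_signature` to a table read by :func:`read_context_table`."""
    if "tmz_emergent" not in df.columns:
        raise ValueError("table lacks a tmz_emergent column separating exposure groups")
    emergent = df[df["tmz_emergent"].astype(int) == 1]["mutation_context"]
    pre = df[df["tmz_emergent"].astype(int) == 0]["mutation_context"]
    return count_signature(emergent, pre)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (toy) reference FASTA into a contig -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
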
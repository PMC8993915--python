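"""DNA-barcode mitotype collapsing and diversity statistics.

Operates on aligned mitochondrial barcode sequences (typically the ~658 bp
COI fragment).  Sequences are collapsed into mitotypes — unique haplotypes
under a configurable missing-data policy — and summarized with Nei's
unbiased haplotype diversity h, per-site nucleotide diversity pi computed
from uncorrected p-distances with pairwise deletion, the maximum pairwise
divergence, and whole-alignment summary statistics (variable sites,
missing fraction, GC content).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "MISSING_STATES",
    "SequenceRecord",
    "BarcodeAlignment",
    "MitotypeSet",
    "DiversityStats",
    "AlignmentSummary",
    "read_fasta",
    "write_fasta",
    "collapse_mitotypes",
    "haplotype_diversity",
    "p_distance_matrix",
    "nucleotide_diversity",
    "alignment_summary",
    "diversity_stats",
    "format_percent",
]

ALPHABET = set("ACGTN-?")
MISSING_STATES = set("N-?")
COI_LENGTH = 658  # canonical COI barcode length; deviation triggers a warning only


class AlignmentError(ValueError):
    """Invalid alignment input."""


def _normalize_seq(sid: str, seq: str) -> str:
    s = str(seq).upper()
    if not s:
        raise AlignmentError(f"{sid}: empty sequence")
    extra = set(s) - ALPHABET
    if extra:
        # IUPAC ambiguity codes carry little information at barcode scale
        warnings.warn(
            f"{sid}: ambiguity codes {sorted(extra)} mapped to N", stacklevel=3
        )
        s = "".join(c if c in ALPHABET else "N" for c in s)
    return s


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", _normalize_seq(self.id, self.seq))


@dataclass
class BarcodeAlignment:
    """Equal-length sequence records with unique ids."""

    records: list

    def __post_init__(self):
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            bad = sorted({r.id for r in self.records if len(r.seq) != len(self.records[0].seq)})
            raise AlignmentError(f"ragged alignment; offending ids: {bad}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate record ids: {dupes}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    def to_matrix(self) -> np.ndarray:
        """Character matrix (n × L, dtype '<U1')."""
        return np.array([list(r.seq) for r in self.records])


def read_fasta(path) -> BarcodeAlignment:
    records = [SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    aln = BarcodeAlignment(records)
    if aln.length != COI_LENGTH:
        warnings.warn(
            f"alignment length {aln.length} differs from the canonical {COI_LENGTH} bp COI barcode",
            stacklevel=2,
        )
    return aln


def write_fasta(aln: BarcodeAlignment, path) -> None:
    recs = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in aln.records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class MitotypeSet:
    """Collapse of an alignment into unique mitotypes.

    ``mitotypes`` maps each representative sequence (the first member seen)
    to the list of member record ids, in input order.
    """

    mitotypes: list  # list of (representative_seq, [member ids])
    n: int = field(init=False)

    def __post_init__(self):
        self.n = sum(len(m) for _, m in self.mitotypes)
        if self.n == 0:
            raise AlignmentError("empty mitotype set")

    @property
    def k(self) -> int:
        return len(self.mitotypes)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for _, m in self.mitotypes])

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n


def _compatible(a: str, b: str) -> bool:
    return all(x == y or x in MISSING_STATES or y in MISSING_STATES for x, y in zip(a, b))


def collapse_mitotypes(aln: BarcodeAlignment, missing_policy: str = "strict") -> MitotypeSet:
    """Collapse aligned sequences into unique mitotypes.

    ``strict``: sequences share a mitotype iff identical as strings (N, -
    and ? count as ordinary states).  ``wildcard``: a sequence joins the
    first existing mitotype whose representative matches it at every site
    where both are non-missing (greedy, input order).  Collapsing is
    idempotent and preserves member ids.
    """
    if missing_policy not in ("strict", "wildcard"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    clusters: list = []  # (representative, [ids])
    index: dict = {}
    for rec in aln.records:
        if missing_policy == "strict":
            pos = index.get(rec.seq)
            if pos is None:
                index[rec.seq] = len(clusters)
                clusters.append((rec.seq, [rec.id]))
            else:
                clusters[pos][1].append(rec.id)
        else:
            for rep, members in clusters:
                if _compatible(rep, rec.seq):
                    members.append(rec.id)
                    break
            else:
                clusters.append((rec.seq, [rec.id]))
    return MitotypeSet(clusters)


def haplotype_diversity(ms: MitotypeSet) -> float:
    """Nei's unbiased haplotype diversity h = n/(n−1) · (1 − Σ p_i²)."""
    n = ms.n
    if n < 2:
        raise AlignmentError("haplotype diversity requires n >= 2 sequences")
    return float(n / (n - 1) * (1.0 - np.sum(ms.frequencies**2)))


def p_distance_matrix(aln: BarcodeAlignment) -> tuple[np.ndarray, float]:
    """Pairwise uncorrected p-distances with pairwise deletion.

    Each distance is mismatches / mutually non-missing sites.  Pairs with
    no comparable site are NaN (flagged; an error only if every pair is
    empty).  Returns the symmetric matrix and its maximum.
    """
    M = aln.to_matrix()
    n = aln.n
    if n < 2:
        raise AlignmentError("need >= 2 sequences")
    ok = ~np.isin(M, sorted(MISSING_STATES))
    D = np.zeros((n, n))
    any_pair = False
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                warnings.warn(
                    f"no mutually non-missing sites between "
                    f"{aln.records[i].id} and {aln.records[j].id}",
                    stacklevel=2,
                )
                D[i, j] = D[j, i] = math.nan
                continue
            any_pair = True
            D[i, j] = D[j, i] = np.sum(M[i, both] != M[j, both]) / m
    if not any_pair:
        raise AlignmentError("no sequence pair shares a non-missing site")
    return D, float(np.nanmax(D))


def nucleotide_diversity(aln: BarcodeAlignment) -> float:
    """Mean pairwise p-distance over all n(n−1)/2 pairs (NaN pairs excluded)."""
    D, _ = p_distance_matrix(aln)
    iu = np.triu_indices(aln.n, k=1)
    return float(np.nanmean(D[iu]))


@dataclass(frozen=True)
class AlignmentSummary:
    length: int
    variable_sites: int
    pct_variable: float
    missing_fraction: float  # percent
    gc_content: float  # percent


def alignment_summary(aln: BarcodeAlignment) -> AlignmentSummary:
    """Variable sites, missing fraction and GC content of an alignment.

    A variable site has ≥ 2 distinct states among {A,C,G,T}; missing
    states (N, -, ?) are ignored when counting variability and GC.
    """
    M = aln.to_matrix()
    ok = ~np.isin(M, sorted(MISSING_STATES))
    variable = 0
    for col in range(aln.length):
        states = set(M[ok[:, col], col])
        if len(states) >= 2:
            variable += 1
    total_cells = M.size
    missing = 100.0 * (total_cells - ok.sum()) / total_cells
    bases = M[ok]
    gc = 100.0 * np.isin(bases, ["G", "C"]).sum() / bases.size if bases.size else 0.0
    return AlignmentSummary(
        length=aln.length,
        variable_sites=variable,
        pct_variable=100.0 * variable / aln.length,
        missing_fraction=float(missing),
        gc_content=float(gc),
    )


@dataclass(frozen=True)
class DiversityStats:
    n: int
    L: int
    k: int
    h: float
    pi: float
    max_div: float


def diversity_stats(aln: BarcodeAlignment, missing_policy: str = "strict") -> DiversityStats:
    """One-stop barcode diversity summary for an alignment."""
    ms = collapse_mitotypes(aln, missing_policy)
    if ms.k == 1:
        return DiversityStats(aln.n, aln.length, 1, 0.0, 0.0, 0.0)
    D, max_div = p_distance_matrix(aln)
    iu = np.triu_indices(aln.n, k=1)
    pi = float(np.nanmean(D[iu]))
    return DiversityStats(aln.n, aln.length, ms.k, haplotype_diversity(ms), pi, max_div)


def format_percent(x: float, decimals: int = 1) -> str:
    """Half-up percentage formatting: 0.00608 → '0.6%'."""
    scaled = x * 100.0 * 10**decimals
    rounded = math.floor(scaled + 0.5) / 10**decimals
    return f"{rounded:.{decimals}f}%"


def distance_matrix_csv(aln: BarcodeAlignment, D: np.ndarray) -> str:
    """Square distance matrix as CSV text."""
    buf = io.StringIO()
    ids = [r.id for r in aln.records]
    buf.write("," + ",".join(ids) + "\n")
    for i, rid in enumerate(ids):
        buf.write(rid + "," + ",".join(f"{v:.6f}" for v in D[i]) + "\n")
    return buf.getvalue()


def distance_matrix_phylip(aln: BarcodeAlignment, D: np.ndarray) -> str:
    """PHYLIP-style square distance matrix."""
    lines = [f"{aln.n}"]
    for i, r in enumerate(aln.records):
        lines.append(f"{r.id[:10]:<10} " + " ".join(f"{v:.6f}" for v in D[i]))
    return "\n".join(lines) + "\n"
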
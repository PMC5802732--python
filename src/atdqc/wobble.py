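"""tRNA acceptor-stem analysis: G4:U69 wobble detection and enrichment.

Eukaryotic alanyl-tRNA synthetase recognizes a G:U wobble pair in the
acceptor stem and will mischarge L-alanine onto non-alanine tRNAs that
carry one at position 4:69 — most prominently tRNA-Thr(G4:U69). This
module reconstructs the seven acceptor-stem base pairs from mature tRNA
gene sequences (canonical numbering: position i pairs 73-i), detects the
directional G4:U69 signature (G on the 5' strand), aggregates per-organism
per-isotype enrichment, and tests its co-occurrence with the presence of
the proofreading factor ATD by a two-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "TRNAGene",
    "AcceptorStem",
    "WobbleCall",
    "EnrichmentRow",
    "CooccurrenceReport",
    "ConsensusReport",
    "SchemaError",
    "read_trna_table",
    "filter_by_score",
    "acceptor_stem_pairs",
    "detect_wobble",
    "enrichment",
    "fisher_exact_two_sided",
    "cooccurrence",
    "acceptor_consensus",
]

MIN_TRNA_LENGTH = 60
TSV_COLUMNS = ("organism", "isotype", "anticodon", "score", "sequence")


class SchemaError(ValueError):
    """Input table missing a mandatory column."""


@dataclass(frozen=True)
class TRNAGene:
    organism: str
    isotype: str
    anticodon: str
    score: float
    sequence: str  # mature gene, RNA alphabet (T normalized to U)
    secondary_structure: Optional[str] = None

    def __post_init__(self):
        if not math.isfinite(self.score):
            raise ValueError("tRNAscan-SE score must be finite")
        object.__setattr__(
            self, "sequence", self.sequence.upper().replace("T", "U")
        )


@dataclass(frozen=True)
class AcceptorStem:
    """The seven 5'/3' base pairs of the acceptor stem.

    Each tuple is (five_prime_base, three_prime_base, five_prime_pos,
    three_prime_pos) with canonical 1-based numbering (pair i is i:73-i).
    """

    pairs: tuple[tuple[str, str, int, int], ...]

    def __post_init__(self):
        if len(self.pairs) != 7:
            raise ValueError("acceptor stem must have exactly 7 pairs")


@dataclass(frozen=True)
class WobbleCall:
    pair_index: int
    bases: tuple[str, str]
    is_G4U69: bool
    is_U4G69: bool


@dataclass(frozen=True)
class EnrichmentRow:
    organism: str
    isotype: str
    n_total: int
    n_wobble: int

    @property
    def fraction(self) -> float:
        return 100.0 * self.n_wobble / self.n_total


@dataclass(frozen=True)
class CooccurrenceReport:
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: enriched?, cols: ATD?
    concordance: float
    fisher_p: float


@dataclass(frozen=True)
class ConsensusReport:
    # per stem pair: ((5' base, 3' base), modal frequency)
    conservation: tuple[tuple[tuple[str, str], float], ...]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trna_table(path, format: str = "tsv") -> list[TRNAGene]:
    """Load tRNA genes from a TSV table or a FASTA file.

    TSV columns: organism, isotype, anticodon, score, sequence, and an
    optional secondary_structure. FASTA headers carry the same metadata as
    ``key=value`` tokens, e.g.::

        >Hsap-Thr-1 organism=Homo_sapiens isotype=Thr anticodon=AGU score=75.2

    DNA input is accepted; T is normalized to U.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in TSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {missing}")
        genes = []
        for row in df.itertuples(index=False):
            ss = getattr(row, "secondary_structure", None)
            genes.append(
                TRNAGene(
                    organism=row.organism,
                    isotype=row.isotype,
                    anticodon=row.anticodon,
                    score=float(row.score),
                    sequence=row.sequence,
                    secondary_structure=None if ss in (None, "") or pd.isna(ss) else ss,
                )
            )
        return genes
    if format == "fasta":
        from Bio import SeqIO

        genes = []
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = dict(
                tok.split("=", 1) for tok in rec.description.split() if "=" in tok
            )
            missing = [k for k in ("organism", "isotype", "anticodon", "score") if k not in fields]
            if missing:
                raise SchemaError(
                    f"FASTA header of {rec.id!r} lacks field(s): {missing}"
                )
            genes.append(
                TRNAGene(
                    organism=fields["organism"],
                    isotype=fields["isotype"],
                    anticodon=fields["anticodon"],
                    score=float(fields["score"]),
                    sequence=str(rec.seq),
                )
            )
        return genes
    raise ValueError("format must be 'tsv' or 'fasta'")


def filter_by_score(genes: Iterable[TRNAGene], threshold: float = 50.0) -> list[TRNAGene]:
    """Keep genes with tRNAscan-SE score strictly greater than ``threshold``."""
    return [g for g in genes if g.score > threshold]


# ---------------------------------------------------------------------------
# Acceptor stem
# ---------------------------------------------------------------------------

def acceptor_stem_pairs(gene: TRNAGene) -> AcceptorStem:
    """Reconstruct the 7 acceptor-stem pairs by positional pairing.

    A terminal CCA, if present, is stripped (gene sequences from tRNA
    databases generally lack it; mature tRNAs carry it). The final base of
    the stripped sequence is the unpaired discriminator; 5' position i then
    pairs 3' position L-i+1 (i = 1..7) where L excludes the discriminator.
    For a canonical 73-nt gene this is the textbook i:73-i pairing, so pair
    4 joins positions 4 and 69. A provided dot-bracket secondary structure
    overrides positional pairing.
    """
    seq = gene.sequence
    if seq.endswith("CCA"):
        seq = seq[:-3]
    if len(seq) < MIN_TRNA_LENGTH:
        raise ValueError(
            f"sequence too short after CCA handling ({len(seq)} < {MIN_TRNA_LENGTH})"
        )
    if gene.secondary_structure is not None:
        return _stem_from_structure(seq, gene.secondary_structure)
    L = len(seq) - 1  # exclude the discriminator base
    pairs = []
    for i in range(1, 8):
        j = L - i + 1  # 1-based 3' partner
        pairs.append((seq[i - 1], seq[j - 1], i, j))
    return AcceptorStem(pairs=tuple(pairs))


def _stem_from_structure(seq: str, ss: str) -> AcceptorStem:
    """Acceptor stem from a dot-bracket string (first 7 opening pairs)."""
    if len(ss) < len(seq):
        raise ValueError("secondary structure shorter than sequence")
    stack, pairing = [], {}
    for i, c in enumerate(ss[: len(seq)]):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced secondary structure")
            j = stack.pop()
            pairing[j] = i
    opens = sorted(pairing)[:7]
    if len(opens) < 7:
        raise ValueError("secondary structure has fewer than 7 stem pairs")
    pairs = tuple(
        (seq[i], seq[pairing[i]], i + 1, pairing[i] + 1) for i in opens
    )
    return AcceptorStem(pairs=pairs)


def detect_wobble(stem: AcceptorStem, pair_index: int = 4) -> WobbleCall:
    """Directional G:U call at a stem pair (1-7).

    ``is_G4U69`` requires G on the 5' strand and U on the 3' strand at
    pair 4; the reversed U4:G69 arrangement is reported separately because
    only the G-on-5' geometry is the synthetase misrecognition element.
    """
    if not 1 <= pair_index <= 7:
        raise ValueError("pair_index must be 1..7")
    five, three, _, _ = stem.pairs[pair_index - 1]
    gu = five == "G" and three == "U"
    ug = five == "U" and three == "G"
    return WobbleCall(
        pair_index=pair_index,
        bases=(five, three),
        is_G4U69=gu and pair_index == 4,
        is_U4G69=ug and pair_index == 4,
    )


def _has_g4u69(gene: TRNAGene) -> bool:
    try:
        return detect_wobble(acceptor_stem_pairs(gene), 4).is_G4U69
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Enrichment and co-occurrence
# ---------------------------------------------------------------------------

def enrichment(
    genes: Sequence[TRNAGene],
    isotype: Optional[str] = None,
) -> list[EnrichmentRow]:
    """Per-(organism, isotype) G4:U69 gene counts and percentage.

    ``genes`` should already be score-filtered. Isodecoder duplicates are
    counted per gene copy. Empty groups cannot arise (groups are formed
    from the genes themselves).
    """
    rows: dict[tuple[str, str], list[int]] = {}
    for g in genes:
        if isotype is not None and g.isotype != isotype:
            continue
        key = (g.organism, g.isotype)
        tot_wob = rows.setdefault(key, [0, 0])
        tot_wob[0] += 1
        if _has_g4u69(g):
            tot_wob[1] += 1
    return [
        EnrichmentRow(org, iso, tot, wob)
        for (org, iso), (tot, wob) in sorted(rows.items())
    ]


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    All tables with the observed margins are enumerated and the
    probabilities of those no more likely than the observed table are
    summed (with a small relative tolerance for float ties).
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def pmf(x: int) -> float:
        return (
            math.comb(c1, x) * math.comb(n - c1, r1 - x) / math.comb(n, r1)
        )

    p_obs = pmf(a)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    total = sum(
        p for x in range(lo, hi + 1) if (p := pmf(x)) <= p_obs * (1 + 1e-9)
    )
    return min(1.0, total)


def cooccurrence(
    rows: Sequence[EnrichmentRow],
    presence: Mapping[str, bool],
    enrich_threshold: float = 10.0,
    isotype: str = "Thr",
) -> CooccurrenceReport:
    """Association between tRNA-Thr(G4:U69) enrichment and ATD presence.

    An organism counts as enriched when its tRNA-Thr G4:U69 percentage is
    at least ``enrich_threshold``; organisms absent from ``rows`` for the
    isotype count as not enriched. Reports the 2x2 table (enriched x ATD
    present), the diagonal concordance, and the two-sided Fisher exact p.
    """
    if len(presence) < 2:
        raise ValueError("need at least 2 organisms")
    frac = {
        r.organism: r.fraction for r in rows if r.isotype == isotype
    }
    t = [[0, 0], [0, 0]]
    for org, present in presence.items():
        enriched = frac.get(org, 0.0) >= enrich_threshold
        t[0 if enriched else 1][0 if present else 1] += 1
    n = len(presence)
    concord = (t[0][0] + t[1][1]) / n
    p = fisher_exact_two_sided(t)
    return CooccurrenceReport(
        table=((t[0][0], t[0][1]), (t[1][0], t[1][1])),
        concordance=concord,
        fisher_p=p,
    )


def acceptor_consensus(genes: Sequence[TRNAGene]) -> ConsensusReport:
    """Modal base pair and its frequency for each of the 7 stem pairs."""
    if not genes:
        raise ValueError("need at least one gene")
    counts: list[dict[tuple[str, str], int]] = [dict() for _ in range(7)]
    n = 0
    for g in genes:
        stem = acceptor_stem_pairs(g)
        n += 1
        for k, (five, three, _, _) in enumerate(stem.pairs):
            counts[k][(five, three)] = counts[k].get((five, three), 0) + 1
    cons = tuple(
        (max(c, key=c.get), c[max(c, key=c.get)] / n) for c in counts
    )
    return ConsensusReport(conservation=cons)
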